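"""XCSR: an accuracy-based learning classifier system on real inputs.

The learner maintains a population [P] of interval-predicate rules.  Each
single-step problem presents one (normalized) patient record: rules whose
condition matches form the match set [M] (covering creates rules when
fewer than ``theta_mna`` actions are represented); the prediction array
[PA] holds, per action, the fitness-weighted mean predicted payoff;
explore trials pick the action by roulette over the [PA] entries and
exploit trials pick the argmax.  The environment pays ``reward_correct``
when the chosen action equals the recorded outcome and
``reward_incorrect`` otherwise.  On explore trials the action set [A] is
updated with the Widrow–Hoff delta rule (MAM averaging early on), an
accuracy-based fitness update is applied, a niche genetic algorithm
recombines and mutates interval predicates, and subsumption plus a
deletion scheme keep the population compact and below its microclassifier
budget ``N``.

Sliding-window exploit accuracy (window 50) is recorded per exploit
trial as the learning curve.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .population import FULL_RANGE, Classifier, IntervalPredicate, Population

__all__ = [
    "XCSRParams",
    "PredictionArray",
    "TrainResult",
    "normalize",
    "denormalize",
    "matches",
    "cover",
    "build_match_set",
    "build_prediction_array",
    "select_action",
    "environment_reward",
    "update_action_set",
    "subsumes",
    "run_ga",
    "enforce_population_limit",
    "rule_accuracy",
    "train",
    "predict",
    "predict_scores",
]

logger = logging.getLogger(__name__)

#: exploit-accuracy sliding window length (trials)
CURVE_WINDOW = 50


@dataclass(frozen=True)
class XCSRParams:
    """Hyperparameters of the learner.

    The defaults are the published configuration for the 40-variable
    extubation problem: 100 passes over the data, at most 1500
    microclassifiers, learning rate ``beta`` 0.2, accuracy fall-off
    ``alpha`` 0.1 with exponent ``nu`` 0.1 and error tolerance
    ``eps_0`` 10, GA threshold 25 with crossover 0.8 / mutation 0.04,
    deletion threshold 20 with fitness fraction ``delta`` 0.1,
    subsumption threshold 20, don't-care probability 0.5, initial
    prediction/error/fitness 10 / 0 / 10 and two actions per match set.

    ``reward_correct``/``reward_incorrect`` (1000/0), the covering
    spread cap ``s_r`` and the mutation step ``m_i`` (both on the
    normalized [0, 1] scale) are not part of the published table and are
    configurable here.
    """

    epochs: int = 100
    N: int = 1500
    beta: float = 0.2
    alpha: float = 0.1
    nu: float = 0.1
    eps_0: float = 10.0
    theta_ga: float = 25.0
    chi: float = 0.8
    mu: float = 0.04
    theta_del: int = 20
    delta: float = 0.1
    theta_sub: int = 20
    p_dontcare: float = 0.5
    p_init: float = 10.0
    eps_init: float = 0.0
    f_init: float = 10.0
    theta_mna: int = 2
    reward_correct: float = 1000.0
    reward_incorrect: float = 0.0
    s_r: float = 0.5
    m_i: float = 0.1
    seed: int = 0
    crossover: str = "uniform"  # "uniform" (gate at chi) or "per_locus" (swap w.p. chi)

    def __post_init__(self) -> None:
        for name in ("beta", "alpha", "chi", "mu", "delta", "p_dontcare"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.N < self.theta_mna:
            raise ValueError("N must be >= theta_mna")
        if self.s_r <= 0 or self.m_i <= 0:
            raise ValueError("s_r and m_i must be > 0")
        if self.crossover not in ("uniform", "per_locus"):
            raise ValueError("crossover must be 'uniform' or 'per_locus'")

    def with_seed(self, seed: int) -> "XCSRParams":
        return replace(self, seed=seed)


@dataclass
class PredictionArray:
    """Per-action expected payoff over a match set.

    ``expected_reward[a]`` is the numerosity-weighted, fitness-weighted
    mean of the predictions of the action-``a`` rules; ``fitness_sum``
    carries the weights for exploit tie-breaking; actions without any
    matching rule are simply absent.
    """

    expected_reward: dict[int, float] = field(default_factory=dict)
    fitness_sum: dict[int, float] = field(default_factory=dict)

    @property
    def present_actions(self) -> set[int]:
        return set(self.expected_reward)


@dataclass
class TrainResult:
    """Outcome of a training run: final population and learning curve."""

    population: Population
    curve: np.ndarray
    ranges: pd.DataFrame | None = None

    def __iter__(self):
        return iter((self.population, self.curve))

    @property
    def final_accuracy(self) -> float:
        """Windowed exploit accuracy at the end of training."""
        return float(self.curve[-1]) if self.curve.size else float("nan")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Min-max scale each column to [0, 1] over the cohort.

    Returns the scaled frame and a per-variable range table (columns
    ``min``, ``max``, ``constant``) used for de-normalized rule
    reporting and don't-care detection.  A constant column carries no
    information on this cohort; it is mapped to 0.5 and flagged.
    """
    lo = frame.min(axis=0)
    hi = frame.max(axis=0)
    const = hi == lo
    if const.any():
        logger.warning(
            "constant variables mapped to 0.5: %s", list(frame.columns[const])
        )
    span = (hi - lo).where(~const, 1.0)
    out = (frame - lo) / span
    if const.any():
        out.loc[:, const[const].index] = 0.5
    ranges = pd.DataFrame({"min": lo, "max": hi, "constant": const})
    return out, ranges


def denormalize(frame: pd.DataFrame, ranges: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`normalize` (constant columns return their value)."""
    lo = ranges["min"]
    span = (ranges["max"] - ranges["min"]).where(~ranges["constant"], 0.0)
    return frame * span + lo


# ---------------------------------------------------------------------------
# matching and covering
# ---------------------------------------------------------------------------

def matches(predicate: IntervalPredicate, x: float) -> bool:
    """Half-open interval test ``c - s <= x < c + s``."""
    return predicate.center - predicate.spread <= x < predicate.center + predicate.spread


def _cover_arrays(x, params: XCSRParams, rng) -> tuple[np.ndarray, np.ndarray]:
    d = x.shape[0]
    dont_care = rng.random(d) < params.p_dontcare
    # spread drawn from (0, s_r]: an empty interval would not match x
    spread = params.s_r * (1.0 - rng.random(d))
    center = np.where(dont_care, FULL_RANGE[0], x)
    spread = np.where(dont_care, FULL_RANGE[1], spread)
    return center, spread


def cover(x, missing_action: int, params: XCSRParams, rng=None, t: int = 0) -> Classifier:
    """Create a rule matching ``x`` with the requested action.

    Each predicate is independently a full-range don't-care interval
    with probability ``p_dontcare``; otherwise it is centred exactly on
    the input value with spread drawn uniformly from (0, s_r].
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    x = np.asarray(x, dtype=float)
    center, spread = _cover_arrays(x, params, rng)
    return Classifier(
        condition=[IntervalPredicate(float(c), float(s)) for c, s in zip(center, spread)],
        action=int(missing_action),
        prediction=params.p_init,
        prediction_error=params.eps_init,
        fitness=params.f_init,
        ga_timestamp=t,
    )


def build_match_set(
    pop: Population, x, t: int, params: XCSRParams, rng
) -> np.ndarray:
    """Row indices of [M], covering until ``theta_mna`` actions appear.

    Covered rules are inserted into [P] (with deletion enforcement), so
    the returned indices are valid for the post-covering population.
    """
    x = np.asarray(x, dtype=float)
    want = min(params.theta_mna, 2)  # binary action space
    while True:
        idx = np.flatnonzero(pop.match_mask(x))
        present = set(pop.actions[idx].tolist())
        missing = [a for a in (0, 1) if a not in present]
        if len(present) >= want or not missing:
            return idx
        center, spread = _cover_arrays(x, params, rng)
        pop.insert(
            center, spread, missing[0], params.p_init, params.eps_init,
            params.f_init, ga_timestamp=t,
        )
        enforce_population_limit(pop, params, rng)


# ---------------------------------------------------------------------------
# prediction and action selection
# ---------------------------------------------------------------------------

def build_prediction_array(pop: Population, match_idx: np.ndarray) -> PredictionArray:
    """Fitness-weighted mean payoff per action over [M].

    Weights are numerosity-weighted fitness.  If an action's weight sum
    is zero the unweighted mean is used instead (flagged in the log).
    """
    if match_idx.size == 0:
        raise ValueError("match set is empty")
    pa = PredictionArray()
    acts = pop.actions[match_idx]
    for a in sorted(set(acts.tolist())):
        rows = match_idx[acts == a]
        w = pop.fitness[rows] * pop.numerosity[rows]
        total = float(w.sum())
        if total > 0:
            value = float((pop.prediction[rows] * w).sum() / total)
        else:
            logger.warning("all-zero fitness for action %d: unweighted PA mean", a)
            value = float(pop.prediction[rows].mean())
        pa.expected_reward[int(a)] = value
        pa.fitness_sum[int(a)] = total
    return pa


def select_action(pa: PredictionArray, mode: str, rng, floor: float = 0.0) -> int:
    """Explore: roulette over [PA] entries; exploit: argmax.

    Roulette entries are shifted to be nonnegative if necessary (all
    zero → uniform).  ``floor`` sets a minimum roulette weight per
    action: purely payoff-proportional selection has an absorbing state
    — an action whose payoff estimate reaches the zero reward is never
    sampled again, freezing its estimate — so the training loop floors
    weights at the initial-prediction scale to keep every action
    reachable.  Exploit ties break on larger fitness sum, then on the
    lower action index.
    """
    if not pa.expected_reward:
        raise ValueError("prediction array has no present action")
    actions = sorted(pa.expected_reward)
    if mode == "explore":
        w = np.array([pa.expected_reward[a] for a in actions], dtype=float)
        if w.min() < 0:
            w = w - w.min()
        if floor > 0:
            w = np.maximum(w, floor)
        if w.sum() <= 0:
            w = np.ones_like(w)
        return int(rng.choice(actions, p=w / w.sum()))
    if mode == "exploit":
        return max(
            actions,
            key=lambda a: (pa.expected_reward[a], pa.fitness_sum.get(a, 0.0), -a),
        )
    raise ValueError(f"unknown mode {mode!r}")


def environment_reward(action: int, outcome: int, params: XCSRParams) -> float:
    """Immediate payoff: correct/incorrect reward for a single-step problem."""
    return params.reward_correct if action == outcome else params.reward_incorrect


# ---------------------------------------------------------------------------
# reinforcement update
# ---------------------------------------------------------------------------

def rule_accuracy(eps, params: XCSRParams):
    """Accuracy ``kappa``: 1 below the error tolerance, power-law fall-off above.

    ``kappa = 1`` if ``eps < eps_0`` else ``alpha * (eps/eps_0)**(-nu)``.
    """
    eps = np.asarray(eps, dtype=float)
    return np.where(
        eps < params.eps_0,
        1.0,
        params.alpha * (np.maximum(eps, params.eps_0) / params.eps_0) ** (-params.nu),
    )


def update_action_set(
    pop: Population, action_idx: np.ndarray, reward: float, params: XCSRParams
) -> None:
    """Widrow–Hoff update of [A] plus the accuracy-based fitness update.

    The problem is single-step, so the Q-learning backup has no
    discounted next-state term and the target is the immediate reward.
    Prediction, error and action-set-size estimates use MAM averaging
    (rate 1/experience) until experience reaches 1/beta.  Accuracy is
    ``kappa = 1`` when the error is below ``eps_0`` and
    ``alpha * (eps/eps_0)**(-nu)`` otherwise; fitness tracks the
    numerosity-weighted relative accuracy within [A].
    """
    A = action_idx
    if A.size == 0:
        raise ValueError("action set is empty")
    pop.experience[A] += 1
    lr = np.where(pop.experience[A] < 1.0 / params.beta,
                  1.0 / pop.experience[A], params.beta)
    err_signal = np.abs(reward - pop.prediction[A])
    pop.error[A] += lr * (err_signal - pop.error[A])
    pop.prediction[A] += lr * (reward - pop.prediction[A])
    set_size = float(pop.numerosity[A].sum())
    pop.as_size[A] += lr * (set_size - pop.as_size[A])

    kappa = rule_accuracy(pop.error[A], params)
    weighted = kappa * pop.numerosity[A]
    rel = weighted / weighted.sum()
    pop.fitness[A] += params.beta * (rel - pop.fitness[A])


# ---------------------------------------------------------------------------
# subsumption
# ---------------------------------------------------------------------------

def _contains(lo_g, hi_g, lo_s, hi_s) -> tuple[bool, bool]:
    """(weak containment at every locus, strict at >= 1 locus)."""
    weak = bool(np.all((lo_g <= lo_s) & (hi_g >= hi_s)))
    strict = bool(np.any((lo_g < lo_s) | (hi_g > hi_s)))
    return weak, strict


def subsumes(general: Classifier, specific: Classifier, params: XCSRParams) -> bool:
    """Can ``general`` absorb ``specific``?

    Requires the same action, experience above ``theta_sub``, error
    below ``eps_0`` and interval containment at every locus with strict
    containment at at least one.
    """
    if general.action != specific.action:
        return False
    if general.experience <= params.theta_sub:
        return False
    if general.prediction_error >= params.eps_0:
        return False
    gc = np.array([p.center for p in general.condition])
    gs = np.array([p.spread for p in general.condition])
    sc = np.array([p.center for p in specific.condition])
    ss = np.array([p.spread for p in specific.condition])
    weak, strict = _contains(gc - gs, gc + gs, sc - ss, sc + ss)
    return weak and strict


def _row_subsumes(pop: Population, g: int, lo_s, hi_s, action: int,
                  params: XCSRParams) -> bool:
    if pop.actions[g] != action:
        return False
    if pop.experience[g] <= params.theta_sub or pop.error[g] >= params.eps_0:
        return False
    lo_g = pop.centers[g] - pop.spreads[g]
    hi_g = pop.centers[g] + pop.spreads[g]
    weak, strict = _contains(lo_g, hi_g, lo_s, hi_s)
    return weak and strict


def _action_set_subsumption(
    pop: Population, action_idx: np.ndarray, params: XCSRParams
) -> np.ndarray:
    """Let the most general eligible rule in [A] absorb the ones it contains."""
    A = action_idx
    eligible = A[
        (pop.experience[A] > params.theta_sub) & (pop.error[A] < params.eps_0)
    ]
    if eligible.size == 0:
        return A
    width = (2 * pop.spreads[eligible]).sum(axis=1)
    g = int(eligible[np.argmax(width)])
    lo_g = pop.centers[g] - pop.spreads[g]
    hi_g = pop.centers[g] + pop.spreads[g]
    absorbed = []
    for i in A:
        i = int(i)
        if i == g:
            continue
        lo_s = pop.centers[i] - pop.spreads[i]
        hi_s = pop.centers[i] + pop.spreads[i]
        weak, strict = _contains(lo_g, hi_g, lo_s, hi_s)
        if weak and strict:
            pop.numerosity[g] += pop.numerosity[i]
            absorbed.append(i)
    if not absorbed:
        return A
    keep = [int(i) for i in A if int(i) not in absorbed]
    # swap-with-last removal: delete from the highest row index down and
    # remap surviving indices that pointed at relocated rows
    for i in sorted(absorbed, reverse=True):
        last = pop.n - 1
        pop.remove(i)
        keep = [i if j == last else j for j in keep]
    return np.array(sorted(set(keep)), dtype=np.int64)


# ---------------------------------------------------------------------------
# genetic algorithm and deletion
# ---------------------------------------------------------------------------

def _roulette(weights: np.ndarray, rng) -> int:
    total = float(weights.sum())
    if total <= 0:
        return int(rng.integers(weights.size))
    return int(rng.choice(weights.size, p=weights / total))


def run_ga(
    pop: Population, action_idx: np.ndarray, x, t: int,
    params: XCSRParams, rng,
) -> bool:
    """Niche GA on [A]; returns True when it actually ran.

    Triggered when the numerosity-weighted mean age since the last GA
    exceeds ``theta_ga``.  Two parents are drawn by roulette over
    numerosity-weighted fitness; offspring exchange interval predicates
    (uniform per-locus swap by default) with probability ``chi`` and
    each center/spread gene is perturbed by ±Uniform(0, m_i] with
    probability ``mu`` (spreads clamped at 0).  Offspring inherit mean
    parental prediction/error and 10% of mean parental fitness, may be
    subsumed by their parents, and insertion is followed by deletion
    enforcement.
    """
    A = action_idx
    if A.size == 0:
        raise ValueError("action set is empty")
    num = pop.numerosity[A].astype(float)
    age = (t - pop.ga_timestamp[A]).astype(float)
    if (age * num).sum() / num.sum() <= params.theta_ga:
        return False
    pop.ga_timestamp[A] = t

    w = pop.fitness[A] * num
    p1 = int(A[_roulette(w, rng)])
    p2 = int(A[_roulette(w, rng)])

    d = pop.n_features
    child_c = [pop.centers[p].copy() for p in (p1, p2)]
    child_s = [pop.spreads[p].copy() for p in (p1, p2)]

    if params.crossover == "uniform":
        if rng.random() < params.chi:
            swap = rng.random(d) < 0.5
            _swap_loci(child_c, child_s, swap)
    else:  # per-locus semantics: each predicate exchanged w.p. chi
        swap = rng.random(d) < params.chi
        _swap_loci(child_c, child_s, swap)

    for c, s in zip(child_c, child_s):
        mut_c = rng.random(d) < params.mu
        mut_s = rng.random(d) < params.mu
        step_c = params.m_i * (1.0 - rng.random(d)) * rng.choice((-1.0, 1.0), d)
        step_s = params.m_i * (1.0 - rng.random(d)) * rng.choice((-1.0, 1.0), d)
        c += np.where(mut_c, step_c, 0.0)
        s += np.where(mut_s, step_s, 0.0)
        np.maximum(s, 0.0, out=s)

    mean_p = 0.5 * (pop.prediction[p1] + pop.prediction[p2])
    mean_e = 0.5 * (pop.error[p1] + pop.error[p2])
    mean_f = 0.5 * (pop.fitness[p1] + pop.fitness[p2])
    mean_as = 0.5 * (pop.as_size[p1] + pop.as_size[p2])
    action = int(pop.actions[p1])

    for c, s in zip(child_c, child_s):
        lo, hi = c - s, c + s
        parent_hit = next(
            (p for p in (p1, p2) if _row_subsumes(pop, p, lo, hi, action, params)),
            None,
        )
        if parent_hit is not None:
            pop.numerosity[parent_hit] += 1
        else:
            pop.insert(
                c, s, action, mean_p, mean_e, 0.1 * mean_f,
                ga_timestamp=t, as_size=mean_as,
            )
    enforce_population_limit(pop, params, rng)
    return True


def _swap_loci(child_c, child_s, swap: np.ndarray) -> None:
    c0, c1 = child_c
    s0, s1 = child_s
    c0[swap], c1[swap] = c1[swap].copy(), c0[swap].copy()
    s0[swap], s1[swap] = s1[swap].copy(), s0[swap].copy()


def enforce_population_limit(pop: Population, params: XCSRParams, rng) -> int:
    """Roulette deletion until the microclassifier count is within ``N``.

    A macroclassifier's vote is its action-set size estimate times its
    numerosity; experienced rules whose per-micro fitness falls below
    ``delta`` times the population mean get their vote inflated by the
    fitness deficit, preferentially removing weak rules.  Returns the
    number of microclassifiers deleted.
    """
    deleted = 0
    while pop.micro_count > params.N:
        n = pop.n
        num = pop.numerosity[:n].astype(float)
        votes = pop.as_size[:n] * num
        mean_f = pop.mean_fitness_per_micro()
        per_micro = pop.fitness[:n] / num
        weak = (pop.experience[:n] > params.theta_del) & (
            per_micro < params.delta * mean_f
        )
        if mean_f > 0:
            votes = np.where(
                weak, votes * mean_f / np.maximum(per_micro, 1e-12 * mean_f), votes
            )
        if votes.sum() <= 0:
            votes = num
        i = _roulette(votes, rng)
        pop.numerosity[i] -= 1
        deleted += 1
        if pop.numerosity[i] == 0:
            pop.remove(i)
    return deleted


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

def train(
    X, y, params: XCSRParams, *, on_trial=None
) -> TrainResult:
    """Run ``epochs`` shuffled passes of single-step problems.

    Explore and exploit trials strictly alternate.  The Widrow–Hoff
    reinforcement update runs on every trial (rules see the payoff of
    whichever action was executed); rule discovery — action-set
    subsumption and the GA — runs on explore trials only.  Exploit
    trials measure performance: the learning curve is the fraction
    correct over the last 50 exploit trials, recorded per exploit
    trial.  Covering applies in both modes so a prediction is always
    defined.  All randomness flows from ``params.seed``.
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training cohort is empty")
    n, d = X.shape
    rng = np.random.default_rng(params.seed)
    pop = Population(d, capacity=max(256, params.N + 64))

    window: deque[bool] = deque(maxlen=CURVE_WINDOW)
    curve: list[float] = []
    t = 0          # GA clock: explore trials
    explore = True
    for _ in range(params.epochs):
        for i in rng.permutation(n):
            x = X[i]
            outcome = int(y[i])
            m_idx = build_match_set(pop, x, t, params, rng)
            pa = build_prediction_array(pop, m_idx)
            if explore:
                action = select_action(pa, "explore", rng, floor=params.p_init)
            else:
                action = select_action(pa, "exploit", rng)
                window.append(action == outcome)
                curve.append(sum(window) / len(window))
            a_idx = m_idx[pop.actions[m_idx] == action]
            reward = environment_reward(action, outcome, params)
            update_action_set(pop, a_idx, reward, params)
            if explore:
                a_idx = _action_set_subsumption(pop, a_idx, params)
                run_ga(pop, a_idx, x, t, params, rng)
                t += 1
            if on_trial is not None:
                on_trial(pop)
            explore = not explore
    return TrainResult(pop, np.asarray(curve))


def predict(pop: Population, x) -> tuple[int | None, PredictionArray]:
    """Exploit-mode prediction without covering, learning or GA.

    Returns ``(action, prediction_array)``; the action is ``None`` when
    no rule matches at all (abstention — callers count these
    separately).  Actions without a matching rule are absent from the
    array.
    """
    x = np.asarray(x, dtype=float)
    idx = np.flatnonzero(pop.match_mask(x))
    if idx.size == 0:
        return None, PredictionArray()
    pa = build_prediction_array(pop, idx)
    rng = np.random.default_rng(0)  # unused: exploit selection is deterministic
    return select_action(pa, "exploit", rng), pa


def predict_scores(
    pop: Population, X, params: XCSRParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-record success-vs-failure payoff scores for ROC analysis.

    The score is PA(success) − PA(failure); an absent entry is imputed
    with ``reward_incorrect``.  Returns (scores, predicted actions with
    −1 for abstention, abstention mask).
    """
    X = np.asarray(X, dtype=float)
    scores = np.empty(X.shape[0])
    actions = np.empty(X.shape[0], dtype=np.int64)
    abstain = np.zeros(X.shape[0], dtype=bool)
    ri = params.reward_incorrect
    for k, x in enumerate(X):
        act, pa = predict(pop, x)
        if act is None:
            abstain[k] = True
            actions[k] = -1
            scores[k] = 0.0
            continue
        actions[k] = act
        scores[k] = pa.expected_reward.get(1, ri) - pa.expected_reward.get(0, ri)
    return scores, actions, abstain
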