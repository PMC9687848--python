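"""Rule-based feature importance: don't-care counts and Prob_usage.

A variable's importance is read directly off the evolved rule set: a
locus whose interval covers the variable's whole normalized range is a
"don't care" — the rule ignores that variable.  For variable *i* over a
stable rule set of ``T`` macroclassifiers with ``D_i`` don't-care loci,

    Prob_usage(i) = (T - D_i) / T * 100%

i.e. the percentage of rules that actually condition on the variable.
The statistic is averaged over repeated independently-seeded model
builds (10 by default) and variables are ranked by mean Prob_usage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .population import Classifier, IntervalPredicate, Population
from .xcsr import TrainResult, XCSRParams, normalize, train

__all__ = [
    "StableRuleCriteria",
    "UsageReport",
    "extract_stable_rules",
    "is_dont_care",
    "prob_usage",
    "dont_care_counts",
    "multi_run_usage",
    "rules_to_records",
]

logger = logging.getLogger(__name__)

#: numerical tolerance for full-range detection on the normalized scale
DONT_CARE_TOL = 1e-9


@dataclass(frozen=True)
class StableRuleCriteria:
    """Filter selecting the stable rule set from the raw population.

    The published model reports far fewer stable rules than the
    population budget, implying a post-hoc filter; the default keeps
    macroclassifiers with experience at least the deletion threshold
    that match at least one training record.
    """

    min_experience: int = 20
    require_match: bool = True
    enabled: bool = True


@dataclass
class UsageReport:
    """Per-variable usage statistics across repeated model builds."""

    variables: list[str]
    seeds: list[int]
    total_rules: list[int]                 # per run
    per_action_counts: list[dict[int, int]]  # per run: action → rule count
    dont_care: np.ndarray                  # (n_runs, n_vars) counts
    prob: np.ndarray                       # (n_runs, n_vars) percent

    @property
    def n_runs(self) -> int:
        return len(self.seeds)

    @property
    def mean(self) -> np.ndarray:
        return self.prob.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        """Across-run SD of Prob_usage (population convention, ddof=0)."""
        return self.prob.std(axis=0, ddof=0)

    @property
    def rank(self) -> np.ndarray:
        """1-based rank by mean Prob_usage, descending (ties: schema order)."""
        order = np.argsort(-self.mean, kind="stable")
        ranks = np.empty(len(self.variables), dtype=np.int64)
        ranks[order] = np.arange(1, len(self.variables) + 1)
        return ranks

    def top(self, k: int) -> list[str]:
        order = np.argsort(-self.mean, kind="stable")
        return [self.variables[i] for i in order[:k]]

    def to_frame(self) -> pd.DataFrame:
        """Ranking table: variable, mean ± SD Prob_usage, per-run columns."""
        df = pd.DataFrame(
            {
                "variable": self.variables,
                "mean_prob_usage": self.mean,
                "sd": self.sd,
                "rank": self.rank,
            }
        )
        for r, seed in enumerate(self.seeds):
            df[f"run_seed{seed}"] = self.prob[r]
        return df.sort_values("rank").reset_index(drop=True)

    def dont_care_frame(self) -> pd.DataFrame:
        """Mean don't-care count per variable, sorted ascending (most-used
        variables first) — the sorted-count view of the rule set."""
        df = pd.DataFrame(
            {
                "variable": self.variables,
                "mean_dont_care_count": self.dont_care.mean(axis=0),
            }
        ).sort_values("mean_dont_care_count", kind="stable")
        return df.reset_index(drop=True)


def is_dont_care(
    predicate: IntervalPredicate, relax_tau: float | None = None
) -> bool:
    """Does this interval cover the whole normalized range [0, 1)?

    With ``relax_tau`` set, the relaxed criterion accepts coverage of at
    least ``1 - relax_tau`` of the range (sensitivity analysis only;
    the strict criterion is the default).
    """
    if relax_tau is not None:
        covered = min(predicate.upper, 1.0) - max(predicate.lower, 0.0)
        return covered >= 1.0 - relax_tau
    return predicate.lower <= DONT_CARE_TOL and predicate.upper >= 1.0 - DONT_CARE_TOL


def prob_usage(total_rules: int, dont_care_count: float) -> float:
    """Percentage of rules whose condition uses the variable."""
    if total_rules <= 0:
        raise ValueError("total_rules must be > 0")
    if not 0 <= dont_care_count <= total_rules:
        raise ValueError("dont_care_count must be in [0, total_rules]")
    return 100.0 * (total_rules - dont_care_count) / total_rules


def extract_stable_rules(
    pop: Population,
    X: np.ndarray | None = None,
    criteria: StableRuleCriteria = StableRuleCriteria(),
) -> list[Classifier]:
    """Macroclassifiers passing the stability filter.

    ``X`` is the normalized training matrix (required when
    ``criteria.require_match``).  Raises if nothing passes, with
    diagnostics about the raw population.
    """
    if not criteria.enabled:
        return pop.classifiers()
    keep = pop.experience[: pop.n] >= criteria.min_experience
    if criteria.require_match:
        if X is None:
            raise ValueError("require_match needs the training matrix")
        matched = np.zeros(pop.n, dtype=bool)
        for x in np.asarray(X, dtype=float):
            matched |= pop.match_mask(x)
        keep &= matched
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError(
            f"no stable rule: population has {pop.n} macroclassifiers, "
            f"max experience {int(pop.experience[:pop.n].max(initial=0))}, "
            f"criteria {criteria}"
        )
    rules = [pop.classifier_at(int(i)) for i in idx]
    by_action = {a: sum(1 for r in rules if r.action == a) for a in (0, 1)}
    logger.info(
        "stable rules: %d of %d macroclassifiers (failure=%d, success=%d)",
        len(rules), pop.n, by_action[0], by_action[1],
    )
    return rules


def dont_care_counts(
    rules: list[Classifier], n_vars: int, relax_tau: float | None = None,
    numerosity_weighted: bool = False,
) -> np.ndarray:
    """Per-variable don't-care locus count over the rule set.

    Counting is per macroclassifier by default, matching the "total
    rules number" denominator; the numerosity-weighted variant counts
    microclassifiers instead.
    """
    counts = np.zeros(n_vars)
    for cl in rules:
        w = cl.numerosity if numerosity_weighted else 1
        for i, pred in enumerate(cl.condition):
            if is_dont_care(pred, relax_tau):
                counts[i] += w
    return counts


def usage_from_rules(
    rules: list[Classifier], n_vars: int, relax_tau: float | None = None,
    numerosity_weighted: bool = False,
) -> tuple[int, np.ndarray, np.ndarray]:
    """(total rules, don't-care counts, Prob_usage vector) for one run."""
    total = (
        sum(cl.numerosity for cl in rules) if numerosity_weighted else len(rules)
    )
    counts = dont_care_counts(rules, n_vars, relax_tau, numerosity_weighted)
    probs = np.array([prob_usage(total, c) for c in counts])
    return total, counts, probs


def multi_run_usage(
    cohort: Cohort,
    params: XCSRParams,
    n_runs: int = 10,
    seeds: list[int] | None = None,
    criteria: StableRuleCriteria = StableRuleCriteria(),
    relax_tau: float | None = None,
    numerosity_weighted: bool = False,
    keep_results: list[TrainResult] | None = None,
) -> UsageReport:
    """Train ``n_runs`` models under distinct seeds and pool Prob_usage.

    The default seed schedule is 1..n_runs.  Results are summarised as
    across-run mean ± SD per variable with a descending-mean ranking.
    Pass a list as ``keep_results`` to also collect the per-run
    populations and learning curves.
    """
    seeds = list(range(1, n_runs + 1)) if seeds is None else list(seeds)
    names = [v.name for v in cohort.schema]
    Xn, ranges = normalize(cohort.features)
    X = Xn.to_numpy(dtype=float)
    y = cohort.outcomes

    totals, actions, dc_rows, prob_rows = [], [], [], []
    for seed in seeds:
        result = train(X, y, params.with_seed(seed))
        result.ranges = ranges
        rules = extract_stable_rules(result.population, X, criteria)
        total, counts, probs = usage_from_rules(
            rules, len(names), relax_tau, numerosity_weighted
        )
        totals.append(int(total))
        actions.append({a: sum(1 for r in rules if r.action == a) for a in (0, 1)})
        dc_rows.append(counts)
        prob_rows.append(probs)
        if keep_results is not None:
            keep_results.append(result)
    return UsageReport(
        variables=names,
        seeds=seeds,
        total_rules=totals,
        per_action_counts=actions,
        dont_care=np.vstack(dc_rows),
        prob=np.vstack(prob_rows),
    )


def rules_to_records(
    rules: list[Classifier], ranges: pd.DataFrame, names: list[str]
) -> list[dict]:
    """Flat export of a rule set with de-normalized intervals.

    Each record maps every variable to ``[low, high)`` on the original
    measurement scale, or the literal token ``"#"`` for a full-range
    (don't care) locus.
    """
    lo = ranges["min"].to_numpy(dtype=float)
    span = np.where(
        ranges["constant"].to_numpy(),
        0.0,
        ranges["max"].to_numpy(dtype=float) - lo,
    )
    out = []
    for cl in rules:
        cond = {}
        for i, pred in enumerate(cl.condition):
            if is_dont_care(pred):
                cond[names[i]] = "#"
            else:
                cond[names[i]] = [
                    float(lo[i] + pred.lower * span[i]),
                    float(lo[i] + pred.upper * span[i]),
                ]
        out.append(
            {
                "condition": cond,
                "action": cl.action,
                "prediction": cl.prediction,
                "prediction_error": cl.prediction_error,
                "fitness": cl.fitness,
                "numerosity": cl.numerosity,
                "experience": cl.experience,
            }
        )
    return out
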