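"""Statistical evaluation: Mann–Whitney U, ROC/AUC and group summaries.

The two outcome groups are of very unequal size, so between-group
differences use the nonparametric Mann–Whitney U test (two-tailed,
significance at p < 0.01).  Discriminative ability is summarised as the
area under the ROC curve, computed by the rank (pair-counting)
formulation that makes AUC the normalized Mann–Whitney statistic.  The
trained model is scored by the difference of its prediction-array
payoffs for the two actions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort
from .population import Population
from .xcsr import XCSRParams, predict_scores

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "auc",
    "roc_curve",
    "model_roc",
    "ModelROC",
    "group_summary",
]

SIGNIFICANCE_LEVEL = 0.01
EXACT_MAX_N = 8


@dataclass(frozen=True)
class GroupComparison:
    """One variable's between-group comparison row."""

    variable: str
    kind: str
    failure_stats: tuple[float, float] | dict
    success_stats: tuple[float, float] | dict
    total_stats: tuple[float, float] | dict
    U: float
    p_two_tailed: float
    auc: float            # oriented: max(a, 1 - a)
    direction: str        # which group tends to score higher
    significant: bool     # p < 0.01


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample ``a``: concordant pairs (a > b) plus half the ties."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-tailed exact p by enumerating all group assignments.

    Enumerates every way of splitting the pooled sample into groups of
    the observed sizes (handles ties exactly); p is the probability of
    a U at least as far from the null mean n1*n2/2 as observed.
    """
    pooled = np.concatenate([a, b])
    n1 = a.size
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mu = n1 * b.size / 2.0
    dev = abs(u_obs - mu) - 1e-12
    hits = 0
    for pick in combinations(range(n), n1):
        u = ranks[list(pick)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mu) >= dev:
            hits += 1
    return hits / comb(n, n1)


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Mann–Whitney U of ``sample_a`` with a two-tailed p value.

    U counts pairs where a > b (ties count one half).  For both sample
    sizes at most 8 the p value is an exact enumeration over group
    assignments (valid under ties); otherwise the normal approximation
    with tie-corrected variance and continuity correction is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    u = _u_statistic(a, b)
    if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N:
        return u, _exact_p(a, b, u)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           use_continuity=True, method="asymptotic")
    return u, float(res.pvalue)


def auc(scores, labels) -> float:
    """Pair-counting AUC: (concordant + 0.5 * tied) / (n1 * n0).

    ``labels`` are binary; a positive (label 1) scoring above a
    negative is concordant.  Equals the normalized Mann–Whitney U of
    the positive-class scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=np.int64)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return _u_statistic(pos, neg) / (pos.size * neg.size)


def roc_curve(scores, labels) -> pd.DataFrame:
    """ROC points (fpr, tpr, threshold) at every distinct score cut.

    A record is called positive when its score is >= the threshold;
    thresholds run from above the maximum score (0, 0) down to the
    minimum (1, 1).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=np.int64)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    last = np.r_[np.flatnonzero(np.diff(s_sorted)), s_sorted.size - 1]
    return pd.DataFrame(
        {
            "fpr": np.r_[0.0, fps[last] / n0],
            "tpr": np.r_[0.0, tps[last] / n1],
            "threshold": np.r_[np.inf, s_sorted[last]],
        }
    )


@dataclass
class ModelROC:
    auc: float
    curve: pd.DataFrame
    scores: np.ndarray
    n_abstained: int


def model_roc(pop: Population, X, y, params: XCSRParams) -> ModelROC:
    """ROC analysis of a trained population on normalized records.

    Scores are the prediction-array payoff difference
    PA(success) − PA(failure); a missing entry is imputed with the
    incorrect reward.  Raises when every record abstains (no matching
    rule for any action).
    """
    scores, _, abstain = predict_scores(pop, X, params)
    if abstain.all():
        raise ValueError("every record abstained: no rule matches anything")
    return ModelROC(
        auc=auc(scores, y),
        curve=roc_curve(scores, y),
        scores=scores,
        n_abstained=int(abstain.sum()),
    )


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    # sample SD (n-1 denominator), the clinical reporting convention
    return float(x.mean()), float(x.std(ddof=1)) if x.size > 1 else 0.0


def group_summary(cohort: Cohort) -> list[GroupComparison]:
    """Per-variable group comparison shaped like a clinical cohort table.

    Continuous variables get mean ± SD per group; discrete variables
    get per-code counts.  Every variable (discrete codes are numeric)
    gets U, two-tailed p, and an oriented AUC (max(a, 1-a), direction
    recorded).  Requires a complete-case cohort with both outcomes.
    """
    y = cohort.outcomes
    if len(set(y.tolist())) < 2:
        raise ValueError("outcome column is constant: one class absent")
    out: list[GroupComparison] = []
    for spec in cohort.schema:
        x = cohort.frame[spec.name].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"{spec.name}: missing values, run exclude_incomplete first")
        fail = x[y == 0]
        succ = x[y == 1]
        u, p = mann_whitney_u(fail, succ)
        raw = auc(x, y)
        oriented = max(raw, 1.0 - raw)
        direction = "success_higher" if raw >= 0.5 else "failure_higher"
        if spec.is_continuous:
            stats_f: tuple | dict = _mean_sd(fail)
            stats_s: tuple | dict = _mean_sd(succ)
            stats_t: tuple | dict = _mean_sd(x)
        else:
            codes = sorted(set(x.tolist()))
            stats_f = {c: int((fail == c).sum()) for c in codes}
            stats_s = {c: int((succ == c).sum()) for c in codes}
            stats_t = {c: int((x == c).sum()) for c in codes}
        out.append(
            GroupComparison(
                variable=spec.name,
                kind=spec.kind,
                failure_stats=stats_f,
                success_stats=stats_s,
                total_stats=stats_t,
                U=u,
                p_two_tailed=p,
                auc=oriented,
                direction=direction,
                significant=p < SIGNIFICANCE_LEVEL,
            )
        )
    return out


def group_summary_frame(cohort: Cohort) -> pd.DataFrame:
    """CSV-ready rendering of :func:`group_summary`."""

    def fmt(stats) -> str:
        if isinstance(stats, dict):
            return "; ".join(f"{c:g}: {n}" for c, n in stats.items())
        m, s = stats
        return f"{m:.2f} ± {s:.2f}"

    rows = [
        {
            "variable": g.variable,
            "kind": g.kind,
            "failure": fmt(g.failure_stats),
            "success": fmt(g.success_stats),
            "total": fmt(g.total_stats),
            "U": g.U,
            "p_two_tailed": g.p_two_tailed,
            "auc": g.auc,
            "direction": g.direction,
            "significant_p<0.01": "*" if g.significant else "",
        }
        for g in group_summary(cohort)
    ]
    return pd.DataFrame(rows)
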