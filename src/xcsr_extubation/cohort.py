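"""Synthetic extubation-cohort generation.

The original EMR data are not public, so every downstream stage is
exercised on synthetic cohorts that reproduce the published two-group
structure: outcome-conditional truncated normals for continuous
variables, empirical code frequencies for discrete ones, optional
missing-value injection (emulating the 262-recruited / 34-excluded /
228-analysed flow) and an optional *planted-rule* mode in which the
outcome is a known deterministic interval rule over a chosen feature
subset — the ground truth used to validate rule-based feature recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .schema import VariableSpec, default_schema, variable_names

__all__ = [
    "GeneratorConfig",
    "Cohort",
    "generate",
    "exclude_incomplete",
    "default_planted_rule",
    "evaluate_rule",
    "OUTCOME_COLUMN",
]

logger = logging.getLogger(__name__)

OUTCOME_COLUMN = "outcome"

#: (variable name, (low, high)) conjuncts; a record satisfies the rule iff
#: low <= x < high for every conjunct.
Conjunct = tuple[str, tuple[float, float]]


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one synthetic cohort draw.

    Defaults emulate the published recruitment: 262 patients, 34 with
    missing data, and a 40/228 failure fraction among complete cases.
    """

    seed: int
    n_total: int = 262
    failure_fraction: float = 40 / 228
    mode: str = "table"
    planted_features: tuple[str, ...] = ()
    planted_rule: tuple[Conjunct, ...] = ()
    label_noise: float = 0.0
    n_missing_records: int = 34

    def __post_init__(self) -> None:
        if self.mode not in ("table", "planted_rule"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.failure_fraction < 1:
            raise ValueError("failure_fraction must be in (0, 1)")
        if not 0 <= self.label_noise < 1:
            raise ValueError("label_noise must be in [0, 1)")
        if self.n_missing_records < 0 or self.n_missing_records > self.n_total:
            raise ValueError("n_missing_records must be in [0, n_total]")
        if self.mode == "planted_rule" and not self.planted_rule:
            raise ValueError("planted_rule mode requires a nonempty planted_rule")
        if self.mode == "table" and self.planted_rule:
            raise ValueError("planted_rule given but mode is 'table'")

    def with_rule(self, rule: list[Conjunct]) -> "GeneratorConfig":
        return replace(
            self,
            mode="planted_rule",
            planted_rule=tuple(rule),
            planted_features=tuple(v for v, _ in rule),
        )


@dataclass
class Cohort:
    """An ordered patient table plus its variable schema.

    ``frame`` holds one row per patient: the 40 predictor columns in
    schema order followed by the binary ``outcome`` column (0 failure /
    1 success).  Missing values are NaN.
    """

    frame: pd.DataFrame
    schema: list[VariableSpec]

    def __post_init__(self) -> None:
        expected = variable_names(self.schema) + [OUTCOME_COLUMN]
        if list(self.frame.columns) != expected:
            raise ValueError("cohort frame columns do not match schema")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def features(self) -> pd.DataFrame:
        return self.frame[variable_names(self.schema)]

    @property
    def outcomes(self) -> np.ndarray:
        return self.frame[OUTCOME_COLUMN].to_numpy(dtype=np.int64)

    @property
    def n_missing(self) -> int:
        return int(self.features.isna().any(axis=1).sum())

    def to_csv(self, path) -> None:
        """Write the cohort; missing values become empty fields."""
        self.frame.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path, schema: list[VariableSpec] | None = None) -> "Cohort":
        schema = schema if schema is not None else default_schema()
        frame = pd.read_csv(path)
        frame[OUTCOME_COLUMN] = frame[OUTCOME_COLUMN].astype(np.int64)
        return cls(frame, schema)


def _calibrated_loc(spec: VariableSpec, mean: float, sd: float) -> float:
    """Location of a truncated normal whose *truncated* mean is ``mean``.

    With heavy one-sided truncation (several SponVT variables have SD
    comparable to the mean and a hard floor at 0) a truncated
    N(mean, sd) would be visibly biased upward; solving for the location
    keeps the sampled group means on the published values.  The printed
    SD is used as the scale parameter.
    """
    lo, hi = spec.bounds()
    if lo <= mean - 6 * sd and hi >= mean + 6 * sd:
        return mean  # truncation numerically irrelevant

    def gap(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    span = 8 * sd
    return optimize.brentq(gap, mean - span, mean + span, xtol=1e-10 * max(1.0, sd))


def _sample_continuous(
    spec: VariableSpec, mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0 or size == 0:
        return np.full(size, mean)
    lo, hi = spec.bounds()
    loc = _calibrated_loc(spec, mean, sd)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _sample_discrete(
    counts: dict[float, int], size: int, rng: np.random.Generator
) -> np.ndarray:
    codes = np.array(sorted(counts), dtype=float)
    freq = np.array([counts[c] for c in sorted(counts)], dtype=float)
    return rng.choice(codes, size=size, p=freq / freq.sum())


def evaluate_rule(frame: pd.DataFrame, rule: tuple[Conjunct, ...]) -> np.ndarray:
    """1 where every conjunct holds (low <= x < high), else 0."""
    ok = np.ones(len(frame), dtype=bool)
    for var, (low, high) in rule:
        if var not in frame.columns:
            raise KeyError(f"planted rule references unknown variable {var!r}")
        x = frame[var].to_numpy(dtype=float)
        ok &= (low <= x) & (x < high)
    return ok.astype(np.int64)


def default_planted_rule(
    features: list[str],
    schema: list[VariableSpec] | None = None,
    positive_fraction: float = 0.5,
    failure_fraction: float = 40 / 228,
) -> list[Conjunct]:
    """Build an interval rule over ``features`` with a workable class balance.

    Each conjunct spans the central mass ``positive_fraction**(1/k)`` of
    the variable's pooled marginal (normal approximation on the mixture
    moments), so the conjunction labels roughly ``positive_fraction`` of
    records positive regardless of how many features are planted.
    """
    schema = schema if schema is not None else default_schema()
    by_name = {v.name: v for v in schema}
    k = len(features)
    if k == 0:
        raise ValueError("planted rule needs at least one feature")
    central = positive_fraction ** (1.0 / k)
    z = stats.norm.ppf(0.5 + central / 2.0)
    rule: list[Conjunct] = []
    for name in features:
        if name not in by_name:
            raise KeyError(f"unknown variable {name!r}")
        m, s = by_name[name].pooled_moments(failure_fraction)
        rule.append((name, (float(m - z * s), float(m + z * s))))
    return rule


def generate(config: GeneratorConfig, schema: list[VariableSpec] | None = None) -> Cohort:
    """Draw a synthetic cohort.

    Table mode: the outcome is drawn first with ``failure_fraction``
    (success probability ``1 - failure_fraction``), then each variable
    from its outcome group's distribution.  Planted-rule mode: each
    variable is drawn independently from its pooled marginal mixture and
    the outcome is the deterministic rule evaluation, flipped with
    probability ``label_noise``.  Exactly ``n_missing_records`` records
    then receive one missing value in a non-planted variable.
    """
    schema = schema if schema is not None else default_schema()
    names = variable_names(schema)
    for var, _ in config.planted_rule:
        if var not in names:
            raise KeyError(f"planted rule references unknown variable {var!r}")

    rng = np.random.default_rng(config.seed)
    n = config.n_total
    data: dict[str, np.ndarray] = {}

    if config.mode == "table":
        outcome = (rng.random(n) >= config.failure_fraction).astype(np.int64)
        for spec in schema:
            col = np.empty(n)
            for grp in (0, 1):
                idx = np.flatnonzero(outcome == grp)
                if spec.is_continuous:
                    m, s = spec.group_params(grp)
                    col[idx] = _sample_continuous(spec, m, s, idx.size, rng)
                else:
                    col[idx] = _sample_discrete(spec.group_counts(grp), idx.size, rng)
            data[spec.name] = col
    else:
        # marginal draws: latent group per record *and variable*, so the
        # planted rule is the only source of feature/outcome association
        for spec in schema:
            grp = (rng.random(n) >= config.failure_fraction).astype(np.int64)
            col = np.empty(n)
            for g in (0, 1):
                idx = np.flatnonzero(grp == g)
                if spec.is_continuous:
                    m, s = spec.group_params(g)
                    col[idx] = _sample_continuous(spec, m, s, idx.size, rng)
                else:
                    col[idx] = _sample_discrete(spec.group_counts(g), idx.size, rng)
            data[spec.name] = col

    frame = pd.DataFrame(data, columns=names)

    if config.mode == "planted_rule":
        outcome = evaluate_rule(frame, config.planted_rule)
        if config.label_noise > 0:
            flip = rng.random(n) < config.label_noise
            outcome = np.where(flip, 1 - outcome, outcome)

    # inject missing values in non-planted variables only
    if config.n_missing_records:
        eligible = [v for v in names if v not in config.planted_features]
        if not eligible:
            raise ValueError("no non-planted variable available for missingness")
        rows = rng.choice(n, size=config.n_missing_records, replace=False)
        cols = rng.choice(len(eligible), size=config.n_missing_records, replace=True)
        for r, c in zip(rows, cols):
            frame.iat[int(r), names.index(eligible[int(c)])] = np.nan

    frame[OUTCOME_COLUMN] = outcome
    return Cohort(frame, schema)


def exclude_incomplete(cohort: Cohort) -> Cohort:
    """Complete-case filter: drop every record with any missing value.

    Original record order is preserved; the excluded/retained counts are
    logged (the published flow excluded 34 of 262 recruits, leaving 228).
    """
    keep = ~cohort.features.isna().any(axis=1)
    retained = cohort.frame.loc[keep].reset_index(drop=True)
    logger.info(
        "complete-case filter: %d retained, %d excluded of %d records",
        int(keep.sum()), int((~keep).sum()), len(cohort),
    )
    return Cohort(retained, cohort.schema)
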