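"""Clinical variable schema for the extubation cohort.

The cohort consists of 40 predictor variables per patient: 19 clinical
variables (demographics, severity scales, ventilator information,
pre-SBT hemodynamics, maximal inspiratory pressure, disease history) and
21 variables acquired during a spontaneous breathing trial (SBT) —
hemodynamics and ventilation sampled at the 1st, 30th, 60th and 90th
minute.  The binary outcome encodes extubation failure (0, respiratory
failure or death within 48 h of tube removal) versus success (1).

Each :class:`VariableSpec` carries the group-conditional summary
statistics of the published 228-patient sample (40 failures / 188
successes): mean ± SD for continuous variables, per-category counts for
discrete ones.  These parameters drive the synthetic cohort generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "VariableSpec",
    "default_schema",
    "N_FAILURE",
    "N_SUCCESS",
    "variable_names",
]

#: Published group sizes of the analysed sample.
N_FAILURE = 40
N_SUCCESS = 188


@dataclass(frozen=True)
class VariableSpec:
    """One predictor variable and its group-conditional parameters.

    Parameters
    ----------
    name : str
        Variable identifier (column name in cohort CSV files).
    kind : {"continuous", "binary", "categorical"}
        Sampling family.  Binary and categorical variables are emitted
        as numeric codes, since the learner consumes all 40 variables
        as real-valued inputs.
    unit : str
        Measurement unit ("a.u." for dimensionless codes/scales).
    failure_mean, failure_sd, success_mean, success_sd : float
        Group-conditional mean and SD (continuous kinds only).
    failure_counts, success_counts : dict[float, int]
        Category code → patient count per outcome group (discrete kinds).
    lower_bound, upper_bound : float
        Physiological truncation bounds for sampling.
    """

    name: str
    kind: str
    unit: str = "a.u."
    failure_mean: float | None = None
    failure_sd: float | None = None
    success_mean: float | None = None
    success_sd: float | None = None
    failure_counts: dict[float, int] = field(default_factory=dict)
    success_counts: dict[float, int] = field(default_factory=dict)
    lower_bound: float | None = None
    upper_bound: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "continuous":
            for sd in (self.failure_sd, self.success_sd):
                if sd is None or sd < 0:
                    raise ValueError(f"{self.name}: sd must be >= 0")
            lo, hi = self.bounds()
            if not lo < hi:
                raise ValueError(f"{self.name}: lower_bound must be < upper_bound")
        else:
            for counts, size in (
                (self.failure_counts, N_FAILURE),
                (self.success_counts, N_SUCCESS),
            ):
                if counts and sum(counts.values()) != size:
                    raise ValueError(
                        f"{self.name}: counts sum to {sum(counts.values())}, "
                        f"expected group size {size}"
                    )

    @property
    def is_continuous(self) -> bool:
        return self.kind == "continuous"

    def bounds(self) -> tuple[float, float]:
        """Truncation bounds: pooled mean ± 4 SD across groups, clipped at 0.

        All continuous quantities in this schema (ages, pressures, rates,
        volumes, saturations, scale scores) are inherently nonnegative,
        so the lower bound is never allowed below zero.
        """
        if not self.is_continuous:
            codes = sorted(set(self.failure_counts) | set(self.success_counts))
            return float(codes[0]), float(codes[-1])
        if self.lower_bound is not None and self.upper_bound is not None:
            return self.lower_bound, self.upper_bound
        lo = min(
            self.failure_mean - 4.0 * self.failure_sd,
            self.success_mean - 4.0 * self.success_sd,
        )
        hi = max(
            self.failure_mean + 4.0 * self.failure_sd,
            self.success_mean + 4.0 * self.success_sd,
        )
        return max(0.0, lo), hi

    def group_params(self, outcome: int) -> tuple[float, float]:
        """(mean, sd) for outcome group (0 = failure, 1 = success)."""
        if outcome == 0:
            return self.failure_mean, self.failure_sd
        return self.success_mean, self.success_sd

    def group_counts(self, outcome: int) -> dict[float, int]:
        return self.failure_counts if outcome == 0 else self.success_counts

    def pooled_moments(self, failure_fraction: float) -> tuple[float, float]:
        """Mean and SD of the two-group mixture marginal.

        Used to place planted-rule intervals on a variable's pooled
        distribution.  Discrete variables use the empirical code
        frequencies.
        """
        w = failure_fraction
        if self.is_continuous:
            m = w * self.failure_mean + (1 - w) * self.success_mean
            ex2 = w * (self.failure_sd**2 + self.failure_mean**2) + (1 - w) * (
                self.success_sd**2 + self.success_mean**2
            )
            return m, max(ex2 - m * m, 0.0) ** 0.5
        total = {}
        for counts, size in (
            (self.failure_counts, N_FAILURE),
            (self.success_counts, N_SUCCESS),
        ):
            for code, cnt in counts.items():
                total[code] = total.get(code, 0.0) + (
                    w * cnt / size if counts is self.failure_counts else (1 - w) * cnt / size
                )
        m = sum(c * p for c, p in total.items())
        v = sum((c - m) ** 2 * p for c, p in total.items())
        return m, v**0.5


def _cont(name, unit, fm, fsd, sm, ssd):
    return VariableSpec(
        name, "continuous", unit,
        failure_mean=fm, failure_sd=fsd, success_mean=sm, success_sd=ssd,
    )


def _disc(name, kind, unit, fcounts, scounts):
    return VariableSpec(
        name, kind, unit, failure_counts=fcounts, success_counts=scounts
    )


def default_schema() -> list[VariableSpec]:
    """The 40-variable extubation schema with published group parameters.

    Ordered as in the source tables: clinical variables first, then the
    SBT-acquired variables.  Gender codes 1=male/2=female; histories
    1=yes/0=no; Endo_size is the endotracheal tube diameter in mm;
    Reason_using_MV is a two-level code.
    """
    return [
        # --- basic information -------------------------------------------
        _disc("Gender", "categorical", "a.u.", {1.0: 18, 2.0: 22}, {1.0: 118, 2.0: 70}),
        _cont("Age", "year", 72.62, 14.05, 67.53, 15.76),
        _cont("Height", "cm", 158.50, 9.05, 162.60, 8.56),
        _cont("BW", "kg", 60.73, 13.22, 60.94, 14.54),
        _cont("IBW", "kg", 55.51, 6.36, 58.27, 6.03),
        # --- severity scales ---------------------------------------------
        _cont("APACHEII", "a.u.", 24.43, 8.19, 21.29, 8.33),
        _cont("GCS_enter_ICU", "a.u.", 6.30, 3.41, 6.84, 3.52),
        _cont("GCS_before_SBT", "a.u.", 9.55, 2.00, 10.10, 1.63),
        # --- mechanical ventilator ---------------------------------------
        # published success counts (31 + 156) sum to 187, one short of the
        # group size; the pooled totals (40/188) imply 157 for the 7.5 mm code
        _disc("Endo_size", "categorical", "mm", {7.0: 9, 7.5: 31}, {7.0: 31, 7.5: 157}),
        # NB: the published pooled cuff_leak mean (283.25) lies outside both
        # group means (203.47 / 245.65); only the group values are used here.
        _cont("cuff_leak", "mL", 203.47, 124.36, 245.65, 107.31),
        _disc("Reason_using_MV", "categorical", "a.u.", {1.0: 21, 2.0: 19}, {1.0: 93, 2.0: 95}),
        # --- hemodynamics before SBT -------------------------------------
        _cont("SBP_before_SBT", "mmHg", 144.25, 26.34, 140.94, 26.47),
        _cont("DBP_before_SBT", "mmHg", 71.40, 17.39, 70.89, 15.86),
        _cont("HR_before_SBT", "bpm", 92.95, 16.96, 88.15, 15.91),
        _cont("SpO2_before_SBT", "%", 97.50, 2.18, 98.22, 1.87),
        # --- ventilation --------------------------------------------------
        _cont("Pimax", "cmH2O", 33.25, 11.99, 34.82, 12.19),
        # --- disease history ----------------------------------------------
        _disc("HX_Res", "binary", "a.u.", {1.0: 12, 0.0: 28}, {1.0: 44, 0.0: 144}),
        # published failure counts (30 yes / 20 no) sum to 50; the pooled
        # totals (134 yes / 94 no of 228) imply 30 yes / 10 no for n=40
        _disc("HX_CV", "binary", "a.u.", {1.0: 30, 0.0: 10}, {1.0: 104, 0.0: 84}),
        _disc("HX_NM", "binary", "a.u.", {1.0: 4, 0.0: 36}, {1.0: 31, 0.0: 157}),
        # --- SBT ----------------------------------------------------------
        _cont("SBT_times", "a.u.", 2.58, 1.41, 2.49, 1.49),
        _cont("m1_HR", "bpm", 94.15, 16.28, 89.07, 15.77),
        _cont("m1_SpO2", "%", 97.70, 2.29, 98.02, 2.13),
        _cont("m30_HR", "bpm", 93.90, 15.97, 88.69, 17.55),
        _cont("m30_SpO2", "%", 97.40, 3.10, 97.71, 2.46),
        _cont("m60_HR", "bpm", 96.40, 17.04, 88.12, 20.33),
        _cont("m60_SpO2", "%", 97.58, 2.77, 96.12, 12.47),
        _cont("m90_HR", "bpm", 92.17, 21.86, 85.94, 20.36),
        _cont("m90_SpO2", "%", 87.78, 29.73, 92.12, 23.11),
        _cont("m1_VE", "L", 7.93, 2.97, 7.94, 2.56),
        _cont("m1_SponVT", "mL", 420.40, 206.83, 463.26, 222.54),
        _cont("m1_RR", "bpm", 19.60, 6.89, 18.73, 6.61),
        _cont("m30_VE", "L", 7.53, 2.46, 7.90, 2.78),
        _cont("m30_SponVT", "mL", 442.27, 244.51, 531.98, 706.51),
        _cont("m30_RR", "bpm", 18.65, 6.19, 17.37, 5.68),
        _cont("m60_VE", "L", 8.20, 3.46, 7.84, 2.62),
        _cont("m60_SponVT", "mL", 451.43, 208.80, 472.49, 174.87),
        _cont("m60_RR", "bpm", 18.87, 6.22, 17.57, 6.17),
        _cont("m90_VE", "L", 7.65, 2.63, 7.81, 2.45),
        _cont("m90_SponVT", "mL", 466.93, 191.02, 478.64, 187.76),
        _cont("m90_RR", "bpm", 17.65, 4.01, 17.52, 6.12),
    ]


def variable_names(schema: list[VariableSpec] | None = None) -> list[str]:
    return [v.name for v in (schema if schema is not None else default_schema())]
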