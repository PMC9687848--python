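"""End-to-end orchestration: generate → exclude → train(×runs) → reports.

One :class:`RunConfig` fully determines a run; everything written to
the output directory (cohort CSVs, per-run rule exports and learning
curves, the usage report, the group-comparison table, ROC points and a
manifest with the config hash and stage counts) is regenerable from the
serialized config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, GeneratorConfig, exclude_incomplete, generate
from .schema import default_schema
from .stats import group_summary_frame, model_roc
from .usage import (
    StableRuleCriteria,
    UsageReport,
    extract_stable_rules,
    multi_run_usage,
    rules_to_records,
)
from .xcsr import TrainResult, XCSRParams, normalize

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a reproducible pipeline run."""

    generator: GeneratorConfig
    xcsr: XCSRParams = XCSRParams()
    n_runs: int = 10
    stable: StableRuleCriteria = StableRuleCriteria()
    output_dir: str = "xcsr_run"
    log_level: str = "INFO"
    seeds: tuple[int, ...] | None = None  # default: 1..n_runs

    def run_seeds(self) -> list[int]:
        return list(self.seeds) if self.seeds else list(range(1, self.n_runs + 1))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["planted_rule"] = [
            [v, float(lo), float(hi)] for v, (lo, hi) in self.generator.planted_rule
        ]
        d["generator"]["planted_features"] = list(self.generator.planted_features)
        d["seeds"] = self.run_seeds()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = dict(d.pop("generator"))
        rule = tuple(
            (v, (float(lo), float(hi))) for v, lo, hi in gen.pop("planted_rule", [])
        )
        gen["planted_rule"] = rule
        gen["planted_features"] = tuple(gen.get("planted_features") or (v for v, _ in rule))
        xcsr = XCSRParams(**d.pop("xcsr", {}))
        stable = StableRuleCriteria(**d.pop("stable", {}))
        seeds = d.pop("seeds", None)
        return cls(
            generator=GeneratorConfig(**gen),
            xcsr=xcsr,
            stable=stable,
            seeds=tuple(seeds) if seeds else None,
            **d,
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full protocol and return the run manifest.

    Stages: cohort generation, complete-case exclusion, normalization,
    ``n_runs`` independently seeded trainings, stable-rule extraction
    with the usage report, and the statistical reports (group summary,
    per-run model ROC).  Any stage failure aborts with the stage name;
    artifacts written so far are preserved.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))

    manifest: dict = {
        "config_hash": config.config_hash(),
        "seeds": config.run_seeds(),
        "counts": {},
        "runs": {},
    }

    schema = default_schema()

    cohort = _stage("generate")(generate)(config.generator, schema)
    cohort.to_csv(out / "cohort_full.csv")
    complete = _stage("exclude_incomplete")(exclude_incomplete)(cohort)
    complete.to_csv(out / "cohort.csv")
    manifest["counts"].update(
        {
            "n_generated": len(cohort),
            "n_excluded": len(cohort) - len(complete),
            "n_retained": len(complete),
            "n_failure": int((complete.outcomes == 0).sum()),
            "n_success": int((complete.outcomes == 1).sum()),
        }
    )

    Xn, ranges = _stage("normalize")(normalize)(complete.features)
    ranges.to_csv(out / "ranges.csv")
    X = Xn.to_numpy(dtype=float)
    y = complete.outcomes
    names = [v.name for v in schema]

    results: list[TrainResult] = []
    report: UsageReport = _stage("train_and_usage")(multi_run_usage)(
        complete, config.xcsr, n_runs=config.n_runs,
        seeds=config.run_seeds(), criteria=config.stable,
        keep_results=results,
    )
    report.to_frame().to_csv(out / "usage_report.csv", index=False)
    (out / "usage_report.json").write_text(
        json.dumps(
            {
                "variables": report.variables,
                "seeds": report.seeds,
                "total_rules": report.total_rules,
                "mean_prob_usage": report.mean.tolist(),
                "sd": report.sd.tolist(),
                "rank": report.rank.tolist(),
            },
            indent=2,
        )
    )
    report.dont_care_frame().to_csv(out / "dont_care_sorted.csv", index=False)

    for seed, result in zip(report.seeds, results):
        curve = pd.DataFrame(
            {
                "exploit_trial": np.arange(1, result.curve.size + 1),
                "windowed_accuracy": result.curve,
            }
        )
        curve.to_csv(out / f"curve_seed{seed}.csv", index=False)
        rules = extract_stable_rules(result.population, X, config.stable)
        records = rules_to_records(rules, ranges, names)
        (out / f"rules_seed{seed}.json").write_text(json.dumps(records, indent=2))
        _rules_csv(records, names).to_csv(out / f"rules_seed{seed}.csv", index=False)
        roc = _stage("model_roc")(model_roc)(result.population, X, y, config.xcsr)
        roc.curve.to_csv(out / f"roc_seed{seed}.csv", index=False)
        manifest["runs"][str(seed)] = {
            "stable_rules": len(rules),
            "rules_success": sum(1 for r in rules if r.action == 1),
            "rules_failure": sum(1 for r in rules if r.action == 0),
            "population_macro": result.population.n,
            "population_micro": result.population.micro_count,
            "final_windowed_accuracy": result.final_accuracy,
            "model_auc": roc.auc,
            "n_abstained": roc.n_abstained,
        }

    summary = _stage("group_summary")(group_summary_frame)(complete)
    summary.to_csv(out / "group_summary.csv", index=False)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", out)
    return manifest


def _rules_csv(records: list[dict], names: list[str]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            name: (
                "#"
                if rec["condition"][name] == "#"
                else f"[{rec['condition'][name][0]:.4g}, {rec['condition'][name][1]:.4g})"
            )
            for name in names
        }
        row.update(
            action=rec["action"],
            prediction=rec["prediction"],
            prediction_error=rec["prediction_error"],
            fitness=rec["fitness"],
            numerosity=rec["numerosity"],
            experience=rec["experience"],
        )
        rows.append(row)
    return pd.DataFrame(rows)
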