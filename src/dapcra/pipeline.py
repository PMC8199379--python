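"""End-to-end orchestration: simulate → summarise → impute → assess.

Each stage is a thin function over the library modules; ``run_pipeline``
chains them, writes every intermediate and final table as commented
CSV, and records a JSON manifest (seed, inputs, participant counts,
exclusion reasons) so a rerun with identical inputs and seed
reproduces identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analytes import ANALYTE_ORDER
from .censored import CensoredVector, km_summary, normalize_creatinine
from .io import (
    load_synthetic_parent_table,
    read_cohort,
    read_parent_table,
    write_cohort,
    write_manifest,
    write_table,
)
from .qrilc import ImputationConfig, impute_cohort
from .risk import RiskConfig, assess_cohort, classify_exceedance, cohort_dose_summary
from .synthetic import apply_censoring, default_config, generate_cohort

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "summarise_cohort",
    "rarely_detected_analytes",
]

SUMMARY_PROBS = (0.25, 0.5, 0.75, 0.95)

#: Analytes detected in at most this many participants are excluded
#: from imputation and summaries (too little signal to fit a tail).
DEFAULT_DETECTION_EXCLUSION_COUNT = 2


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    out_dir: Path
    seed: int = 0
    n_participants: int = 4456
    cohort_path: Path | None = None  # skip simulation, read this instead
    parent_table_path: Path | None = None  # default: bundled synthetic table
    risk: RiskConfig = field(default_factory=RiskConfig)
    imputation: ImputationConfig | None = None
    detection_exclusion_count: int = DEFAULT_DETECTION_EXCLUSION_COUNT


def cohort_vector(cohort: pd.DataFrame, analyte: str) -> CensoredVector:
    """Extract one analyte's censored vector from a cohort table."""
    return CensoredVector(
        cohort[analyte].to_numpy(dtype=float),
        cohort[f"{analyte}_censored"].to_numpy(dtype=bool),
        cohort[f"{analyte}_limit"].to_numpy(dtype=float),
    )


def rarely_detected_analytes(
    cohort: pd.DataFrame, max_detected: int = DEFAULT_DETECTION_EXCLUSION_COUNT
) -> set[str]:
    """Analytes whose detected count is at or below ``max_detected``."""
    out = set()
    for a in ANALYTE_ORDER:
        if f"{a}_censored" in cohort.columns:
            detected = int((cohort[f"{a}_censored"] == 0).sum())
            if detected <= max_detected:
                out.add(a)
    return out


def summarise_cohort(
    cohort: pd.DataFrame,
    probs=SUMMARY_PROBS,
    excluded: set[str] | frozenset[str] = frozenset(),
    completed: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Analyte-by-statistic summary, crude and creatinine-normalised.

    Detection rates and Kaplan-Meier quantiles per analyte; quantiles
    inside the censored mass are NaN.  When a ``completed``
    (post-imputation) table is supplied, arithmetic mean and SD of the
    completed data are reported (the convention for such panels);
    otherwise the KM mean/SD are shown.  Rarely detected analytes in
    ``excluded`` get only a detection rate.
    """
    rows = []
    cr = cohort["urinary_creatinine"].to_numpy(dtype=float)
    for a in ANALYTE_ORDER:
        if a not in cohort.columns:
            continue
        for block, scale in (("crude", np.ones_like(cr)), ("creatinine", cr)):
            vec = cohort_vector(cohort, a)
            row = {"analyte": a, "block": block, "n": len(vec)}
            flags = vec.censored
            if block == "creatinine":
                values = normalize_creatinine(vec.values, cr)
                limits = normalize_creatinine(vec.limits, cr)
                vec = CensoredVector(values, flags, limits)
            row["detection_rate"] = float((~flags).mean())
            if a in excluded:
                rows.append(row)
                continue
            stats = km_summary(vec, probs)
            if completed is not None:
                comp = completed[a].to_numpy(dtype=float)
                if block == "creatinine":
                    comp = normalize_creatinine(comp, cr)
                row["mean"], row["sd"] = float(comp.mean()), float(comp.std(ddof=1))
            else:
                row["mean"], row["sd"] = stats.mean, stats.sd
            for p in probs:
                row[f"p{int(round(p * 100))}"] = stats.quantiles[p]
            rows.append(row)
    return pd.DataFrame(rows)


def _exclude_incomplete(cohort: pd.DataFrame):
    """Drop records unusable for dose reconstruction, with reasons."""
    exclusions = []
    keep = pd.Series(True, index=cohort.index)
    for col, reason in (
        ("urinary_creatinine", "missing or non-positive urinary creatinine"),
        ("body_weight", "missing or non-positive body weight"),
    ):
        bad = cohort[col].isna() | (cohort[col] <= 0)
        for idx in cohort.index[bad & keep]:
            exclusions.append(
                {"id": cohort.loc[idx, "id"] if "id" in cohort else idx,
                 "reason": reason}
            )
        keep &= ~bad
    return cohort.loc[keep].reset_index(drop=True), exclusions


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write all outputs under ``out_dir``.

    Outputs: ``cohort.csv`` (when simulated), ``summary.csv``
    (analyte-by-statistic table), ``completed_cohort.csv`` and
    ``imputation_audit.csv``, ``doses.csv`` (per participant),
    ``dose_summary.csv``, ``exceedance.csv`` and ``manifest.json``.
    Returns the in-memory results keyed by the same names.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed}
    inputs: dict = {"seed": config.seed}

    if config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path)
        inputs["cohort"] = str(config.cohort_path)
    else:
        syn = default_config(config.n_participants, config.seed)
        truth = generate_cohort(syn)
        cohort, _rates = apply_censoring(truth)
        inputs["cohort"] = f"simulated(n={config.n_participants})"
        write_cohort(cohort, out / "cohort.csv", meta)
    n_input = len(cohort)

    cohort, exclusions = _exclude_incomplete(cohort)
    excluded_analytes = rarely_detected_analytes(
        cohort, config.detection_exclusion_count
    )

    impute_cfg = config.imputation or ImputationConfig(seed=config.seed)
    completed, audit = impute_cohort(cohort, impute_cfg, excluded=excluded_analytes)
    write_cohort(completed, out / "completed_cohort.csv", meta)
    write_table(audit, out / "imputation_audit.csv", meta)

    summary = summarise_cohort(
        cohort, excluded=excluded_analytes, completed=completed
    )
    write_table(summary, out / "summary.csv", meta)

    parents = (
        load_synthetic_parent_table()
        if config.parent_table_path is None
        else read_parent_table(config.parent_table_path)
    )
    inputs["parent_table"] = str(config.parent_table_path or "bundled synthetic")
    doses = assess_cohort(
        completed, parents, config.risk,
        excluded=excluded_analytes | {"DEDTP"},
    )
    write_table(doses, out / "doses.csv", meta)
    dose_summary = cohort_dose_summary(doses)
    write_table(dose_summary, out / "dose_summary.csv", meta, index=True)
    exceedance = classify_exceedance(doses, config.risk)
    write_table(pd.DataFrame([exceedance]), out / "exceedance.csv", meta)

    write_manifest(
        out / "manifest.json",
        seed=config.seed,
        inputs=inputs,
        counts={
            "input": n_input,
            "after_exclusions": len(cohort),
            "assessed": len(doses),
        },
        exclusions=exclusions,
    )
    return {
        "cohort": cohort,
        "summary": summary,
        "completed": completed,
        "audit": audit,
        "doses": doses,
        "dose_summary": dose_summary,
        "exceedance": exceedance,
        "excluded_analytes": excluded_analytes,
    }
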