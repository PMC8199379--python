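"""Cumulative organophosphate dose equivalents from urinary DAP panels.

The chemical-mixture approach aggregates the dimethyl (DMs) and
diethyl (DEs) metabolite panels into daily molar excretions, maps them
back to parent-pesticide mass using release-weighted proportions and
relative potency factors (RPFs), and compares the resulting cumulative
dose equivalent ``D_cum`` (µg per kg body weight per day) against a
benchmark level.

Molar excretion over 24 h (per alkyl class)::

    µMol = (Σ_i C_i / MW_i) * (Cr_ref / Cr_conc)

with ``C_i`` the completed urinary concentration (ng/mL), ``MW_i`` the
metabolite's free-acid molecular weight (g/mol), ``Cr_ref`` the mean
daily urinary creatinine excretion (mg/day) and ``Cr_conc`` the
participant's urinary creatinine (mg/L): the creatinine ratio estimates
the 24-h urine volume in L/day, so the product is µmol/day.

Cumulative dose::

    D_cum = µMol_DM * Σ_{i∈DM} P_i MW_i RPF_i / BW
          + µMol_DE * Σ_{i∈DE} P_i MW_i RPF_i / BW

with ``P_i`` each parent pesticide's release-weighted share of its
class, ``MW_i`` the *parent* molecular weight, ``RPF_i`` its potency
relative to the index chemical (a BMDL₁₀ ratio) and ``BW`` body weight
in kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .analytes import AnalyteDefinition, default_analytes

__all__ = [
    "ParentOpp",
    "RiskConfig",
    "DoseResult",
    "molar_excretion",
    "release_weighted_proportions",
    "compute_rpf",
    "cumulative_dose",
    "assess_cohort",
    "classify_exceedance",
    "cohort_dose_summary",
]

MG_PER_DL_TO_MG_PER_L = 10.0


@dataclass(frozen=True)
class ParentOpp:
    """A parent organophosphate pesticide.

    ``bmdl10`` is the lower 95% confidence limit of the benchmark
    dose for 10% brain-cholinesterase inhibition (µg/kg/day);
    ``annual_release`` maps year to mass released (any consistent
    mass unit — only relative shares matter).
    """

    name: str
    molecular_weight: float
    bmdl10: float
    annual_release: Mapping[int, float]
    alkyl_class: Literal["dimethyl", "diethyl"]

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        if self.bmdl10 <= 0:
            raise ValueError("bmdl10 must be positive")
        if any(v < 0 for v in self.annual_release.values()):
            raise ValueError("annual releases must be non-negative")
        if self.alkyl_class not in ("dimethyl", "diethyl"):
            raise ValueError(f"unknown alkyl class {self.alkyl_class!r}")


@dataclass
class RiskConfig:
    """Assessment settings.

    ``cr_ref`` is the mean daily urinary creatinine excretion of the
    target population in mg/day; ``comparison_level`` is the dose
    (µg/kg/day) above which a participant is flagged, by default the
    index chemical's BMDL₁₀ with the margin of exposure already
    reflected in the benchmark; ``rpf_orientation`` selects whether
    the reference BMDL₁₀ sits in the numerator (default) or the
    denominator of the potency ratio.
    """

    cr_ref: float = 1050.0
    moe: float = 100.0
    reference_chemical: str = "fenitrothion"
    comparison_level: float = 13.0
    rpf_orientation: Literal["reference-over-chemical", "chemical-over-reference"] = (
        "reference-over-chemical"
    )
    sampling_year_weights: dict[int, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.cr_ref <= 0:
            raise ValueError("cr_ref must be positive")
        if self.moe < 1:
            raise ValueError("moe must be at least 1")
        if self.comparison_level <= 0:
            raise ValueError("comparison_level must be positive")
        if self.sampling_year_weights:
            total = sum(self.sampling_year_weights.values())
            if abs(total - 1.0) > 1e-8:
                raise ValueError("sampling year weights must sum to 1")


@dataclass
class DoseResult:
    """Per-participant cumulative dose equivalents (µg/kg/day)."""

    id: str
    umol_dm: float
    umol_de: float
    d_cum_dm: float
    d_cum_de: float
    d_cum: float
    exceeds: bool


def molar_excretion(
    concentrations: Mapping[str, float],
    cr_conc_mg_per_l: float,
    cr_ref: float,
    alkyl_class: Literal["dimethyl", "diethyl"],
    analytes: Mapping[str, AnalyteDefinition] | None = None,
    excluded: Iterable[str] = ("DEDTP",),
) -> float:
    """Total micromoles of one metabolite class excreted over 24 h.

    ``concentrations`` maps analyte code to completed concentration in
    ng/mL; ``cr_conc_mg_per_l`` is urinary creatinine in mg/L.
    """
    if cr_conc_mg_per_l <= 0:
        raise ValueError("urinary creatinine concentration must be positive")
    if cr_ref <= 0:
        raise ValueError("cr_ref must be positive")
    analytes = analytes or default_analytes()
    excluded = set(excluded)
    total = 0.0
    for code, c in concentrations.items():
        if code in excluded or code not in analytes:
            continue
        a = analytes[code]
        if a.alkyl_class != alkyl_class:
            continue
        if c < 0:
            raise ValueError(f"negative concentration for {code}")
        total += c / a.molecular_weight  # ng/mL / (g/mol) = µmol/L
    return total * (cr_ref / cr_conc_mg_per_l)  # × L/day


def release_weighted_proportions(
    parents: Iterable[ParentOpp],
    year_weights: Mapping[int, float],
) -> dict[str, float]:
    """Release-weighted share ``P_i`` of each parent within its class.

    Each parent's release is averaged over years with the fraction of
    the cohort sampled in that year as weight, then normalised within
    its alkyl class so per-class shares sum to one.
    """
    total_w = sum(year_weights.values())
    if abs(total_w - 1.0) > 1e-8:
        raise ValueError("year weights must sum to 1")
    parents = list(parents)
    weighted = {
        p.name: sum(p.annual_release.get(y, 0.0) * w for y, w in year_weights.items())
        for p in parents
    }
    shares: dict[str, float] = {}
    for cls in ("dimethyl", "diethyl"):
        members = [p for p in parents if p.alkyl_class == cls]
        if not members:
            continue
        denom = sum(weighted[p.name] for p in members)
        if denom <= 0:
            raise ValueError(f"all-zero weighted release in class {cls!r}")
        for p in members:
            shares[p.name] = weighted[p.name] / denom
    return shares


def compute_rpf(
    parent: ParentOpp,
    reference: ParentOpp,
    orientation: str = "reference-over-chemical",
) -> float:
    """Relative potency factor of ``parent`` against the index chemical.

    Default orientation puts the reference benchmark in the numerator,
    so a parent with a *lower* BMDL₁₀ (more potent) gets an RPF above
    one; the inverted convention is selectable for sensitivity checks.
    """
    if parent.bmdl10 <= 0 or reference.bmdl10 <= 0:
        raise ValueError("BMDL10 values must be positive")
    if orientation == "reference-over-chemical":
        return reference.bmdl10 / parent.bmdl10
    if orientation == "chemical-over-reference":
        return parent.bmdl10 / reference.bmdl10
    raise ValueError(f"unknown RPF orientation {orientation!r}")


def _class_factor(
    parents: list[ParentOpp],
    proportions: Mapping[str, float],
    rpfs: Mapping[str, float],
    cls: str,
) -> float:
    """Σ P_i · MW_i · RPF_i over the parents of one alkyl class."""
    factor = 0.0
    for p in parents:
        if p.alkyl_class != cls:
            continue
        if p.name not in proportions or p.name not in rpfs:
            raise KeyError(f"missing proportion or RPF for parent {p.name!r}")
        factor += proportions[p.name] * p.molecular_weight * rpfs[p.name]
    return factor


def cumulative_dose(
    umol_dm: float,
    umol_de: float,
    body_weight: float,
    parents: Iterable[ParentOpp],
    proportions: Mapping[str, float],
    rpfs: Mapping[str, float],
) -> tuple[float, float, float]:
    """Cumulative dose equivalent in µg/kg/day.

    Returns ``(d_cum_dm, d_cum_de, d_cum)``; µmol/day × g/mol = µg/day,
    divided by body weight in kg.
    """
    if body_weight <= 0:
        raise ValueError("body weight must be positive")
    parents = list(parents)
    dm = umol_dm * _class_factor(parents, proportions, rpfs, "dimethyl") / body_weight
    de = umol_de * _class_factor(parents, proportions, rpfs, "diethyl") / body_weight
    return dm, de, dm + de


def sampling_year_weights(cohort: pd.DataFrame) -> dict[int, float]:
    """Fraction of participants sampled in each calendar year, from the
    ``sampling_month`` column (ISO ``YYYY-MM``)."""
    years = cohort["sampling_month"].astype(str).str.slice(0, 4).astype(int)
    counts = years.value_counts(normalize=True)
    return {int(y): float(f) for y, f in counts.items()}


def assess_cohort(
    cohort: pd.DataFrame,
    parents: Iterable[ParentOpp],
    config: RiskConfig | None = None,
    analytes: Mapping[str, AnalyteDefinition] | None = None,
    excluded: Iterable[str] = ("DEDTP",),
) -> pd.DataFrame:
    """Per-participant dose equivalents for a completed cohort table.

    ``cohort`` must hold completed (post-imputation) analyte columns,
    ``urinary_creatinine`` in mg/dL (converted to mg/L internally),
    and ``body_weight`` in kg.  Year weights default to the cohort's
    own sampling distribution.  Returns a DataFrame with one row per
    participant: ``id, umol_dm, umol_de, d_cum_dm, d_cum_de, d_cum,
    exceeds``.
    """
    config = config or RiskConfig()
    config.validate()
    parents = list(parents)
    analytes = analytes or default_analytes()
    excluded = set(excluded)
    names = {p.name for p in parents}
    if config.reference_chemical not in names:
        raise ValueError(
            f"reference chemical {config.reference_chemical!r} not in parent table"
        )
    reference = next(p for p in parents if p.name == config.reference_chemical)
    rpfs = {
        p.name: compute_rpf(p, reference, config.rpf_orientation) for p in parents
    }
    weights = config.sampling_year_weights or sampling_year_weights(cohort)
    proportions = release_weighted_proportions(parents, weights)

    cr_l = cohort["urinary_creatinine"].to_numpy(dtype=float) * MG_PER_DL_TO_MG_PER_L
    if np.any(cr_l <= 0):
        raise ValueError("urinary creatinine must be positive")
    bw = cohort["body_weight"].to_numpy(dtype=float)
    if np.any(bw <= 0):
        raise ValueError("body weight must be positive")

    panel = {
        code: cohort[code].to_numpy(dtype=float)
        for code in analytes
        if code in cohort.columns and code not in excluded
    }
    umol = {}
    for cls in ("dimethyl", "diethyl"):
        molar = np.zeros(len(cohort))
        for code, conc in panel.items():
            if analytes[code].alkyl_class == cls:
                molar += conc / analytes[code].molecular_weight
        umol[cls] = molar * (config.cr_ref / cr_l)

    f_dm = _class_factor(parents, proportions, rpfs, "dimethyl")
    f_de = _class_factor(parents, proportions, rpfs, "diethyl")
    d_dm = umol["dimethyl"] * f_dm / bw
    d_de = umol["diethyl"] * f_de / bw
    d_cum = d_dm + d_de
    return pd.DataFrame(
        {
            "id": cohort["id"] if "id" in cohort else np.arange(len(cohort)),
            "umol_dm": umol["dimethyl"],
            "umol_de": umol["diethyl"],
            "d_cum_dm": d_dm,
            "d_cum_de": d_de,
            "d_cum": d_cum,
            "exceeds": d_cum > config.comparison_level,
        }
    )


def classify_exceedance(
    doses: pd.DataFrame, config: RiskConfig | None = None
) -> dict:
    """Count and characterise participants above the comparison level.

    Returns counts, percentage, and median/IQR of the exceeders'
    doses (NaN when nobody exceeds).
    """
    config = config or RiskConfig()
    config.validate()
    if len(doses) == 0:
        raise ValueError("no dose results to classify")
    d = doses["d_cum"].to_numpy(dtype=float)
    mask = d > config.comparison_level
    exceeders = d[mask]
    if len(exceeders) > 0:
        med = float(np.median(exceeders))
        q25, q75 = (float(q) for q in np.percentile(exceeders, [25, 75]))
    else:
        med = q25 = q75 = float("nan")
    return {
        "comparison_level": config.comparison_level,
        "n": int(len(d)),
        "n_exceed": int(mask.sum()),
        "pct_exceed": float(100.0 * mask.mean()),
        "exceeder_median": med,
        "exceeder_q25": q25,
        "exceeder_q75": q75,
    }


def cohort_dose_summary(doses: pd.DataFrame) -> pd.DataFrame:
    """Distributional summary of dose equivalents per class.

    Rows: mean, SD, geometric mean, geometric SD, min, quartiles, 95th
    percentile, max; columns: DAPs (all metabolites), DMs-only,
    DEs-only.  Non-positive doses are excluded from the geometric
    statistics (their count is reported in the ``n_gm_excluded`` row);
    GSD is undefined (NaN) for fewer than two positive doses.
    """
    if len(doses) == 0:
        raise ValueError("no dose results to summarise")
    cols = {"DAPs": "d_cum", "DMs": "d_cum_dm", "DEs": "d_cum_de"}
    stats = [
        "mean", "sd", "gm", "gsd", "min", "p25", "p50", "p75", "p95", "max",
        "n_gm_excluded",
    ]
    out = pd.DataFrame(index=stats, columns=list(cols), dtype=float)
    for label, col in cols.items():
        d = doses[col].to_numpy(dtype=float)
        pos = d[d > 0]
        logs = np.log(pos)
        out.loc["mean", label] = d.mean()
        out.loc["sd", label] = d.std(ddof=1) if len(d) > 1 else float("nan")
        out.loc["gm", label] = np.exp(logs.mean()) if len(pos) else float("nan")
        out.loc["gsd", label] = (
            np.exp(logs.std(ddof=1)) if len(pos) > 1 else float("nan")
        )
        out.loc["min", label] = d.min()
        out.loc["p25", label], out.loc["p50", label], out.loc["p75", label], \
            out.loc["p95", label] = np.percentile(d, [25, 50, 75, 95])
        out.loc["max", label] = d.max()
        out.loc["n_gm_excluded", label] = float(len(d) - len(pos))
    return out
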