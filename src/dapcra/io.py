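"""File I/O: cohort tables, chemical parameter tables, run metadata.

All tables are plain CSV.  Files written by this package carry a
commented header block (``# key: value`` lines) recording the seed and
parameters of the run, so every output is audit-traceable; readers
skip comment lines.
"""

from __future__ import annotations

import importlib.resources
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .analytes import ANALYTE_ORDER
from .risk import ParentOpp

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_parent_table",
    "load_synthetic_parent_table",
    "write_table",
    "write_manifest",
]

REQUIRED_COVARIATES = ("urinary_creatinine", "body_weight")


def _validate_cohort(df: pd.DataFrame, path=None) -> pd.DataFrame:
    where = f" in {path}" if path else ""
    analytes = [a for a in ANALYTE_ORDER if a in df.columns]
    if not analytes:
        raise ValueError(f"no analyte columns found{where}")
    unknown = [
        c.rsplit("_", 1)[0]
        for c in df.columns
        if c.endswith("_censored") and c.rsplit("_", 1)[0] not in ANALYTE_ORDER
    ]
    if unknown:
        raise ValueError(f"unknown analyte code(s) {unknown}{where}")
    for a in analytes:
        flag_col, lim_col = f"{a}_censored", f"{a}_limit"
        if flag_col in df.columns and lim_col not in df.columns:
            raise ValueError(f"censor flags for {a} without reporting limits{where}")
        if (df[a] < 0).any():
            row = int(df.index[df[a] < 0][0])
            raise ValueError(f"negative concentration for {a} at row {row}{where}")
    for col in REQUIRED_COVARIATES:
        if col not in df.columns:
            raise ValueError(f"required column {col!r} missing{where}")
    if "sampling_month" in df.columns:
        try:
            pd.PeriodIndex(df["sampling_month"].astype(str), freq="M")
        except Exception as exc:
            raise ValueError(f"malformed sampling_month{where}: {exc}") from exc
    return df


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV (standard layout, ``#`` comments allowed)."""
    df = pd.read_csv(path, comment="#", dtype={"sampling_month": str})
    return _validate_cohort(df, path)


def write_cohort(df: pd.DataFrame, path, metadata: Mapping | None = None) -> None:
    """Write a cohort CSV with a commented metadata header."""
    write_table(df, path, metadata)


def write_table(
    df: pd.DataFrame, path, metadata: Mapping | None = None, index: bool = False
) -> None:
    """Write any result table as CSV with ``# key: value`` header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=index)


def read_parent_table(path) -> list[ParentOpp]:
    """Read a parent-pesticide parameter CSV.

    Columns: ``name, alkyl_class, molecular_weight, bmdl10`` and one
    ``release_<year>`` column per year.
    """
    df = pd.read_csv(path, comment="#")
    required = {"name", "alkyl_class", "molecular_weight", "bmdl10"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parent table {path} missing columns {sorted(missing)}")
    year_cols = {
        int(c.split("_", 1)[1]): c for c in df.columns if c.startswith("release_")
    }
    if not year_cols:
        raise ValueError(f"parent table {path} has no release_<year> columns")
    parents = []
    for _, row in df.iterrows():
        parents.append(
            ParentOpp(
                name=str(row["name"]),
                molecular_weight=float(row["molecular_weight"]),
                bmdl10=float(row["bmdl10"]),
                annual_release={y: float(row[c]) for y, c in year_cols.items()},
                alkyl_class=str(row["alkyl_class"]),
            )
        )
    return parents


def load_synthetic_parent_table() -> list[ParentOpp]:
    """The bundled placeholder parent-OPP table (synthetic BMDL₁₀ and
    release values; real molecular weights)."""
    ref = importlib.resources.files("dapcra.data") / "parent_opp_synthetic.csv"
    with importlib.resources.as_file(ref) as path:
        return read_parent_table(path)


def write_manifest(
    path,
    seed: int,
    inputs: Mapping,
    counts: Mapping[str, int],
    exclusions: Iterable[Mapping] = (),
) -> None:
    """Write a JSON run manifest: seed, inputs, participant counts per
    stage and explicit exclusion reasons (no stage drops rows silently)."""
    from . import __version__

    manifest = {
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": dict(inputs),
        "participant_counts": dict(counts),
        "exclusions": list(exclusions),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=str))
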