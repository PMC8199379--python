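"""Quantile-regression imputation of left-censored concentrations (QRILC).

Nondetects are assumed to come from the lower tail of the same
lognormal that generated the detects.  The fit step regresses the log
observed order statistics against standard-normal quantiles evaluated
at plotting positions that account for the censored fraction (the
classic probability-plot / ROS construction); the imputation step then
replaces each nondetect with a draw from the fitted lognormal
truncated above at that observation's own reporting limit, so no
imputed value can reach its limit and observed values are never
touched.

The draw is a single pass per analyte: with each analyte imputed
marginally from its own fitted distribution, iterative refinement
across analytes adds nothing, so no Gibbs-style sweep is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import norm

from .analytes import ANALYTE_ORDER
from .censored import CensoredVector

__all__ = [
    "ImputationConfig",
    "fit_censored_lognormal",
    "qrilc_impute",
    "impute_cohort",
]


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for the truncated-tail draw.

    ``tail_draw`` selects how nondetects are placed within the fitted
    truncated tail: ``random-truncated`` (default) draws uniformly in
    truncated-CDF space; ``deterministic-quantile`` spreads them over
    evenly spaced truncated quantiles (reproducible without a seed and
    useful for debugging).  ``tune_sigma`` multiplies the fitted scale
    before drawing (1.0 = use the fitted scale as-is).
    """

    seed: int = 0
    tail_draw: Literal["random-truncated", "deterministic-quantile"] = (
        "random-truncated"
    )
    tune_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.tune_sigma <= 0:
            raise ValueError("tune_sigma must be positive")
        if self.tail_draw not in ("random-truncated", "deterministic-quantile"):
            raise ValueError(f"unknown tail_draw mode {self.tail_draw!r}")


def fit_censored_lognormal(x: CensoredVector) -> tuple[float, float]:
    """Fit (location, scale) of a lognormal to a left-censored sample.

    Observed log values, sorted ascending, occupy overall ranks
    ``n_cens + 1 .. n``; Hazen plotting positions ``(i - 0.5)/n`` over
    the full sample convert ranks to probabilities, and an ordinary
    least-squares line of log value on the standard-normal quantile of
    its position gives intercept = location, slope = scale (natural
    log).
    """
    n = len(x)
    obs = np.sort(np.log(x.values[~x.censored]))
    n_obs = len(obs)
    if n_obs < 3:
        raise ValueError("need at least 3 uncensored observations")
    if np.ptp(obs) == 0:
        raise ValueError("observed values all equal; scale is degenerate")
    n_cens = n - n_obs
    ranks = n_cens + np.arange(1, n_obs + 1)
    z = norm.ppf((ranks - 0.5) / n)
    slope, intercept = np.polyfit(z, obs, 1)
    if slope <= 0:
        raise ValueError("degenerate fit: non-positive scale")
    return float(intercept), float(slope)


def qrilc_impute(
    x: CensoredVector,
    config: ImputationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Return a completed concentration vector.

    Observed entries are returned unchanged; each censored entry is
    replaced by a value from the fitted lognormal truncated above at
    that entry's reporting limit, hence strictly positive and strictly
    below the limit.  Deterministic for a fixed ``(data, config)``
    pair when ``rng`` is not supplied.
    """
    config = config or ImputationConfig()
    out = x.values.astype(float).copy()
    cens_idx = np.flatnonzero(x.censored)
    m = len(cens_idx)
    if m == 0:
        return out

    mu, sigma = fit_censored_lognormal(x)
    sigma = sigma * config.tune_sigma
    limits = x.limits[cens_idx]
    # truncated-CDF mass below each observation's own limit
    p_limit = norm.cdf((np.log(limits) - mu) / sigma)

    if config.tail_draw == "deterministic-quantile":
        # spread censored entries over even quantiles of their tails,
        # ordered by limit then position for reproducibility
        order = np.lexsort((cens_idx, limits))
        u = np.empty(m)
        u[order] = (np.arange(1, m + 1) - 0.5) / m
    else:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        u = rng.uniform(0.0, 1.0, size=m)

    # map into the truncated tail; keep strictly interior to avoid
    # imputing exactly at the limit
    q = np.clip(u * p_limit, 1e-300, p_limit * (1 - 1e-12))
    draws = np.exp(mu + sigma * norm.ppf(q))
    draws = np.minimum(draws, limits * (1 - 1e-12))
    out[cens_idx] = draws
    return out


def impute_cohort(
    cohort: pd.DataFrame,
    config: ImputationConfig | None = None,
    analytes: list[str] | None = None,
    excluded: set[str] | frozenset[str] = frozenset(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute every censored analyte cell of a cohort table.

    ``cohort`` uses the standard layout (``<analyte>``,
    ``<analyte>_censored``, ``<analyte>_limit`` columns).  Analytes in
    ``excluded`` (e.g. one detected too rarely to fit) are left
    untouched.  Returns the completed table and an audit table with
    one row per imputed cell (participant, analyte, limit, value).
    Each analyte gets an independent substream of the seed so results
    do not depend on analyte order.
    """
    config = config or ImputationConfig()
    if analytes is None:
        analytes = [a for a in ANALYTE_ORDER if a in cohort.columns]
    out = cohort.copy()
    audit_rows = []
    for a in analytes:
        if a in excluded:
            continue
        stream = ANALYTE_ORDER.index(a) if a in ANALYTE_ORDER else len(ANALYTE_ORDER)
        flags = cohort[f"{a}_censored"].to_numpy(dtype=bool)
        if not flags.any():
            continue
        vec = CensoredVector(
            cohort[a].to_numpy(dtype=float),
            flags,
            cohort[f"{a}_limit"].to_numpy(dtype=float),
        )
        rng = np.random.default_rng([config.seed, stream])
        completed = qrilc_impute(vec, config, rng=rng)
        out[a] = completed
        for idx in np.flatnonzero(flags):
            audit_rows.append(
                {
                    "id": cohort["id"].iloc[idx] if "id" in cohort else idx,
                    "analyte": a,
                    "limit": vec.limits[idx],
                    "imputed_value": completed[idx],
                    "seed": config.seed,
                }
            )
    audit = pd.DataFrame(
        audit_rows, columns=["id", "analyte", "limit", "imputed_value", "seed"]
    )
    return out, audit
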