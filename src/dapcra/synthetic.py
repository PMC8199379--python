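"""Synthetic pregnancy-cohort generator.

Real biomonitoring tables of this kind are access-restricted, so every
downstream stage is exercised on synthetic cohorts with the same
statistical structure: correlated multivariate-lognormal analyte
concentrations whose marginals are calibrated to published summary
statistics (medians and interquartile ranges where detection is high;
detection rate and 95th percentile where it is low), lognormal urinary
creatinine, near-unity specific gravity, and plausible maternal
covariates (age, body weight, BMI, serum creatinine, sampling month).

Calibration inverts lognormal quantiles: a median ``m`` gives the
log-location ``ln m``; an interquartile range ``(q25, q75)`` gives the
log-scale ``ln(q75/q25) / (2 * z_0.75)``; when the median itself is
below the reporting limit, the detection rate ``d`` at limit ``L`` and
the 95th percentile ``q95`` jointly give scale
``ln(q95/L) / (z_0.95 - z_{1-d})`` and location ``ln L - z_{1-d} * scale``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .analytes import ANALYTE_ORDER, default_mrls

__all__ = [
    "SyntheticConfig",
    "default_config",
    "generate_cohort",
    "apply_censoring",
    "lognormal_params_from_quantiles",
    "lognormal_params_from_detection",
    "default_correlation",
]

COVARIATE_COLUMNS = (
    "urinary_creatinine",
    "specific_gravity",
    "serum_creatinine",
    "age",
    "body_weight",
    "bmi",
    "sampling_month",
)


def lognormal_params_from_quantiles(median: float, q25: float, q75: float):
    """Log-location and log-scale from a median and IQR."""
    if not 0 < q25 < median < q75:
        raise ValueError("need 0 < q25 < median < q75")
    z75 = norm.ppf(0.75)
    return float(np.log(median)), float(np.log(q75 / q25) / (2 * z75))


def lognormal_params_from_detection(detection_rate: float, mrl: float, q95: float):
    """Log-location and log-scale from a detection rate at the
    reporting limit plus the 95th percentile (for analytes whose
    median is itself a nondetect)."""
    if not 0 < detection_rate < 1:
        raise ValueError("detection rate must be in (0, 1)")
    if q95 <= mrl:
        raise ValueError("95th percentile must exceed the reporting limit")
    z_nd = norm.ppf(1.0 - detection_rate)  # standardised position of the MRL
    z95 = norm.ppf(0.95)
    scale = float(np.log(q95 / mrl) / (z95 - z_nd))
    loc = float(np.log(mrl) - z_nd * scale)
    return loc, scale


def default_correlation(
    same_class: float = 0.5, cross_class: float = 0.2
) -> np.ndarray:
    """Analyte log-space correlation: shared parent compounds induce
    positive correlation, stronger within an alkyl class than across."""
    n = len(ANALYTE_ORDER)
    corr = np.full((n, n), cross_class)
    dm = [i for i, a in enumerate(ANALYTE_ORDER) if a.startswith("DM")]
    de = [i for i, a in enumerate(ANALYTE_ORDER) if a.startswith("DE")]
    for group in (dm, de):
        for i in group:
            for j in group:
                corr[i, j] = same_class
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Scale parameters are strictly positive; the analyte correlation
    matrix must be symmetric with unit diagonal and positive
    semi-definite.  Defaults (see :func:`default_config`) are
    calibrated so that marginal medians, IQRs and detection rates match
    a large published pregnancy-biomonitoring panel.
    """

    n_participants: int
    seed: int
    analyte_log_location: dict[str, float]
    analyte_log_scale: dict[str, float]
    analyte_correlation: np.ndarray
    creatinine_log_location: float = float(np.log(83.0))  # median 83 mg/dL
    creatinine_log_scale: float = 0.5
    sg_mean: float = 1.015
    sg_sd: float = 0.005
    bw_mean: float = 53.0
    bw_sd: float = 7.0
    age_min: float = 18.0
    age_max: float = 45.0
    serum_cr_mean: float = 0.55
    serum_cr_sd: float = 0.08
    bmi_mean: float = 20.9
    bmi_sd: float = 2.5
    period_start: str = "2011-01"
    period_end: str = "2014-03"
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")
        missing = set(ANALYTE_ORDER) - set(self.analyte_log_location)
        if missing or set(ANALYTE_ORDER) - set(self.analyte_log_scale):
            raise ValueError("log location/scale required for every analyte")
        for a in ANALYTE_ORDER:
            if self.analyte_log_scale[a] <= 0:
                raise ValueError(f"log scale for {a} must be positive")
        for name in ("creatinine_log_scale", "sg_sd", "bw_sd",
                     "serum_cr_sd", "bmi_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        corr = np.asarray(self.analyte_correlation, dtype=float)
        k = len(ANALYTE_ORDER)
        if corr.shape != (k, k):
            raise ValueError(f"correlation matrix must be {k}x{k}")
        if not np.allclose(corr, corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        eig = np.linalg.eigvalsh(corr)
        if eig.min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        start = pd.Period(self.period_start, freq="M")
        end = pd.Period(self.period_end, freq="M")
        if end < start:
            raise ValueError("sampling period end precedes start")


def default_config(n_participants: int = 4456, seed: int = 0) -> SyntheticConfig:
    """Cohort calibrated to the published urinary DAP panel.

    DMP/DMTP/DEP are calibrated from their crude medians and IQRs
    (2.93 [1.33-6.16], 3.29 [1.32-9.38], 2.78 [1.32-5.47] ng/mL);
    DMDTP and DETP, whose medians are nondetects, from detection rate
    and 95th percentile (16.1% / 2.94 ng/mL and 22.9% / 4.50 ng/mL);
    DEDTP sits far below its limit so that at most a couple of detects
    appear per several thousand participants.
    """
    loc: dict[str, float] = {}
    scale: dict[str, float] = {}
    loc["DMP"], scale["DMP"] = lognormal_params_from_quantiles(2.93, 1.33, 6.16)
    loc["DMTP"], scale["DMTP"] = lognormal_params_from_quantiles(3.29, 1.32, 9.38)
    loc["DEP"], scale["DEP"] = lognormal_params_from_quantiles(2.78, 1.32, 5.47)
    loc["DMDTP"], scale["DMDTP"] = lognormal_params_from_detection(0.161, 0.997, 2.94)
    loc["DETP"], scale["DETP"] = lognormal_params_from_detection(0.229, 1.2, 4.50)
    loc["DEDTP"], scale["DEDTP"] = -3.5, 1.0  # detection ~0.02%
    return SyntheticConfig(
        n_participants=n_participants,
        seed=seed,
        analyte_log_location=loc,
        analyte_log_scale=scale,
        analyte_correlation=default_correlation(),
    )


def _truncated_normal(rng, mean, sd, lower, upper, size):
    a, b = (lower - mean) / sd, (upper - mean) / sd
    u = rng.uniform(norm.cdf(a), norm.cdf(b), size=size)
    return mean + sd * norm.ppf(u)


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Draw a cohort table of true (uncensored) analyte concentrations
    and covariates; deterministic for a fixed seed.

    Returns one row per participant with columns ``id``, the six
    analyte concentrations (ng/mL), and the covariates in
    :data:`COVARIATE_COLUMNS`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    k = len(ANALYTE_ORDER)

    mu = np.array([config.analyte_log_location[a] for a in ANALYTE_ORDER])
    sig = np.array([config.analyte_log_scale[a] for a in ANALYTE_ORDER])
    corr = np.asarray(config.analyte_correlation, dtype=float)
    cov = corr * np.outer(sig, sig)
    logs = rng.multivariate_normal(mu, cov, size=n, method="cholesky" if
                                   np.linalg.eigvalsh(corr).min() > 1e-10 else "svd")
    conc = np.exp(logs)

    df = pd.DataFrame(conc, columns=list(ANALYTE_ORDER))
    df.insert(0, "id", [f"P{i:06d}" for i in range(1, n + 1)])
    df["urinary_creatinine"] = np.exp(
        rng.normal(config.creatinine_log_location, config.creatinine_log_scale, n)
    )
    df["specific_gravity"] = _truncated_normal(
        rng, config.sg_mean, config.sg_sd, 1.001, 1.060, n
    )
    df["serum_creatinine"] = _truncated_normal(
        rng, config.serum_cr_mean, config.serum_cr_sd, 0.2, 2.0, n
    )
    df["age"] = np.round(rng.uniform(config.age_min, config.age_max, n), 1)
    df["body_weight"] = _truncated_normal(
        rng, config.bw_mean, config.bw_sd, 35.0, 120.0, n
    )
    df["bmi"] = _truncated_normal(rng, config.bmi_mean, config.bmi_sd, 14.0, 40.0, n)
    months = pd.period_range(config.period_start, config.period_end, freq="M")
    df["sampling_month"] = [str(m) for m in rng.choice(months.astype(str), size=n)]
    return df


def apply_censoring(
    cohort: pd.DataFrame, mrls: dict[str, float] | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Left-censor analyte columns at their reporting limits.

    Every value below its MRL is flagged as censored and replaced by
    the MRL; values at or above are untouched.  Returns the censored
    table (adding ``<analyte>_censored`` 0/1 flags and
    ``<analyte>_limit`` columns) and per-analyte detection rates.
    """
    mrls = dict(default_mrls() if mrls is None else mrls)
    present = [a for a in ANALYTE_ORDER if a in cohort.columns]
    missing = [a for a in present if a not in mrls]
    if missing:
        raise ValueError(f"missing MRL for analytes: {missing}")
    for a, m in mrls.items():
        if m <= 0:
            raise ValueError(f"MRL for {a} must be positive")

    out = cohort.copy()
    rates: dict[str, float] = {}
    for a in present:
        limit = float(mrls[a])
        cens = out[a].to_numpy(dtype=float) < limit
        out[a] = np.where(cens, limit, out[a])
        out[f"{a}_censored"] = cens.astype(int)
        out[f"{a}_limit"] = limit
        rates[a] = float(1.0 - cens.mean())
    return out, rates


def make_cohort(
    n_participants: int = 4456, seed: int = 0, **overrides
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Convenience wrapper: generate truth, censor at default MRLs.

    Returns ``(censored_cohort, truth, detection_rates)``.
    """
    config = default_config(n_participants, seed)
    if overrides:
        config = replace(config, **overrides)
    truth = generate_cohort(config)
    censored, rates = apply_censoring(truth)
    return censored, truth, rates
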