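"""Descriptive statistics for left-censored concentration data.

Concentrations below a minimum reporting level (MRL) are known only to
lie below that limit.  Rather than substituting such nondetects with a
fixed fraction of the limit, summary statistics here use the
Kaplan-Meier (KM) estimator on *flipped* data: left-censored values
become right-censored after subtracting every observation from a
constant exceeding the maximum, the survival curve is estimated, and
location statistics are mapped back.  With no censoring the KM
distribution coincides with the empirical distribution, so all
statistics reduce to their plain empirical counterparts.

Also provided are the standard urine-dilution corrections (creatinine
and specific-gravity normalisation), the base-10 log transform used
for downstream statistics, and the Japanese female eGFR equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter

__all__ = [
    "CensoredVector",
    "SummaryStats",
    "detection_rate",
    "km_summary",
    "normalize_creatinine",
    "normalize_specific_gravity",
    "log10_transform",
    "egfr",
]


@dataclass
class CensoredVector:
    """Concentration measurements with left-censoring indicators.

    ``values`` holds the measured concentration for detects and the
    reporting limit for nondetects; ``censored`` marks nondetects;
    ``limits`` carries each observation's reporting limit (used for
    truncation during imputation; for detects it is informational).
    """

    values: np.ndarray
    censored: np.ndarray
    limits: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        self.limits = np.asarray(self.limits, dtype=float)
        if not (len(self.values) == len(self.censored) == len(self.limits)):
            raise ValueError("values, censored and limits must be equal length")
        if np.any(self.values <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(self.limits[self.censored] <= 0):
            raise ValueError("reporting limits must be strictly positive")
        # censored observations carry their limit as value
        if not np.allclose(self.values[self.censored], self.limits[self.censored]):
            raise ValueError("censored observations must carry their limit as value")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_observed(self) -> int:
        return int((~self.censored).sum())

    @classmethod
    def uncensored(cls, values) -> "CensoredVector":
        v = np.asarray(values, dtype=float)
        return cls(v, np.zeros(len(v), dtype=bool), v.copy())

    @classmethod
    def from_values_limits(cls, values, limits) -> "CensoredVector":
        """Build from raw (true) values: anything below its limit is
        censored and replaced by the limit."""
        v = np.asarray(values, dtype=float).copy()
        lim = np.broadcast_to(np.asarray(limits, dtype=float), v.shape).copy()
        cens = v < lim
        v[cens] = lim[cens]
        return cls(v, cens, lim)


@dataclass
class SummaryStats:
    """Summary of one analyte: detection rate, KM mean/SD and quantiles.

    ``quantiles`` maps probability to concentration; a value of NaN with
    the probability listed in ``below_limit`` means the quantile falls
    inside the unresolved censored mass and is reported as "<MRL" rather
    than a number.
    """

    n: int
    detection_rate: float
    mean: float
    sd: float
    quantiles: dict[float, float] = field(default_factory=dict)
    below_limit: set[float] = field(default_factory=set)

    def quantile_label(self, p: float, fmt: str = "{:.3g}") -> str:
        if p in self.below_limit:
            return "<MRL"
        return fmt.format(self.quantiles[p])


def detection_rate(x: CensoredVector) -> float:
    """Fraction of observations at or above their reporting limit."""
    if len(x) == 0:
        raise ValueError("empty vector")
    return x.n_observed / len(x)


def _km_masses(x: CensoredVector, flip_offset: float = 1.0):
    """Kaplan-Meier probability masses for a left-censored sample.

    Flips to right-censoring (``y = M - x`` with ``M = max(values) +
    flip_offset``), fits KM, and returns ``(support, mass,
    unresolved_mass, max_limit)`` in the original scale, support sorted
    ascending.  ``unresolved_mass`` is the probability the survival
    curve leaves below the smallest resolvable value, i.e. in the
    censored region below the largest reporting limit.
    """
    M = float(x.values.max()) + flip_offset
    durations = M - x.values
    observed = ~x.censored
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    sf = kmf.survival_function_.iloc[:, 0]
    times = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    prev = np.concatenate([[1.0], surv[:-1]])
    drops = prev - surv  # mass at each event time in flipped scale
    keep = drops > 1e-15
    support = M - times[keep]
    mass = drops[keep]
    order = np.argsort(support)
    support = support[order]
    mass = mass[order]
    unresolved = max(0.0, 1.0 - mass.sum())
    max_limit = float(x.limits[x.censored].max()) if x.censored.any() else np.nan
    return support, mass, unresolved, max_limit


def km_summary(
    x: CensoredVector,
    probs=(0.25, 0.5, 0.75, 0.95),
    flip_offset: float = 1.0,
) -> SummaryStats:
    """Kaplan-Meier summary statistics for left-censored data.

    Mean and SD place any unresolved censored mass at the largest
    reporting limit (the standard convention for nondetect KM means;
    it biases the mean upward by at most that mass times the limit).
    Quantiles use the left-continuous step inverse (smallest support
    value whose estimated CDF reaches ``p``); a quantile falling inside
    the unresolved censored mass is flagged ``below_limit`` instead of
    being fabricated.
    """
    if len(x) == 0:
        raise ValueError("empty vector")
    if x.n_observed == 0:
        raise ValueError("all observations censored; KM statistics undefined")
    probs = [float(p) for p in probs]
    if any(not 0.0 < p < 1.0 for p in probs):
        raise ValueError("probabilities must lie in (0, 1)")

    support, mass, unresolved, max_limit = _km_masses(x, flip_offset)

    # moments: unresolved censored mass sits at the largest limit
    if unresolved > 1e-12:
        m_support = np.concatenate([[max_limit], support])
        m_mass = np.concatenate([[unresolved], mass])
    else:
        m_support, m_mass = support, mass
    m_mass = m_mass / m_mass.sum()
    mean = float(np.sum(m_support * m_mass))
    var = float(np.sum(m_mass * (m_support - mean) ** 2))
    sd = math.sqrt(max(var, 0.0))

    cdf = unresolved + np.cumsum(mass)
    quantiles: dict[float, float] = {}
    below: set[float] = set()
    for p in probs:
        if p <= unresolved + 1e-12:
            quantiles[p] = float("nan")
            below.add(p)
        else:
            idx = int(np.searchsorted(cdf, p - 1e-12))
            quantiles[p] = float(support[min(idx, len(support) - 1)])

    return SummaryStats(
        n=len(x),
        detection_rate=detection_rate(x),
        mean=mean,
        sd=sd,
        quantiles=quantiles,
        below_limit=below,
    )


def normalize_creatinine(c, cr):
    """Creatinine-normalise a urinary concentration.

    ``c`` in ng/mL divided by urinary creatinine ``cr`` in mg/dL
    (converted to g/L) gives µg analyte per g creatinine.
    """
    c = np.asarray(c, dtype=float)
    cr = np.asarray(cr, dtype=float)
    if np.any(cr <= 0):
        raise ValueError("urinary creatinine must be positive")
    return c / (cr * 0.01)


def normalize_specific_gravity(c, sg, sg_ref: float = 1.020):
    """Specific-gravity normalisation (Levine-Fahy convention).

    Scales concentration by ``(sg_ref - 1) / (sg - 1)``; a urine more
    concentrated than the reference is scaled down and vice versa.
    """
    c = np.asarray(c, dtype=float)
    sg = np.asarray(sg, dtype=float)
    if sg_ref <= 1:
        raise ValueError("reference specific gravity must exceed 1")
    if np.any(sg <= 1):
        raise ValueError("specific gravity must exceed 1 (no urinary solutes)")
    return c * (sg_ref - 1.0) / (sg - 1.0)


def log10_transform(x):
    """Elementwise base-10 logarithm.

    Accepts an array of positive concentrations or a
    :class:`CensoredVector`, whose censor flags are carried through
    unchanged (limits are log-transformed alongside the values).
    """
    if isinstance(x, CensoredVector):
        if np.any(x.values <= 0):
            raise ValueError("log10 requires strictly positive values")
        return _log10_censored(x)
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("log10 requires strictly positive values")
    return np.log10(arr)


def _log10_censored(x: CensoredVector):
    """Log-transform a censored vector without positivity re-validation
    (log values may be negative; the flags/limit pairing is preserved)."""
    out = CensoredVector.__new__(CensoredVector)
    out.values = np.log10(x.values)
    out.censored = x.censored.copy()
    out.limits = np.log10(x.limits)
    return out


def egfr(serum_creatinine, age):
    """Estimated glomerular filtration rate (mL/min/1.73 m²) for
    Japanese women: ``194 * Scr^-1.094 * age^-0.287 * 0.739``.

    ``serum_creatinine`` in mg/dL, ``age`` in years.
    """
    scr = np.asarray(serum_creatinine, dtype=float)
    a = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(a <= 0):
        raise ValueError("serum creatinine and age must be positive")
    return 194.0 * scr ** -1.094 * a ** -0.287 * 0.739
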