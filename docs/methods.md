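# Methods

## Statistical model

### Left-censored concentrations

Each analyte's concentration vector is treated as a positive random
variable observed exactly at or above a minimum reporting level (MRL)
and only as "< limit" below it. The package's unit of work is the
`CensoredVector`: values (nondetects carry their limit), boolean
censor flags, and per-observation limits (limits may differ across
observations, e.g. DETP batches reported at 1.2 or 1.3 ng/mL).

**Kaplan–Meier descriptive statistics.** Left-censored data are
flipped to right-censored by `y = M − x` with `M = max(x) + 1`; the KM
survival curve of `y` (fitted with `lifelines`) is converted to
probability masses and mapped back. Any constant strictly above the
maximum gives identical statistics — verified as a property test, so
the choice of offset is immaterial. Conventions:

- *Quantiles*: left-continuous step inverse — the smallest support
  value whose estimated CDF reaches `p`. On fully observed data this
  is exactly the type-1 (inverted-CDF) empirical quantile, and all KM
  statistics collapse to their empirical counterparts.
- *Unresolved mass*: when the smallest values are censored the KM
  curve does not resolve the lower tail. A quantile falling inside
  that mass is reported as a below-limit marker (NaN + flag), never a
  number — this is why medians and lower quartiles of analytes with
  detection < 50% (DMDTP, DETP) appear as dashes in summary tables.
- *Mean/SD*: the unresolved mass is placed at the largest reporting
  limit, the standard convention for nondetect KM means; it biases the
  mean upward by at most (mass × limit). Post-imputation means/SDs
  are preferred for reporting and are what the pipeline's summary
  table shows after the imputation stage has run.
- *Ties*: at equal magnitude, detects precede nondetects (the
  flipped-space deaths-before-censoring convention), so censored mass
  sits strictly below an observed value at the same level.

**QRILC imputation.** The fit step regresses log observed order
statistics on standard-normal quantiles at Hazen plotting positions
`(i − 0.5)/n` computed over the *full* sample size, with observed
ranks offset by the censored count — the classic probability-plot /
ROS construction for a common detection limit. Intercept = location,
slope = scale (natural log; the log10 values used elsewhere differ by
the exact factor ln 10). The draw step replaces each nondetect by
`exp(μ + σ·Φ⁻¹(U · Φ((ln L − μ)/σ)))` with `U ~ Uniform(0,1)` and `L`
that observation's own limit, i.e. a truncated-lognormal draw that is
strictly positive and strictly below the limit. A deterministic mode
(`tail_draw="deterministic-quantile"`) spreads nondetects over evenly
spaced truncated quantiles for seedless reproducibility. Because each
analyte is imputed marginally from its own fitted distribution, a
Gibbs-style sweep across analytes would change nothing; the
implementation is a single pass, with one RNG substream per analyte
keyed by the analyte's canonical index so results are independent of
processing order. `tune_sigma` (default 1.0) rescales the fitted
spread for sensitivity analyses.

Analytes detected in at most 2 participants (DEDTP at cohort scale)
carry too little signal to fit a tail and are excluded from
imputation, summaries and molar sums; the threshold is configurable.

### Normalisations and covariates

- Creatinine normalisation: `c [ng/mL] / (Cr [mg/dL] × 0.01)` =
  µg analyte per g creatinine.
- Specific-gravity normalisation uses the Levine–Fahy convention
  `c · (SG_ref − 1)/(SG − 1)` with reference 1.020; SG ≤ 1 is a
  domain error (no urinary solutes).
- eGFR uses the Japanese female equation
  `194 · Scr^−1.094 · age^−0.287 · 0.739` (serum creatinine in mg/dL).

### Dose reconstruction

Per participant and alkyl class, the daily molar excretion is
`(Σ C_i/MW_i) · (Cr_ref/Cr_conc)`: ng/mL over g/mol gives µmol/L, and
the ratio of reference daily creatinine excretion (mg/day) to urinary
creatinine concentration (mg/L) estimates the 24-h urine volume in
L/day. `Cr_ref` defaults to 1050 mg/day, a physiologically sensible
daily creatinine excretion for pregnant women; urinary creatinine is
accepted in the clinical mg/dL convention and converted to mg/L
internally (×10). Metabolite molecular weights are free-acid values
(DMP 126.05, DMTP 142.11, DMDTP 158.18, DEP 154.10, DETP 170.17
g/mol) since the urinary analyte is the acid/anion, not the potassium
salt used as calibration standard.

Parent attribution weights `P_i` are release-weighted market shares:
each parent's annual release is averaged with the fraction of the
cohort sampled per year as weights, then normalised within its alkyl
class (6 dimethyl parents, 2 diethyl parents; per-class shares sum
to 1). Relative potency factors default to
`BMDL10(reference)/BMDL10(i)` — more potent parents (lower benchmark)
get larger RPFs, and the reference (fenitrothion) has RPF 1 — with
the inverted orientation available in config for sensitivity checks,
since both conventions appear in the applied literature.

The exceedance comparison level defaults to 13.0 µg/kg/day, read as
the index chemical's benchmark with the 100-fold margin of exposure
already reflected; both the raw benchmark and the margin are config
fields so either convention can be expressed explicitly.

## Synthetic cohort

The generator emulates the data structure the analysis assumes:

- **Analytes**: multivariate lognormal in log space, correlation 0.5
  within an alkyl class and 0.2 across (shared parent compounds induce
  positive correlation; the true cross-correlations are not published,
  so these are calibration choices, overridable in config).
  Marginals are calibrated by quantile inversion: DMP/DMTP/DEP from
  their published crude medians and IQRs; DMDTP/DETP (medians below
  the limit) from detection rate and 95th percentile; DEDTP placed at
  log-location −3.5 so that essentially no detects occur. Under this
  calibration the implied detection rates at the default MRLs
  (0.997 ng/mL; DETP 1.2) come out at ~83/79/16/83/22/0.02% — within
  a few points of the published 80.8/80.0/16.1/81.2/22.9/0.02%.
- **Urinary creatinine**: lognormal with median 83 mg/dL (chosen so
  crude and creatinine-normalised medians relate as published:
  2.93 ng/mL → 3.53 µg/g) and log-scale 0.5, a typical spot-urine
  spread.
- **Covariates**: body weight N(53, 7²) kg truncated to [35, 120]
  (published tables give BMI but not weight, so the weight
  distribution is a free, documented choice); BMI N(20.9, 2.5²)
  carried as a covariate only; age uniform on [18, 45]; serum
  creatinine N(0.55, 0.08²) mg/dL (plausible pregnancy values, used
  only by the eGFR equation); specific gravity N(1.015, 0.005²)
  truncated above 1.001; sampling month uniform over 2011-01 to
  2014-03.

**What the generator does not emulate.** Urinary creatinine is drawn
independently of the analytes, whereas in real spot urine both share
hydration-driven dilution variance; consequently creatinine
normalisation does not *narrow* the synthetic IQRs the way it does in
real data (synthetic normalised IQRs are somewhat wider than
published ones, while medians match). There is also no seasonality,
no food-intake structure, and no measurement error beyond the
lognormal itself. Passing tests therefore demonstrate the estimators
and the dose algebra, not the epidemiology of any real cohort.

The bundled parent-OPP table uses real molecular weights but
placeholder benchmark doses and annual releases (the authoritative
appendix is not available); it is a labelled synthetic stand-in,
chosen so the index chemical dominates its class and the diethyl
parents are an order of magnitude less potent than the reference —
which places the synthetic dose distribution (median ≈ 0.5 µg/kg/day,
GSD ≈ 3, exceedance ≈ 0.5% at 13 µg/kg/day) in the published range.

## Numerical and design choices

- Flip offset 1.0 for KM (any positive offset equivalent, tested).
- Truncated draws are clipped strictly inside (0, limit) with a
  relative margin of 1e-12 to guarantee the truncation contract under
  floating-point rounding.
- Degenerate inputs raise: empty vectors, all-censored vectors, fewer
  than 3 detects for a fit, zero-variance detects, non-positive
  creatinine/weights/benchmarks, correlation matrices that are
  asymmetric or not positive semi-definite.
- Geometric mean/SD exclude non-positive doses with a reported count;
  GSD is undefined (NaN) below two positive values.
- Records missing urinary creatinine or body weight are excluded
  before assessment with an explicit reason in the run manifest; no
  stage drops rows silently.
- End-to-end determinism: the pipeline seed feeds the generator and
  per-analyte imputation substreams; identical inputs and seed give
  byte-identical output CSVs.

## Problem sizes

Tests use n = 2000 for recovery checks (50 Monte-Carlo replicates
where distributional claims are made), n = 20000 once for marginal
calibration of the widest-tailed analyte, and n = 5000 for the
end-to-end run; the acceptance script uses the study-scale n = 4456.
The full suite runs in well under a minute on one CPU.

## Known limitations

- The KM mean's censored-mass-at-limit convention is upward-biased
  when detection is low; medians and the post-imputation means are
  the preferred location summaries.
- QRILC here is marginal per analyte; a joint multivariate imputation
  could borrow strength across correlated analytes but is out of
  scope.
- The fit assumes a single dominant reporting limit when assigning
  plotting positions (observed ranks offset by the total censored
  count); with widely differing per-observation limits this is an
  approximation, though truncation always respects each observation's
  own limit.
- Dose reconstruction inherits the usual spot-urine caveats: the
  creatinine-ratio volume estimate, population-level release shares
  instead of personal use, and the assumption of complete
  metabolism to DAPs.
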