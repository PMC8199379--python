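"""Simulate a censored biomonitoring cohort.

Draws correlated lognormal urinary DAP concentrations with covariates,
censors them at the minimum reporting levels, and prints the per-analyte
detection rates.  Rates near 80% (DMP/DMTP/DEP), ~16-23% (DMDTP/DETP)
and ~0% (DEDTP) reflect the calibration of the default configuration.
"""

from dapcra import make_cohort

censored, truth, rates = make_cohort(n_participants=2000, seed=1)

print(f"cohort of {len(censored)} participants")
for analyte, rate in rates.items():
    print(f"  {analyte:6s} detection rate {100 * rate:5.1f}%")
print("\nfirst record:")
print(censored.iloc[0, :10].to_string())
print("\nDetection rate = fraction of samples at or above the reporting")
print("limit; nondetects carry the limit as value with a censor flag.")
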