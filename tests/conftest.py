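import numpy as np
import pandas as pd
import pytest

from dapcra import CensoredVector, default_config, generate_cohort, apply_censoring


@pytest.fixture(scope="session")
def cohort_2000():
    """Censored synthetic cohort of 2000 with its uncensored truth."""
    cfg = default_config(2000, seed=42)
    truth = generate_cohort(cfg)
    censored, rates = apply_censoring(truth)
    return censored, truth, rates, cfg


@pytest.fixture
def toy_censored_vector():
    """Five observations, two nondetects at limit 1: {<1, <1, 2, 3, 4}."""
    return CensoredVector(
        np.array([1.0, 1.0, 2.0, 3.0, 4.0]),
        np.array([True, True, False, False, False]),
        np.array([1.0, 1.0, 2.0, 3.0, 4.0]),
    )


@pytest.fixture
def tiny_cohort():
    """Three complete participants in the standard cohort layout."""
    rows = []
    rng = np.random.default_rng(5)
    for i in range(3):
        row = {"id": f"P{i:06d}"}
        for a, base in [("DMP", 3.0), ("DMTP", 4.0), ("DMDTP", 0.5),
                        ("DEP", 2.5), ("DETP", 0.8), ("DEDTP", 0.05)]:
            value = base * rng.uniform(0.8, 1.2)
            limit = 1.2 if a == "DETP" else 0.997
            cens = value < limit
            row[a] = limit if cens else value
            row[f"{a}_censored"] = int(cens)
            row[f"{a}_limit"] = limit
        row.update(
            urinary_creatinine=rng.uniform(50, 150),
            specific_gravity=1.015,
            serum_creatinine=0.55,
            age=30 + i,
            body_weight=rng.uniform(45, 65),
            bmi=21.0,
            sampling_month=f"2012-{i + 1:02d}",
        )
        rows.append(row)
    return pd.DataFrame(rows)
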