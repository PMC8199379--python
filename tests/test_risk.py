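"""Dose reconstruction: molar sums, RPFs, proportions, exceedance."""

import numpy as np
import pandas as pd
import pytest

from dapcra import (
    ParentOpp,
    RiskConfig,
    assess_cohort,
    classify_exceedance,
    cohort_dose_summary,
    compute_rpf,
    cumulative_dose,
    default_analytes,
    molar_excretion,
    release_weighted_proportions,
)

FENITROTHION = ParentOpp("fenitrothion", 277.23, 13.0, {2012: 100.0}, "dimethyl")


def toy_parents():
    return [
        ParentOpp("fenitrothion", 277.23, 13.0, {2011: 600, 2012: 590}, "dimethyl"),
        ParentOpp("methidathion", 302.33, 2.2, {2011: 60, 2012: 58}, "dimethyl"),
        ParentOpp("malathion", 330.36, 500.0, {2011: 80, 2012: 78}, "dimethyl"),
        ParentOpp("trichlorfon", 257.44, 50.0, {2011: 40, 2012: 39}, "dimethyl"),
        ParentOpp("dimethoate", 229.26, 25.0, {2011: 30, 2012: 29}, "dimethyl"),
        ParentOpp("pirimiphos-methyl", 305.33, 70.0, {2011: 10, 2012: 10}, "dimethyl"),
        ParentOpp("diazinon", 304.35, 52.0, {2011: 120, 2012: 115}, "diethyl"),
        ParentOpp("chlorpyrifos", 350.59, 76.0, {2011: 40, 2012: 38}, "diethyl"),
    ]


class TestMolarExcretion:
    def test_unit_fixture(self):
        """One analyte at its own molecular weight in ng/mL with a
        creatinine ratio of exactly 1 L/day gives 1 µmol/day."""
        umol = molar_excretion({"DMP": 126.05}, 1050.0, 1050.0, "dimethyl")
        assert umol == pytest.approx(1.0, rel=1e-12)

    def test_zero_concentrations(self):
        umol = molar_excretion({"DMP": 0.0, "DMTP": 0.0}, 1000.0, 1050.0, "dimethyl")
        assert umol == 0.0

    def test_halving_creatinine_doubles_result(self):
        a = molar_excretion({"DMP": 5.0}, 1000.0, 1050.0, "dimethyl")
        b = molar_excretion({"DMP": 5.0}, 500.0, 1050.0, "dimethyl")
        assert b == pytest.approx(2 * a)

    def test_dedtp_and_other_class_excluded(self):
        umol = molar_excretion(
            {"DMP": 126.05, "DEP": 154.1, "DEDTP": 186.24},
            1050.0, 1050.0, "dimethyl",
        )
        assert umol == pytest.approx(1.0, rel=1e-12)

    def test_nonpositive_creatinine_rejected(self):
        with pytest.raises(ValueError):
            molar_excretion({"DMP": 1.0}, 0.0, 1050.0, "dimethyl")


class TestProportions:
    def test_direct_proportion(self):
        parents = [
            ParentOpp("a", 250, 10, {2012: 100}, "dimethyl"),
            ParentOpp("b", 260, 10, {2012: 300}, "dimethyl"),
        ]
        p = release_weighted_proportions(parents, {2012: 1.0})
        assert p == {"a": pytest.approx(0.25), "b": pytest.approx(0.75)}

    def test_equal_releases_invariant_to_year_weights(self):
        parents = [
            ParentOpp("a", 250, 10, {2011: 50, 2012: 50}, "dimethyl"),
            ParentOpp("b", 260, 10, {2011: 150, 2012: 150}, "dimethyl"),
        ]
        p1 = release_weighted_proportions(parents, {2011: 0.9, 2012: 0.1})
        p2 = release_weighted_proportions(parents, {2011: 0.1, 2012: 0.9})
        assert p1["a"] == pytest.approx(p2["a"]) == pytest.approx(0.25)

    def test_hand_weighted_two_year_case(self):
        parents = [
            ParentOpp("a", 250, 10, {2011: 100, 2012: 0}, "dimethyl"),
            ParentOpp("b", 260, 10, {2011: 0, 2012: 100}, "dimethyl"),
        ]
        p = release_weighted_proportions(parents, {2011: 0.5, 2012: 0.5})
        assert p["a"] == pytest.approx(0.5) and p["b"] == pytest.approx(0.5)

    def test_per_class_shares_sum_to_one(self):
        p = release_weighted_proportions(toy_parents(), {2011: 0.4, 2012: 0.6})
        dm = sum(p[x.name] for x in toy_parents() if x.alkyl_class == "dimethyl")
        de = sum(p[x.name] for x in toy_parents() if x.alkyl_class == "diethyl")
        assert dm == pytest.approx(1.0) and de == pytest.approx(1.0)

    def test_all_zero_release_class_rejected(self):
        parents = [ParentOpp("a", 250, 10, {2012: 0.0}, "dimethyl")]
        with pytest.raises(ValueError, match="all-zero"):
            release_weighted_proportions(parents, {2012: 1.0})

    def test_bad_year_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            release_weighted_proportions(toy_parents(), {2011: 0.5})


class TestRpf:
    def test_reference_is_unity(self):
        assert compute_rpf(FENITROTHION, FENITROTHION) == 1.0

    def test_ratio_and_reciprocal(self):
        half = ParentOpp("x", 300, 6.5, {2012: 1}, "dimethyl")
        tenx = ParentOpp("y", 300, 130.0, {2012: 1}, "dimethyl")
        assert compute_rpf(half, FENITROTHION) == pytest.approx(2.0)
        assert compute_rpf(tenx, FENITROTHION) == pytest.approx(0.1)

    def test_orientation_switch(self):
        half = ParentOpp("x", 300, 6.5, {2012: 1}, "dimethyl")
        assert compute_rpf(half, FENITROTHION,
                           "chemical-over-reference") == pytest.approx(0.5)

    def test_common_rescaling_leaves_rpfs_unchanged(self):
        parents = toy_parents()
        ref = parents[0]
        scaled = [
            ParentOpp(p.name, p.molecular_weight, p.bmdl10 * 7.3,
                      p.annual_release, p.alkyl_class)
            for p in parents
        ]
        for p, q in zip(parents, scaled):
            assert compute_rpf(q, scaled[0]) == pytest.approx(
                compute_rpf(p, ref), rel=1e-12
            )


class TestCumulativeDose:
    def test_hand_fixture(self):
        """µMol_DM = 1, single DM parent (MW 277.23, RPF 1, P 1),
        BW 60 kg → 277.23/60 = 4.6205 µg/kg/day."""
        dm, de, total = cumulative_dose(
            1.0, 0.0, 60.0, [FENITROTHION], {"fenitrothion": 1.0},
            {"fenitrothion": 1.0},
        )
        assert total == pytest.approx(4.6205, abs=5e-5)
        assert de == 0.0

    def test_linearity(self):
        parents = toy_parents()
        p = release_weighted_proportions(parents, {2011: 0.5, 2012: 0.5})
        rpfs = {x.name: compute_rpf(x, parents[0]) for x in parents}
        _, _, d1 = cumulative_dose(1.0, 0.5, 60.0, parents, p, rpfs)
        _, _, d2 = cumulative_dose(2.0, 1.0, 60.0, parents, p, rpfs)
        _, _, d3 = cumulative_dose(1.0, 0.5, 120.0, parents, p, rpfs)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)
        assert d3 == pytest.approx(d1 / 2, rel=1e-12)

    def test_missing_parent_rejected(self):
        with pytest.raises(KeyError):
            cumulative_dose(1.0, 0.0, 60.0, [FENITROTHION], {}, {})


def independent_dcum(row, parents, year_weights, cr_ref=1050.0,
                     reference="fenitrothion"):
    """Single-expression oracle for the cumulative dose equations,
    written directly from the formulas with no shared pipeline code."""
    mw = {"DMP": 126.05, "DMTP": 142.11, "DMDTP": 158.18,
          "DEP": 154.10, "DETP": 170.17}
    ref_bmdl = next(p.bmdl10 for p in parents if p.name == reference)
    tw = {p.name: sum(p.annual_release.get(y, 0) * w
                      for y, w in year_weights.items()) for p in parents}
    cls_tot = {
        c: sum(tw[p.name] for p in parents if p.alkyl_class == c)
        for c in ("dimethyl", "diethyl")
    }
    cr_l = row["urinary_creatinine"] * 10.0
    umol = {
        "dimethyl": sum(row[a] / mw[a] for a in ("DMP", "DMTP", "DMDTP"))
        * cr_ref / cr_l,
        "diethyl": sum(row[a] / mw[a] for a in ("DEP", "DETP")) * cr_ref / cr_l,
    }
    return sum(
        umol[c]
        * sum((tw[p.name] / cls_tot[c]) * p.molecular_weight
              * (ref_bmdl / p.bmdl10)
              for p in parents if p.alkyl_class == c)
        / row["body_weight"]
        for c in ("dimethyl", "diethyl")
    )


class TestPipelineAgainstOracle:
    def test_ten_random_toy_participants(self):
        rng = np.random.default_rng(23)
        n = 10
        cohort = pd.DataFrame({
            "id": [f"T{i}" for i in range(n)],
            "DMP": rng.uniform(0.1, 20, n),
            "DMTP": rng.uniform(0.1, 40, n),
            "DMDTP": rng.uniform(0.05, 3, n),
            "DEP": rng.uniform(0.1, 15, n),
            "DETP": rng.uniform(0.05, 5, n),
            "urinary_creatinine": rng.uniform(30, 250, n),
            "body_weight": rng.uniform(42, 90, n),
            "sampling_month": rng.choice(["2011-06", "2012-06"], n),
        })
        parents = toy_parents()
        doses = assess_cohort(cohort, parents)
        years = cohort["sampling_month"].str[:4].astype(int)
        weights = years.value_counts(normalize=True).to_dict()
        for i, row in cohort.iterrows():
            expected = independent_dcum(row, parents, weights)
            got = doses["d_cum"].iloc[i]
            assert got == pytest.approx(expected, rel=1e-12)

    def test_additivity_to_machine_precision(self, cohort_2000):
        censored, _, _, _ = cohort_2000
        doses = assess_cohort(censored, toy_parents())
        np.testing.assert_allclose(
            doses["d_cum"], doses["d_cum_dm"] + doses["d_cum_de"], rtol=1e-14
        )


class TestExceedance:
    def make_doses(self, values):
        v = np.asarray(values, dtype=float)
        return pd.DataFrame({
            "id": [str(i) for i in range(len(v))],
            "d_cum": v, "d_cum_dm": v * 0.9, "d_cum_de": v * 0.1,
        })

    def test_threshold_comparisons(self):
        doses = self.make_doses([15.5, 0.45])
        out = classify_exceedance(doses, RiskConfig(comparison_level=13.0))
        assert out["n_exceed"] == 1
        assert out["exceeder_median"] == pytest.approx(15.5)

    def test_monotone_limits(self):
        doses = self.make_doses([0.1, 1.0, 5.0, 20.0])
        huge = classify_exceedance(doses, RiskConfig(comparison_level=1e9))
        tiny = classify_exceedance(doses, RiskConfig(comparison_level=1e-9))
        assert huge["n_exceed"] == 0 and tiny["n_exceed"] == 4

    def test_count_nonincreasing_in_level(self):
        rng = np.random.default_rng(4)
        doses = self.make_doses(np.exp(rng.normal(-0.8, 1.1, 500)))
        counts = [
            classify_exceedance(doses, RiskConfig(comparison_level=lv))["n_exceed"]
            for lv in (0.1, 0.5, 1.0, 5.0, 13.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_exceedance(self.make_doses([]))


class TestDoseSummary:
    def make_doses(self, values):
        v = np.asarray(values, dtype=float)
        return pd.DataFrame({
            "id": [str(i) for i in range(len(v))],
            "d_cum": v, "d_cum_dm": v * 0.9, "d_cum_de": v * 0.1,
        })

    def test_single_participant(self):
        s = cohort_dose_summary(self.make_doses([0.7]))
        assert s.loc["mean", "DAPs"] == pytest.approx(0.7)
        assert s.loc["p50", "DAPs"] == pytest.approx(0.7)
        assert np.isnan(s.loc["gsd", "DAPs"])

    def test_lognormal_gm_gsd_oracle(self):
        rng = np.random.default_rng(8)
        logs = rng.normal(-0.8, 1.0, 4000)
        s = cohort_dose_summary(self.make_doses(np.exp(logs)))
        assert s.loc["gm", "DAPs"] == pytest.approx(np.exp(logs.mean()), rel=1e-9)
        assert s.loc["gsd", "DAPs"] == pytest.approx(
            np.exp(logs.std(ddof=1)), rel=1e-9
        )
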