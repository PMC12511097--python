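import numpy as np
import pandas as pd
import pytest

from tradmod.measurement import (composite_stats, cronbach_alpha,
                                 discriminant_report, estimate_loadings,
                                 fornell_larcker, harman_single_factor,
                                 marker_check, reliability_report)
from tradmod.survey import SurveyDataset

from conftest import exact_cov_sample


def compound_symmetric(k, r):
    return np.full((k, k), r) + (1 - r) * np.eye(k)


class TestCronbachAlpha:
    def test_equicorrelated_closed_form(self):
        # 3 unit-variance items, pairwise r = 0.7 -> alpha = (3/2)(1 - 3/7.2)
        X = exact_cov_sample(compound_symmetric(3, 0.7), n=200, seed=1)
        assert cronbach_alpha(X) == pytest.approx(0.875, abs=1e-10)

    def test_uncorrelated_pair_is_zero(self):
        X = exact_cov_sample(np.eye(2), n=100, seed=2)
        assert cronbach_alpha(X) == pytest.approx(0.0, abs=1e-10)

    def test_identical_items_is_one(self):
        x = np.random.default_rng(3).normal(size=60)
        X = np.column_stack([x, x, x])
        assert cronbach_alpha(X) == pytest.approx(1.0)

    def test_matches_spearman_brown_when_standardized(self):
        k, r = 4, 0.55
        X = exact_cov_sample(compound_symmetric(k, r) * 2.3, n=150, seed=4)
        sb = k * r / (1 + (k - 1) * r)
        assert cronbach_alpha(X, standardized=True) == pytest.approx(sb, abs=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((10, 1)))
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((10, 3)))   # zero total variance


class TestCompositeStats:
    @pytest.mark.parametrize("lam,ave,cr", [
        ((0.8, 0.8, 0.8), 0.64, 5.76 / (5.76 + 1.08)),
        ((1.0, 1.0), 1.0, 1.0),
    ])
    def test_closed_forms(self, lam, ave, cr):
        out = composite_stats(lam)
        assert out["AVE"] == pytest.approx(ave, abs=1e-12)
        assert out["CR"] == pytest.approx(cr, abs=1e-12)

    def test_equal_loadings_reproduce_pi_row(self):
        lam = [np.sqrt(0.824)] * 3
        assert composite_stats(lam)["AVE"] == pytest.approx(0.824, abs=1e-12)

    def test_item_order_invariance(self):
        a = composite_stats([0.9, 0.7, 0.8])
        b = composite_stats([0.7, 0.8, 0.9])
        assert a["CR"] == pytest.approx(b["CR"], abs=1e-12)
        assert a["AVE"] == pytest.approx(b["AVE"], abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            composite_stats([])
        with pytest.raises(ValueError):
            composite_stats([1.2])


class TestFornellLarcker:
    def test_sqrt_ave_diagonal(self):
        rep = fornell_larcker(np.eye(2), {"PI": 0.824, "PB": 0.748},
                              names=["PI", "PB"])
        assert rep.table.loc["PI", "PI"] == pytest.approx(np.sqrt(0.824))
        assert round(rep.table.loc["PI", "PI"], 3) == 0.908

    def test_perfect_ave_always_passes(self):
        R = compound_symmetric(3, 0.8)
        rep = fornell_larcker(R, np.ones(3), names=list("ABC"))
        assert rep.all_pass

    def test_mfsc_fn_block_passes(self):
        R = np.array([[1.0, 0.237], [0.237, 1.0]])
        rep = fornell_larcker(R, {"MFSC": 0.710, "FN": 0.75},
                              names=["MFSC", "FN"])
        assert rep.all_pass

    def test_relabeling_invariance(self):
        R = np.array([[1, 0.5, 0.9], [0.5, 1, 0.2], [0.9, 0.2, 1.0]])
        aves = {"A": 0.7, "B": 0.6, "C": 0.5}
        rep = fornell_larcker(R, aves, names=list("ABC"))
        perm = [2, 0, 1]
        rep2 = fornell_larcker(R[np.ix_(perm, perm)],
                               {list("ABC")[i]: aves[list("ABC")[i]] for i in perm},
                               names=[list("ABC")[i] for i in perm])
        for a in "ABC":
            for b in "ABC":
                assert rep.verdicts.loc[a, b] == rep2.verdicts.loc[a, b]

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            fornell_larcker(np.eye(3), np.ones(2), names=list("ABC"))


class TestHarman:
    def test_single_common_factor_share(self):
        # loadings 0.9 -> inter-item r = 0.81; first eigenvalue of the
        # compound-symmetric matrix is 1 + (k-1) r
        k = 6
        rng = np.random.default_rng(5)
        f = rng.normal(size=10_000)
        X = 0.9 * f[:, None] + np.sqrt(1 - 0.81) * rng.normal(size=(10_000, k))
        expected = (1 + (k - 1) * 0.81) / k * 100
        assert harman_single_factor(pd.DataFrame(X)) == pytest.approx(
            expected, abs=2.0)

    def test_flat_spectrum_limit(self):
        k = 8
        X = exact_cov_sample(np.eye(k), n=500, seed=6)
        assert harman_single_factor(pd.DataFrame(X)) == pytest.approx(
            100.0 / k, abs=1e-8)

    def test_default_survey_below_majority(self, survey_corr):
        assert harman_single_factor(survey_corr) < 50.0


class TestMarker:
    def test_generator_default_passes(self, survey_corr):
        assert marker_check(survey_corr)["pass"]

    def test_duplicated_marker_fails(self, survey_corr):
        data = survey_corr.data.copy()
        for i in (1, 2, 3):
            data[f"MK{i}"] = data[f"CI{i}"]
        dup = SurveyDataset(data, survey_corr.construct_map)
        out = marker_check(dup)
        assert out["max_abs_r"] > 0.95 and not out["pass"]

    def test_independent_marker_tiny_at_scale(self, big_survey_corr):
        assert marker_check(big_survey_corr)["max_abs_r"] < 0.02

    def test_missing_marker(self, survey_corr):
        with pytest.raises(ValueError, match="marker"):
            marker_check(survey_corr, marker="NOPE")


class TestEstimation:
    def test_ave_recovered_from_generated_items(self, gen_corr):
        ds = gen_corr.sample(5000, seed=31)
        rel = reliability_report(ds, ["CI"])
        assert rel.loc["CI", "AVE"] == pytest.approx(0.778, abs=0.05)

    def test_loadings_recovered_in_continuous_mode(self, spec):
        from tradmod.generate import SurveyGenerator
        gen = SurveyGenerator(spec, regime="corr-matched", continuous=True)
        ds = gen.sample(20_000, seed=8)
        lam = estimate_loadings(ds.scored_items("ATT"))
        np.testing.assert_allclose(lam, np.sqrt(0.805), atol=0.02)

    def test_discriminant_report_reproduces_structure(self, survey_corr):
        rep = discriminant_report(survey_corr, ["CI", "MFSC", "ATT", "PP",
                                                "PI", "PB"])
        assert rep.kind == "composite"
        assert rep.all_pass
        # the estimated sqrt-AVE diagonal sits near the design diagonal
        assert rep.table.loc["PI", "PI"] == pytest.approx(0.908, abs=0.02)
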