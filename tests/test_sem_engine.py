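import numpy as np
import pandas as pd
import pytest

from tradmod.sem import SemModel, parse_model
from tradmod.sem.model import compile_model

from conftest import exact_cov_sample

TWO_FACTOR = """
F1 =~ x1 + x2 + x3
F2 =~ x4 + x5 + x6
F2 ~ F1
"""


def two_factor_population_cov(beta=0.6, lam=0.8):
    """Analytic covariance of the two-factor model with equal loadings."""
    lat = np.array([[1.0, beta], [beta, 1.0]])
    L = np.zeros((6, 2))
    L[:3, 0] = lam
    L[3:, 1] = lam
    return L @ lat @ L.T + np.eye(6) * (1 - lam ** 2)


def frame_cov(S, names):
    return pd.DataFrame(S, index=names, columns=names)


class TestParser:
    def test_lavaan_and_alias_spellings_agree(self):
        a = parse_model("F =~ x1 + x2\nY ~ F")
        b = parse_model("latent F =~ x1 x2\npath Y <- F")
        assert a.measurement["F"][0].name == b.measurement["F"][0].name
        assert a.regressions == b.regressions

    def test_fixed_and_labelled_terms(self):
        d = parse_model("F =~ 1*x1 + a*x2\nF ~~ 0.5*F")
        assert d.measurement["F"][0].fixed == 1.0
        assert d.measurement["F"][1].label == "a"
        assert d.covariances[0][2].fixed == 0.5

    def test_unparseable_line(self):
        with pytest.raises(ValueError, match="cannot parse"):
            parse_model("x1 x2 x3")


class TestCompile:
    def test_study_model_has_seven_structural_paths(self, survey_model):
        model = SemModel.from_survey(survey_model,
                                     __import__("tradmod.sem", fromlist=["STUDY_MODEL"]).STUDY_MODEL)
        paths = [p for p in model.compiled.params if p.block in ("B", "Gamma")]
        assert len(paths) == 7

    def test_just_identified_cfa_df_zero(self):
        S = frame_cov(two_factor_population_cov()[:3, :3], ["x1", "x2", "x3"])
        res = SemModel("F =~ x1 + x2 + x3", sample_cov=S, nobs=200).fit(se=False)
        assert res.df == 0
        assert res.chi2 == pytest.approx(0.0, abs=1e-6)

    def test_cyclic_model_rejected(self):
        S = frame_cov(np.eye(2) + 0.3 * (1 - np.eye(2)), ["x", "y"])
        with pytest.raises(ValueError, match="cyclic"):
            SemModel("x ~ y\ny ~ x", sample_cov=S, nobs=100)

    def test_latent_without_indicators_rejected(self):
        S = frame_cov(np.eye(2), ["x1", "x2"])
        with pytest.raises(ValueError, match="no indicators"):
            SemModel("F =~ x1 + x2\nG =~ ", sample_cov=S, nobs=100)

    def test_unknown_indicator_rejected(self):
        S = frame_cov(np.eye(2), ["x1", "x2"])
        with pytest.raises(ValueError, match="not in data"):
            SemModel("F =~ x1 + x9", sample_cov=S, nobs=100)


class TestGradient:
    @pytest.mark.parametrize("mean_structure", [False, True])
    def test_analytic_gradient_matches_finite_difference(self, mean_structure):
        rng = np.random.default_rng(0)
        X = exact_cov_sample(two_factor_population_cov(), 300, seed=1,
                             means=[0.3, -0.2, 0.1, 0.0, 0.5, -0.4])
        data = pd.DataFrame(X, columns=[f"x{i}" for i in range(1, 7)])
        model = SemModel(TWO_FACTOR, data=data, mean_structure=mean_structure)
        eng = model._engine
        theta = eng.start + rng.normal(0, 0.05, size=eng.n_free)
        theta[eng.is_variance] = np.abs(theta[eng.is_variance]) + 0.3
        f0, g = eng.objective_nat(theta)
        num = np.zeros_like(g)
        for k in range(len(theta)):
            h = 1e-6 * max(1, abs(theta[k]))
            tp = theta.copy(); tp[k] += h
            tm = theta.copy(); tm[k] -= h
            num[k] = (eng.objective_nat(tp)[0] - eng.objective_nat(tm)[0]) / (2 * h)
        np.testing.assert_allclose(g, num, rtol=2e-4, atol=2e-4)


class TestImpliedMoments:
    def test_observed_path_tracing(self):
        # x -> y with coefficient b and unit exogenous variance
        S = frame_cov(np.array([[1.0, 0.7], [0.7, 1.49]]), ["x", "y"])
        res = SemModel("y ~ x", sample_cov=S, nobs=500).fit(se=False)
        implied = res.implied_cov()
        assert implied.loc["x", "y"] == pytest.approx(0.7, abs=1e-6)
        assert res.params["y~x"] == pytest.approx(0.7, abs=1e-6)

    def test_zero_structural_paths_block_diagonal(self):
        S = frame_cov(two_factor_population_cov(beta=0.6),
                      [f"x{i}" for i in range(1, 7)])
        spec = "F1 =~ x1 + x2 + x3\nF2 =~ x4 + x5 + x6\nF1 ~~ 0*F2"
        res = SemModel(spec, sample_cov=S, nobs=500).fit(se=False)
        implied = res.implied_cov().to_numpy()
        np.testing.assert_allclose(implied[:3, 3:], 0.0, atol=1e-10)

    def test_self_consistency_at_optimum(self, survey_model):
        from tradmod.sem import STUDY_MODEL
        res = SemModel.from_survey(survey_model, STUDY_MODEL).fit(se=False)
        assert res.srmr() < 0.05


class TestPerfectFit:
    def test_zero_discrepancy_fixed_point(self):
        S0 = two_factor_population_cov(beta=0.6, lam=0.8)
        names = [f"x{i}" for i in range(1, 7)]
        res = SemModel(TWO_FACTOR, sample_cov=frame_cov(S0, names),
                       nobs=1000).fit(se=False)
        assert res.fml == pytest.approx(0.0, abs=1e-9)
        assert res.chi2 == pytest.approx(0.0, abs=1e-5)
        assert res.params["F2~F1"] == pytest.approx(0.6, abs=1e-4)
        assert res.params["F1=~x2"] == pytest.approx(1.0, abs=1e-4)
        fi = res.fit_indices()
        assert fi["CFI"] == pytest.approx(1.0)
        assert fi["RMSEA"] == 0.0
        assert fi["SRMR"] < 1e-5

    def test_standardized_single_path_r2(self):
        S0 = two_factor_population_cov(beta=0.6, lam=0.8)
        names = [f"x{i}" for i in range(1, 7)]
        res = SemModel(TWO_FACTOR, sample_cov=frame_cov(S0, names),
                       nobs=1000).fit(se=False)
        assert res.std_path("F2", "F1") == pytest.approx(0.6, abs=1e-4)
        assert res.rsquared["F2"] == pytest.approx(0.36, abs=1e-4)

    def test_duplicate_label_constrains_equality(self):
        S0 = two_factor_population_cov()
        names = [f"x{i}" for i in range(1, 7)]
        spec = "F1 =~ x1 + a*x2 + a*x3\nF2 =~ x4 + x5 + x6\nF2 ~ F1"
        res = SemModel(spec, sample_cov=frame_cov(S0, names), nobs=500).fit(se=False)
        sol = res.standardized_solution()
        lam = sol[(sol.op == "=~") & (sol.rhs.isin(["x2", "x3"]))]["estimate"]
        assert lam.nunique() == 1


class TestIndices:
    def test_independence_model_cfi_zero(self):
        S = frame_cov(np.array([[1.0, 0.5], [0.5, 1.0]]), ["x1", "x2"])
        res = SemModel("x1 ~~ x1\nx2 ~~ x2", sample_cov=S, nobs=300).fit(se=False)
        assert res.fit_indices()["CFI"] == pytest.approx(0.0, abs=1e-8)

    def test_omitted_cross_loading_lowers_cfi(self, spec):
        rng = np.random.default_rng(12)
        n = 1076
        f = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], size=n)
        lam = 0.8
        X = {}
        for i in range(3):
            X[f"x{i+1}"] = lam * f[:, 0] + 0.6 * rng.normal(size=n)
        for i in range(3):
            load2 = lam * f[:, 1]
            if i == 0:  # true cross-loading on F1
                load2 = load2 + 0.5 * f[:, 0]
            X[f"x{i+4}"] = load2 + 0.6 * rng.normal(size=n)
        data = pd.DataFrame(X)
        base = "F1 =~ x1 + x2 + x3\nF2 =~ x4 + x5 + x6"
        truth = base + "\nF1 =~ x4"
        cfi_mis = SemModel(base, data=data).fit(se=False).fit_indices()["CFI"]
        cfi_true = SemModel(truth, data=data).fit(se=False).fit_indices()["CFI"]
        assert cfi_mis < cfi_true

    def test_scale_invariance_of_standardized_solution(self, survey_model):
        from tradmod.sem import STUDY_MODEL
        frame = survey_model.scored_items().copy()
        frame["urban"] = (survey_model.data["location"] == "urban").astype(float)
        res1 = SemModel(STUDY_MODEL, data=frame).fit(se=False)
        frame2 = frame.copy()
        frame2["PI1"] = frame2["PI1"] * 10.0
        res2 = SemModel(STUDY_MODEL, data=frame2).fit(se=False)
        for pair in [("ATT", "CI"), ("PI", "ATT"), ("PB", "PI")]:
            assert res1.std_path(*pair) == pytest.approx(
                res2.std_path(*pair), abs=1e-4)
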