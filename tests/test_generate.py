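import io

import numpy as np
import pandas as pd
import pytest

from tradmod.generate import (SurveyGenerator, generate_respondents,
                              generate_survey, latent_to_likert,
                              structural_latent_cov)
from tradmod.population import build_population_spec


class TestStructuralConstruction:
    def test_single_path_covariance(self):
        order, cov, dist = structural_latent_cov({("Y", "X"): 0.6}, {})
        i, j = order.index("X"), order.index("Y")
        assert cov[i, j] == pytest.approx(0.6)
        assert dist["Y"] == pytest.approx(1 - 0.36)
        np.testing.assert_allclose(np.diag(cov), 1.0)

    def test_cyclic_graph_rejected(self):
        with pytest.raises(ValueError, match="cyclic"):
            structural_latent_cov({("A", "B"): 0.5, ("B", "A"): 0.5}, {})

    def test_overdetermined_variance_rejected(self):
        with pytest.raises(ValueError, match="systematic variance"):
            structural_latent_cov({("Y", "A"): 0.9, ("Y", "B"): 0.9},
                                  {("A", "B"): 0.9})


class TestRespondents:
    def test_determinism(self, spec):
        a = generate_respondents(spec, 200, seed=3)
        b = generate_respondents(spec, 200, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_minimum_n(self, spec):
        with pytest.raises(ValueError, match="n must be"):
            generate_respondents(spec, 1, seed=0)

    def test_urban_fraction_near_target(self, spec):
        lat = generate_respondents(spec, 1076, seed=5)
        frac = (lat["location"] == "urban").mean()
        assert frac == pytest.approx(0.546, abs=0.05)   # ~3 binomial SDs

    def test_zero_urban_effect_equalises_mfsc(self):
        s = build_population_spec({"urban_effect": 0.0})
        lat = generate_respondents(s, 60_000, seed=5)
        gap = (lat.loc[lat.location == "urban", "MFSC"].mean()
               - lat.loc[lat.location == "rural", "MFSC"].mean())
        assert abs(gap) < 0.03

    def test_urban_effect_shifts_mfsc_by_effect_sds(self, spec):
        lat = generate_respondents(spec, 120_000, seed=5)
        gap = (lat.loc[lat.location == "urban", "MFSC"].mean()
               - lat.loc[lat.location == "rural", "MFSC"].mean())
        assert gap == pytest.approx(spec.urban_effect, abs=0.03)

    def test_large_sample_latent_correlation(self, spec):
        lat = generate_respondents(spec, 100_000, seed=9)
        r = np.corrcoef(lat["CI"], lat["ATT"])[0, 1]
        assert r == pytest.approx(spec.corr("CI", "ATT"), abs=0.01)


class TestLikertMapping:
    def test_continuous_unit_loading_reproduces_latent(self, spec):
        lat = generate_respondents(spec, 500, seed=1)
        ds = latent_to_likert(lat, spec, seed=2,
                              loadings={c.name: 1.0 for c in spec.constructs},
                              continuous=True)
        ci = spec.construct("CI")
        expected = ci.mean + ci.sd * lat["CI"].to_numpy()
        np.testing.assert_allclose(ds.data["CI1"].to_numpy(), expected,
                                   atol=1e-10)

    def test_reverse_item_at_scale_maximum(self, spec):
        lat = generate_respondents(spec, 50, seed=1)
        lat["MFSC"] = 50.0      # far above every threshold
        ds = latent_to_likert(lat, spec, seed=2)
        assert (ds.data["MFSC1"] == 1).all()          # recorded reversed
        assert (ds.scored_items("MFSC")["MFSC1"] == 5).all()

    def test_responses_are_integer_categories(self, survey_model):
        items = survey_model.data[survey_model.item_names()]
        assert items.isin([1, 2, 3, 4, 5]).all().all()

    def test_missing_loading_named_in_error(self, spec):
        lat = generate_respondents(spec, 50, seed=1)
        bad = {c.name: c.loading for c in spec.constructs}
        bad["PI"] = None
        with pytest.raises(ValueError, match="PI"):
            latent_to_likert(lat, spec, seed=2, loadings=bad)

    def test_discretization_monotone_in_latent(self, spec):
        lat = generate_respondents(spec, 400, seed=4)
        higher = lat.copy()
        higher["CI"] = higher["CI"] + 0.8
        low = latent_to_likert(lat, spec, seed=6)
        high = latent_to_likert(higher, spec, seed=6)   # same noise stream
        for item in ("CI1", "CI2", "CI3"):
            assert (high.data[item] >= low.data[item]).all()


class TestGenerateSurvey:
    def test_pi_composite_mean_near_anchor(self, gen_model):
        ds = gen_model.sample(1076, seed=23)
        assert ds.composites()["PI"].mean() == pytest.approx(3.73, abs=0.1)

    def test_same_seed_byte_identical(self, tmp_path):
        out = []
        for _ in range(2):
            ds = generate_survey(n=150, seed=42)
            buf = io.StringIO()
            ds.data.to_csv(buf)
            out.append(buf.getvalue())
        assert out[0] == out[1]

    def test_marker_low_correlation(self, survey_corr):
        comps = survey_corr.composites()
        focal = [c for c in comps.columns if c != "MK"]
        assert comps[focal].corrwith(comps["MK"]).abs().max() < 0.15

    def test_composite_moment_recovery_at_scale(self, big_survey_corr, spec):
        comps = big_survey_corr.composites(list(spec.names))
        obs = comps.corr().to_numpy()
        err = np.abs(obs - spec.correlations)
        np.fill_diagonal(err, 0.0)
        assert err.max() < 0.02

    def test_model_generated_urban_gap_matches_path(self, gen_model):
        lat = gen_model.latents(150_000, seed=3)
        p = gen_model.spec.urban_proportion
        expected = gen_model.design.urban_corr[
            list(gen_model.spec.names).index("MFSC")] / np.sqrt(p * (1 - p))
        gap = (lat.loc[lat.location == "urban", "MFSC"].mean()
               - lat.loc[lat.location == "rural", "MFSC"].mean())
        assert gap == pytest.approx(expected, abs=0.03)

    def test_unknown_regime_rejected(self, spec):
        with pytest.raises(ValueError, match="regime"):
            SurveyGenerator(spec, regime="bootstrap")

    def test_survey_roundtrip(self, tmp_path, survey_model):
        path = tmp_path / "s.csv"
        survey_model.to_csv(path)
        from tradmod.survey import SurveyDataset
        back = SurveyDataset.read_csv(path)
        pd.testing.assert_frame_equal(
            back.data, survey_model.data, check_dtype=False)
        assert back.construct_map == survey_model.construct_map
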