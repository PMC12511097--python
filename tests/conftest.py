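import numpy as np
import pandas as pd
import pytest

from tradmod.generate import SurveyGenerator
from tradmod.population import default_spec


@pytest.fixture(scope="session")
def spec():
    return default_spec()


@pytest.fixture(scope="session")
def gen_model(spec):
    return SurveyGenerator(spec, regime="model-generated")


@pytest.fixture(scope="session")
def gen_corr(spec):
    return SurveyGenerator(spec, regime="corr-matched")


@pytest.fixture(scope="session")
def survey_model(gen_model):
    """One study-sized model-generated survey."""
    return gen_model.sample(1076, seed=7)


@pytest.fixture(scope="session")
def survey_corr(gen_corr):
    return gen_corr.sample(1076, seed=7)


@pytest.fixture(scope="session")
def big_survey_corr(gen_corr):
    """Large corr-matched survey for moment-recovery checks."""
    return gen_corr.sample(100_000, seed=11)


def exact_cov_sample(target_cov: np.ndarray, n: int, seed: int = 0,
                     means=None) -> np.ndarray:
    """n draws whose *sample* covariance equals target_cov exactly.

    Whitens a random sample empirically and recolours it with the target
    Cholesky factor - handy for testing closed-form statistics.
    """
    k = target_cov.shape[0]
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, k))
    X = X - X.mean(axis=0)
    S = np.cov(X, rowvar=False, ddof=1)
    X = X @ np.linalg.inv(np.linalg.cholesky(S)).T
    X = X @ np.linalg.cholesky(target_cov).T
    if means is not None:
        X = X + np.asarray(means)
    return X
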