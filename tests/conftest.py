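import pytest

from amuplan.mixrf import MixRFConfig, fit_mixrf
from amuplan.preprocess import preprocess
from amuplan.synthetic import SyntheticConfig, generate_farms

#: Small planted-effect design shared across test modules: 32 farms,
#: 4 countries, one harmful and one protective measure, low noise.
TINY = dict(n_countries=4, farms_per_country=8, n_features=6,
            true_effects={"q_001": 0.8, "q_002": -0.8},
            sigma_country=0.5, sigma_noise=0.2,
            zero_inflation=0.0, missing_rate=0.0, seed=7)

FAST_MIXRF = dict(n_trees=30, max_em_iter=3, seed=7)


@pytest.fixture(scope="session")
def tiny_table():
    return generate_farms(SyntheticConfig(**TINY))


@pytest.fixture(scope="session")
def tiny_data(tiny_table):
    X, y, groups, retained, report = preprocess(tiny_table)
    return X, y, groups


@pytest.fixture(scope="session")
def tiny_fit(tiny_data):
    X, y, groups = tiny_data
    return fit_mixrf(X, y, groups, config=MixRFConfig(**FAST_MIXRF))
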