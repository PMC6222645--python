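import numpy as np
import pytest

import quechers_rsm as q


@pytest.fixture(scope="session")
def space():
    return q.published_factor_space()


@pytest.fixture(scope="session")
def citrate_models():
    return q.load_published_models("citrate")


@pytest.fixture(scope="session")
def acetate_models():
    return q.load_published_models("acetate")


@pytest.fixture(scope="session")
def citrate_sigma0_table(space, citrate_models):
    """Noiseless recovery table on the published citrate surfaces."""
    spec = q.SimulationSpec(
        space=space,
        true_coefficients={c: m.coef_ for c, m in citrate_models.items()},
        noise_sd=0.0,
        seed=0,
    )
    return q.simulate_recoveries(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
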