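import numpy as np
import pytest

from mkmdose import (
    default_beam_model,
    compute_profile,
    optimize_weights,
    preset,
    table1_suite,
)


@pytest.fixture(scope="session")
def ray_params():
    return preset("ray2019")


@pytest.fixture(scope="session")
def nirs_params():
    return preset("nirs2015")


@pytest.fixture(scope="session")
def model():
    """The default deterministic beam-layer library (built once)."""
    return default_beam_model()


@pytest.fixture(scope="session")
def suite_results(model, ray_params):
    """Optimized plans and profiles for the whole evaluation suite."""
    out = {}
    for plan in table1_suite():
        optimized = optimize_weights(model, plan, ray_params)
        out[plan.name] = (
            optimized,
            compute_profile(model, optimized, ray_params),
        )
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
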