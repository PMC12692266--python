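import numpy as np
import pytest
from hypothesis import settings

import glycoforge as gf
from glycoforge.model import FITTED_ENZYMES

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model():
    return gf.default_model()


@pytest.fixture(scope="session")
def compiled(model):
    return gf.CompiledModel(model)


@pytest.fixture(scope="session")
def median_result(compiled):
    """Simulation at the shipped median enzyme totals."""
    return gf.simulate_sequential(compiled)


@pytest.fixture(scope="session")
def noisefree_subject(model, compiled):
    """A synthetic subject simulated from known enzyme totals, no noise."""
    rng = np.random.default_rng(42)
    truth = {e: model.totals[e] * rng.uniform(0.7, 1.3) for e in FITTED_ENZYMES}
    gp = gf.simulate_sequential(compiled, truth).gp
    return truth, gp


@pytest.fixture(scope="session")
def noisefree_fit(model, compiled, noisefree_subject):
    """Evolutionary fit of the noise-free subject (shared: fits are costly)."""
    _, gp = noisefree_subject
    return gf.personalize(gp, model, seed=1, compiled=compiled)
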