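import pytest
from hypothesis import HealthCheck, settings

import unzipmap as um

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def layout():
    """Canonical template: 800 bp, TF site 10 bp from the 601NPE edge."""
    return um.build_template(800, 10)


@pytest.fixture(scope="session")
def signature():
    return um.SignatureModel()


@pytest.fixture(scope="session")
def instrument():
    return um.InstrumentModel()


@pytest.fixture(scope="session")
def quiet_models():
    """Noiseless signature/instrument pair for exactness checks."""
    return um.SignatureModel().noiseless(), um.InstrumentModel().noiseless()


@pytest.fixture(scope="session")
def reference(layout, signature, instrument):
    return um.simulate_naked_reference(layout, signature, instrument, seed=1)


@pytest.fixture(scope="session")
def quiet_reference(layout, quiet_models):
    sig, ins = quiet_models
    return um.simulate_naked_reference(layout, sig, ins, seed=1)
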