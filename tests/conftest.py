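import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def template():
    from esiptkit.synthetic import default_template

    return default_template()


@pytest.fixture(scope="session")
def system3_pair():
    """A modest protein-environment-like ensemble pair with ground truth."""
    from esiptkit.synthetic import generate_paired_ensembles, preset_landscape

    return generate_paired_ensembles(preset_landscape("system3", n_frames=1500, seed=123))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
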