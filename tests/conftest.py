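import numpy as np
import pytest

from cinquant.synth import SynthConfig, generate_field


@pytest.fixture(scope="session")
def small_config():
    """Two-nucleus field, clean G1 conditions: fast unit-test workhorse."""
    return SynthConfig(
        field_shape=(17, 224, 224),
        n_nuclei=2,
        s_phase_fraction=0.0,
        g2_fraction=0.0,
        mn_rate=0.0,
        detritus_rate=0.0,
        nucleus_radius_um=4.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_field(small_config):
    return generate_field(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
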