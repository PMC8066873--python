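import numpy as np
import pytest

from nvcpipe.pipeline import PipelineConfig
from nvcpipe.synthetic import CouplingSpec, generate_subject

# Small problem sizes keep the unit suite fast; the acceptance tests run
# the full study-scale conditions.
SMALL = dict(duration_s=120.0, n_eeg_channels=32)


@pytest.fixture(scope="session")
def small_config():
    return PipelineConfig(duration_s=120.0, n_boot=500, seed=0)


@pytest.fixture(scope="session")
def coupled_subject():
    """One subject with a single strong theta-HbO coupling and low noise."""
    spec = CouplingSpec(
        beta_true={("theta", "hbo"): 0.5}, scalp_gain_long=0.2, noise_sd_od=0.001
    )
    return generate_subject(spec, age=70.0, label=0, seed=11, **SMALL)


@pytest.fixture(scope="session")
def null_subject():
    """A subject with no neural coupling at all."""
    spec = CouplingSpec(scalp_gain_long=0.2, noise_sd_od=0.001)
    return generate_subject(spec, age=70.0, label=1, seed=12, **SMALL)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
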