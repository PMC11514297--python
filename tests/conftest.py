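import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "fixed",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A tiny simulation config: 16 x 32 spectra after processing."""
    from echorecon import scaled_config

    return scaled_config()


@pytest.fixture(scope="session")
def single_peak_spectrum():
    """Noiseless absorptive spectrum with one decaying on-grid peak."""
    from echorecon import (ExponentialParams, SimConfig, process_spectrum,
                           synthesize_fid)

    cfg = SimConfig(n_indirect=16, n_direct=32, snr=np.inf)
    params = [ExponentialParams(1.0, 0.25, -0.125,
                                decay_indirect=20.0, decay_direct=10.0)]
    fid = synthesize_fid(params, cfg)
    return process_spectrum(fid)
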