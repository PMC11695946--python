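import numpy as np
import pytest

from cochlear_calcium.config import AnalysisConfig, SyntheticConfig
from cochlear_calcium import synthetic as syn


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def quiet_synth() -> SyntheticConfig:
    """Synthetic config with all activity and artifacts off."""
    s = SyntheticConfig()
    s.lambda_ind_per_min = 0.0
    s.wave_rate_per_min = 0.0
    s.artifact_rate_per_min = 0.0
    s.lambda_term_pillar_per_min = 0.0
    s.lambda_term_modiolar_per_min = 0.0
    s.photon_gain = 0.0
    return s


@pytest.fixture
def small_geometry(quiet_synth):
    return syn.generate_geometry(8, 9.0, 0.0, quiet_synth, seed=11)


def make_kernel_trace(times, amps, duration_s, frame_rate=30.0,
                      fdhm=1.5, tau_rise=0.05, noise_sd=0.0, seed=0):
    """A dF/F0 trace as a sum of indicator kernels plus white noise."""
    td = syn.decay_for_fdhm(fdhm, tau_rise)
    t = np.arange(int(duration_s * frame_rate)) / frame_rate
    x = np.zeros_like(t)
    for t0, a in zip(times, amps):
        x += a * syn.transient_kernel(t - t0, tau_rise, td)
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, x.shape)
    return x
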