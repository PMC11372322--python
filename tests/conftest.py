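import numpy as np
import pytest

from pulsekit import SimConfig, UniformSignal, generate_rr_series, synthesize_ppg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_signal(values, rate=30.0, start=0.0):
    return UniformSignal(start, rate, np.asarray(values, dtype=float))


@pytest.fixture
def clean_subject():
    """One 120 s noise-free recording (no dicrotic bump, no drift)."""
    cfg = SimConfig(duration_s=120, seed=11, ppg_noise_sd=0.0,
                    drift_amplitude=0.0, dicrotic_rel_amplitude=0.0)
    truth = generate_rr_series(cfg)
    return cfg, truth, synthesize_ppg(truth, cfg)
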