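import numpy as np
import pytest

from ffnquant import RegionKinetics, make_stimulus_protocol


@pytest.fixture
def train_10hz():
    """The standard train: 10 pulses at 10 Hz, onset 1 s."""
    return make_stimulus_protocol(10.0, 10, onset_s=1.0)


@pytest.fixture
def single_pulse():
    return make_stimulus_protocol(10.0, 1, onset_s=1.0)


@pytest.fixture
def probe_kinetics():
    """Single-pulse recovery probe: 10 % amplitude, instant rise, 1 s decay."""
    return RegionKinetics(
        baseline_f0=1000.0,
        bleach_slope=0.005,
        amplitude_per_pulse=10.0,
        rise_tau_s=0.0,
        decay_tau_s=1.0,
        facilitation_per_pulse=0.0,
        recovery_tau_s=60.0,
    )


@pytest.fixture
def exp_decay_trace():
    """Noiseless exponential %dF/F transient factory."""

    def _make(tau_s, amp_pct=10.0, onset_s=1.0, rate_hz=10.0, duration_s=8.0):
        t = np.arange(int(duration_s * rate_hz)) / rate_hz
        v = np.where(t >= onset_s, amp_pct * np.exp(-(t - onset_s) / tau_s), 0.0)
        return t, v

    return _make
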