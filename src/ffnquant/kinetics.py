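"""Transient kinetics: pulse-resolved derivatives and decay times.

Two complementary views of transient shape. The frame-wise first difference
of the %dF/F trace ("derivative", one 100 ms bin per frame interval at the
default 10 Hz) resolves the contribution of individual electrical pulses; at
50 Hz stimulation several pulses share a frame interval and hence a bin. The
decay of the transient after its post-stimulus peak is summarized by a
log-linear fit: the time for the fitted exponential to fall to a floor
fraction (10 % by default) of the peak, the fitted log-slope, and the
goodness of fit (r squared) of the log-transformed trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .extraction import DFFTrace
from .protocols import StimulusProtocol

__all__ = [
    "DerivativeTrace",
    "DecayResult",
    "pulse_binned_derivative",
    "derivative_at_landmarks",
    "decay_metrics",
]


@dataclass
class DerivativeTrace:
    """First difference of %dF/F per frame interval.

    ``values[i]`` is the change over ``[bin_times_s[i], bin_times_s[i] + dt]``
    in %dF/F per bin; length is one less than the trace.
    """

    bin_times_s: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class DecayResult:
    """Log-linear decay summary of a transient.

    ``decay_time_s`` is the time for the fitted exponential to fall from the
    post-stimulus peak to ``floor_fraction`` of it (with the default floor of
    0.10 this equals ``tau * ln 10``); ``log_slope`` is in 1/s (negative for
    a decaying transient); ``r_squared`` measures the fit on log-values.
    """

    decay_time_s: float
    log_slope: float
    r_squared: float
    fit_window_s: tuple[float, float]
    peak_pct: float
    peak_time_s: float

    @property
    def tau_s(self) -> float:
        """Fitted exponential time constant, -1/log_slope."""
        return -1.0 / self.log_slope


def pulse_binned_derivative(
    dff: DFFTrace, protocol: StimulusProtocol | None = None
) -> DerivativeTrace:
    """Frame-interval first difference of the %dF/F trace.

    The cumulative sum of the returned values reconstructs the trace exactly
    up to its first sample. When stimulation is faster than the frame rate,
    all pulses within one frame interval contribute to the same bin.
    """
    if len(dff) < 2:
        raise ValueError("need at least 2 samples to differentiate")
    return DerivativeTrace(dff.times_s[:-1].copy(), np.diff(dff.values))


def _bin_index(times: np.ndarray, target: float, dt: float) -> int:
    idx = int(np.argmin(np.abs(times - target)))
    if abs(times[idx] - target) > dt / 2 + 1e-9:
        raise ValueError(f"no derivative bin starts near t = {target:g} s")
    return idx


def derivative_at_landmarks(
    dff: DFFTrace,
    protocol: StimulusProtocol,
    bin_s: float = 0.1,
) -> tuple[float, float, float]:
    """Derivative in three 100-ms landmark bins.

    Returns the %dF/F change over the bin starting 100 ms before stimulation,
    the bin starting at the first pulse, and the bin starting at the second
    pulse. Requires a protocol with at least two pulses and a frame rate able
    to resolve the bins.
    """
    if protocol.n_pulses < 2:
        raise ValueError("landmark analysis needs at least 2 pulses")
    deriv = pulse_binned_derivative(dff, protocol)
    dt = dff.frame_interval_s
    if bin_s < dt - 1e-9:
        raise ValueError("bin width is below the frame interval")
    t = deriv.bin_times_s
    i_pre = _bin_index(t, protocol.onset_s - bin_s, dt)
    i_p1 = _bin_index(t, protocol.pulse_times_s[0], dt)
    i_p2 = _bin_index(t, protocol.pulse_times_s[1], dt)
    return (
        float(deriv.values[i_pre]),
        float(deriv.values[i_p1]),
        float(deriv.values[i_p2]),
    )


def decay_metrics(
    dff: DFFTrace,
    protocol: StimulusProtocol,
    floor_fraction: float = 0.10,
    peak_window_tail_s: float = 0.5,
) -> DecayResult:
    """Fit the post-peak decay of a transient on a log scale.

    The peak is the maximum %dF/F between stimulus onset and half a second
    after the last pulse (earliest frame wins ties). The fit covers the
    contiguous run of samples from the peak until the trace first drops to
    ``floor_fraction * peak``; restricting to this run keeps late noise-floor
    samples (and non-positive values, which have no logarithm) out of the
    fit. ``decay_time_s = ln(1/floor_fraction) / (-log_slope)``: the time for
    the fitted exponential to fall from the peak to the floor.

    Raises if the peak is non-positive or fewer than 3 samples are available
    for the fit; a non-decaying fit (slope >= 0) yields an infinite decay
    time rather than an error.
    """
    if not 0 < floor_fraction < 1:
        raise ValueError("floor_fraction must be in (0, 1)")
    t = dff.times_s
    v = dff.values
    win = (t >= protocol.onset_s - 1e-9) & (
        t <= protocol.last_pulse_s + peak_window_tail_s + 1e-9
    )
    if not np.any(win):
        raise ValueError("peak window contains no samples")
    idx_win = np.flatnonzero(win)
    peak_rel = int(np.argmax(v[idx_win]))  # argmax takes the earliest maximum
    i_peak = idx_win[peak_rel]
    peak = float(v[i_peak])
    if peak <= 0:
        raise ValueError("non-positive post-stimulus peak")
    floor = floor_fraction * peak
    i_end = i_peak
    while i_end + 1 < len(v) and v[i_end + 1] > floor:
        i_end += 1
    sel = slice(i_peak, i_end + 1)
    tt, vv = t[sel], v[sel]
    if tt.size < 3:
        raise ValueError("fewer than 3 samples above the decay floor")
    log_v = np.log(vv)
    slope, intercept = np.polyfit(tt, log_v, deg=1)
    pred = slope * tt + intercept
    ss_res = float(np.sum((log_v - pred) ** 2))
    ss_tot = float(np.sum((log_v - log_v.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if slope < 0:
        decay_time = math.log(1.0 / floor_fraction) / (-slope)
    else:
        decay_time = math.inf
    return DecayResult(
        decay_time_s=float(decay_time),
        log_slope=float(slope),
        r_squared=float(r2),
        fit_window_s=(float(tt[0]), float(tt[-1])),
        peak_pct=peak,
        peak_time_s=float(t[i_peak]),
    )
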