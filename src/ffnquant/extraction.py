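"""Whole-field %dF/F extraction and AUC scoring.

The analysis unit is a field of view: every frame of a movie is collapsed to
its mean pixel intensity, a line is fitted to the 500 ms of data immediately
before stimulation, and the trace is expressed as percent change relative to
that extrapolated baseline. Transient size is the trapezoidal integral of the
%dF/F trace over the stimulus window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocols import StimulusProtocol

__all__ = [
    "RawTrace",
    "BaselineModel",
    "DFFTrace",
    "MeanTrace",
    "frame_mean_trace",
    "fit_baseline",
    "compute_dff",
    "auc",
    "average_transients",
    "extract_dff",
]

_TOL = 1e-9


def _check_uniform(times: np.ndarray) -> None:
    if times.size >= 2:
        gaps = np.diff(times)
        if np.max(np.abs(gaps - gaps[0])) > 1e-6:
            raise ValueError("trace times must be uniformly spaced")


@dataclass
class RawTrace:
    """Mean frame intensity over time, in arbitrary fluorescence units."""

    times_s: np.ndarray
    values: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape or self.times_s.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if np.any(self.values < 0):
            raise ValueError("raw fluorescence values must be non-negative")
        _check_uniform(self.times_s)

    def __len__(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class BaselineModel:
    """Linear fit to the pre-stimulus fluorescence: B(t) = slope*t + intercept."""

    slope: float
    intercept: float
    fit_window_s: tuple[float, float]

    def predict(self, times_s: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(times_s, dtype=float) + self.intercept


@dataclass
class DFFTrace:
    """Baseline-corrected trace in percent dF/F."""

    times_s: np.ndarray
    values: np.ndarray
    protocol: StimulusProtocol | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape or self.times_s.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        _check_uniform(self.times_s)

    @property
    def frame_interval_s(self) -> float:
        if self.times_s.size < 2:
            raise ValueError("need at least two samples")
        return float(self.times_s[1] - self.times_s[0])

    def __len__(self) -> int:
        return self.times_s.size


@dataclass
class MeanTrace:
    """Pointwise mean +/- SEM across repeated %dF/F traces."""

    times_s: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int


def frame_mean_trace(movie) -> RawTrace:
    """Collapse a movie to the arithmetic mean of all pixels per frame."""
    frames = np.asarray(movie.frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("movie must be a non-empty T x H x W stack")
    rate = float(movie.frame_rate_hz)
    times = np.arange(frames.shape[0]) / rate
    return RawTrace(times, frames.mean(axis=(1, 2)), rate)


def fit_baseline(
    raw: RawTrace,
    protocol: StimulusProtocol,
    window_s: float = 0.5,
) -> BaselineModel:
    """Ordinary least-squares line over the pre-stimulus window.

    The fit uses samples with ``onset - window_s <= t < onset`` (the data
    immediately prior to stimulation; the default window is 500 ms).
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    onset = protocol.onset_s
    mask = (raw.times_s >= onset - window_s - _TOL) & (raw.times_s < onset - _TOL)
    if np.count_nonzero(mask) < 2:
        raise ValueError(
            f"need >= 2 samples in [{onset - window_s:g}, {onset:g}) to fit baseline"
        )
    slope, intercept = np.polyfit(raw.times_s[mask], raw.values[mask], deg=1)
    return BaselineModel(float(slope), float(intercept), (onset - window_s, onset))


def compute_dff(
    raw: RawTrace,
    baseline: BaselineModel,
    protocol: StimulusProtocol | None = None,
) -> DFFTrace:
    """Percent dF/F: ``100 * (raw(t) - B(t)) / B(t)``.

    The fitted line is extrapolated over the whole trace, so a linear
    photobleaching drift is cancelled exactly.
    """
    b = baseline.predict(raw.times_s)
    if np.any(b <= 0):
        raise ValueError("fitted baseline is non-positive somewhere on the trace")
    return DFFTrace(raw.times_s.copy(), 100.0 * (raw.values - b) / b, protocol)


def auc(
    dff: DFFTrace,
    window_s: tuple[float, float],
    abscissa: str = "seconds",
) -> float:
    """Trapezoidal integral of %dF/F over a time window.

    Samples with ``start <= t <= end`` form the integration nodes; adjacent
    windows that share a boundary sample therefore add exactly
    (``auc(a,b) + auc(b,c) == auc(a,c)``).

    Parameters
    ----------
    window_s
        (start, end) in seconds.
    abscissa
        ``"seconds"`` (result in %dF/F * s) or ``"frames"`` (the abscissa is
        the frame index, matching analyses that integrate over frame number).
    """
    start, end = window_s
    if end <= start:
        raise ValueError("window end must exceed start")
    t = dff.times_s
    if start < t[0] - _TOL or end > t[-1] + _TOL:
        raise ValueError("AUC window extends outside the trace support")
    mask = (t >= start - _TOL) & (t <= end + _TOL)
    if np.count_nonzero(mask) < 2:
        raise ValueError("AUC window must contain at least two samples")
    if abscissa == "seconds":
        x = t[mask]
    elif abscissa == "frames":
        x = t[mask] * (1.0 / dff.frame_interval_s)
    else:
        raise ValueError(f"unknown abscissa dialect: {abscissa!r}")
    return float(np.trapezoid(dff.values[mask], x))


def stimulus_window(
    protocol: StimulusProtocol, tail_s: float = 0.0
) -> tuple[float, float]:
    """Default AUC window: the stimulus period, onset to last pulse (+tail)."""
    return (protocol.onset_s, protocol.last_pulse_s + tail_s)


def average_transients(traces: list[DFFTrace]) -> MeanTrace:
    """Pointwise mean and SEM (sample SD / sqrt(n)) across traces.

    All traces must share the same time base (and protocol, when set).
    """
    if not traces:
        raise ValueError("need at least one trace")
    t0 = traces[0].times_s
    for tr in traces[1:]:
        if tr.times_s.shape != t0.shape or np.max(np.abs(tr.times_s - t0)) > 1e-6:
            raise ValueError("traces have mismatched time bases")
        if (
            tr.protocol is not None
            and traces[0].protocol is not None
            and tr.protocol != traces[0].protocol
        ):
            raise ValueError("traces have mismatched protocols")
    stack = np.vstack([tr.values for tr in traces])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    if n > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros_like(mean)
    return MeanTrace(t0.copy(), mean, sem, n)


def extract_dff(movie, baseline_window_s: float = 0.5) -> DFFTrace:
    """Movie -> frame-mean trace -> baseline fit -> %dF/F, in one call."""
    if movie.protocol is None:
        raise ValueError("movie has no stimulus protocol attached")
    raw = frame_mean_trace(movie)
    model = fit_baseline(raw, movie.protocol, baseline_window_s)
    return compute_dff(raw, model, movie.protocol)
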