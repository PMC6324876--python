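"""Generative models of evoked FFN102 imaging experiments.

Every analysis stage in this package can be exercised against data with
known ground truth. The generator emulates the structure of the slice
experiments: a bleaching baseline, pulse-evoked %dF/F transients whose
kinetics differ by region (sustained in striatum, brief "flashes" in the
GPe), calcium-dependent amplitudes with saturation, frequency-dependent
facilitation, inter-train recovery, punctate baseline anatomy, and pixel
noise.

The evoked transient is a sum of per-pulse kernels::

    dff_true(t) = sum_p A_p * h(t - t_p)          [percent dF/F]
    raw(t)      = B(t) * (1 + dff_true(t) / 100) + noise

where ``B(t) = F0 * (1 - bleach_slope * t)`` is the bleaching baseline and
``h`` is a difference-of-exponentials kernel normalized to unit peak. Pulse
amplitudes combine a Hill-type calcium dependence, short-term facilitation
that decays between pulses (so closely spaced, high-frequency pulses
facilitate more), and first-order recovery since the previous train.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .extraction import RawTrace
from .protocols import StimulusProtocol, make_stimulus_protocol
from .spatial import FieldOfViewRecord, SliceSession

__all__ = [
    "RegionKinetics",
    "GroundTruth",
    "Movie",
    "region_kinetics",
    "hill_saturation",
    "transient_kernel",
    "pulse_amplitudes",
    "recovery_fraction",
    "simulate_trace",
    "simulate_movie",
    "simulate_slice_session",
]


@dataclass(frozen=True)
class RegionKinetics:
    """Phenomenological release/kinetics parameters for one region.

    Attributes
    ----------
    baseline_f0
        Resting whole-field fluorescence (arbitrary units).
    bleach_slope
        Linear photobleaching, fraction of F0 lost per second.
    amplitude_per_pulse
        Single-pulse %dF/F amplitude at saturating calcium, before
        facilitation/recovery scaling.
    rise_tau_s, decay_tau_s
        Kernel time constants; ``rise_tau_s = 0`` means an instantaneous rise.
    facilitation_per_pulse
        Strength of short-term facilitation (dimensionless, >= 0).
    facilitation_tau_s
        Facilitation decays between pulses with this time constant, making
        facilitation frequency-dependent.
    recovery_tau_s
        First-order recovery of releasable amplitude between trains.
    ca_ec50_mM, ca_hill
        Hill-type dependence of release on extracellular calcium.
    """

    baseline_f0: float = 1000.0
    bleach_slope: float = 0.005
    amplitude_per_pulse: float = 1.0
    rise_tau_s: float = 0.01
    decay_tau_s: float = 4.0
    facilitation_per_pulse: float = 0.0
    facilitation_tau_s: float = 0.04
    recovery_tau_s: float = 60.0
    ca_ec50_mM: float = 1.0
    ca_hill: float = 2.0

    def __post_init__(self) -> None:
        if self.baseline_f0 <= 0:
            raise ValueError("baseline_f0 must be positive")
        if self.decay_tau_s <= 0 or self.recovery_tau_s <= 0:
            raise ValueError("time constants must be positive")
        if self.rise_tau_s < 0 or self.rise_tau_s >= self.decay_tau_s:
            raise ValueError("need 0 <= rise_tau_s < decay_tau_s")
        if self.facilitation_tau_s <= 0:
            raise ValueError("facilitation_tau_s must be positive")
        if self.amplitude_per_pulse < 0 or self.facilitation_per_pulse < 0:
            raise ValueError("amplitude and facilitation must be >= 0")
        if self.ca_ec50_mM <= 0 or self.ca_hill <= 0:
            raise ValueError("ca_ec50_mM and ca_hill must be positive")


# Region presets. Striatum: dense innervation, large sustained transients
# (long decay), no facilitation, slow (~60 s) inter-train recovery. GPe:
# sparse innervation, small flash-like transients (sub-second decay), strong
# frequency-dependent facilitation, fast (~10 s) recovery. Amplitudes are set
# so that at standard 2.4 mM calcium the first-pulse 100-ms rise is ~0.8 %
# (striatum) and ~0.2 % (GPe); the GPe decay constant puts the noiseless
# decay-to-10 % time near 2.2 s. Rise and facilitation time constants are
# fast relative to a 100 ms frame so the first-pulse bin carries the largest
# derivative while high-frequency trains still facilitate.
_PRESETS: dict[str, RegionKinetics] = {
    "striatum": RegionKinetics(
        baseline_f0=1000.0,
        bleach_slope=0.005,
        amplitude_per_pulse=1.0,
        rise_tau_s=0.01,
        decay_tau_s=4.0,
        facilitation_per_pulse=0.0,
        facilitation_tau_s=0.04,
        recovery_tau_s=60.0,
    ),
    "GPe": RegionKinetics(
        baseline_f0=600.0,
        bleach_slope=0.005,
        amplitude_per_pulse=0.24,
        rise_tau_s=0.01,
        decay_tau_s=0.95,
        facilitation_per_pulse=0.8,
        facilitation_tau_s=0.04,
        recovery_tau_s=10.0,
    ),
}


def region_kinetics(region: str) -> RegionKinetics:
    """Return the kinetics preset for ``"striatum"`` or ``"GPe"``."""
    try:
        return _PRESETS[region]
    except KeyError:
        raise ValueError(
            f"unknown region {region!r}; presets: {sorted(_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put into a simulated recording."""

    amplitudes_pct: tuple[float, ...]
    decay_tau_s: float
    noise_sd: float
    seed: int
    puncta_positions_px: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes_pct):
            raise ValueError("true amplitudes must be >= 0")

    @property
    def puncta_count(self) -> int:
        return len(self.puncta_positions_px)

    @property
    def total_amplitude_pct(self) -> float:
        return float(sum(self.amplitudes_pct))


@dataclass
class Movie:
    """A T x H x W fluorescence stack with acquisition metadata."""

    frames: np.ndarray
    frame_rate_hz: float = 10.0
    pixel_size_um: float = 50.0 / 64.0
    region_label: str = "GPe"
    protocol: StimulusProtocol | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a T x H x W array")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration_s(self) -> float:
        return self.frames.shape[0] / self.frame_rate_hz


def hill_saturation(calcium_mM: float, ec50_mM: float = 1.0, hill: float = 2.0) -> float:
    """Hill function c^h / (c^h + EC50^h); 0 at zero calcium, ->1 saturating."""
    if calcium_mM < 0:
        raise ValueError("calcium_mM must be >= 0")
    if calcium_mM == 0:
        return 0.0
    ch = calcium_mM**hill
    return float(ch / (ch + ec50_mM**hill))


def transient_kernel(
    t_s: np.ndarray, rise_tau_s: float, decay_tau_s: float
) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak.

    ``h(t) = (exp(-t/tau_d) - exp(-t/tau_r)) / peak`` for ``t >= 0`` and 0
    before; with ``rise_tau_s == 0`` this degenerates to a step-and-decay
    ``exp(-t/tau_d)`` whose peak (=1) sits at t = 0.
    """
    t = np.asarray(t_s, dtype=float)
    h = np.zeros_like(t)
    pos = t >= 0
    if rise_tau_s == 0:
        h[pos] = np.exp(-t[pos] / decay_tau_s)
        return h
    if not rise_tau_s < decay_tau_s:
        raise ValueError("rise_tau_s must be smaller than decay_tau_s")
    t_peak = (
        rise_tau_s * decay_tau_s / (decay_tau_s - rise_tau_s)
    ) * math.log(decay_tau_s / rise_tau_s)
    peak = math.exp(-t_peak / decay_tau_s) - math.exp(-t_peak / rise_tau_s)
    h[pos] = (np.exp(-t[pos] / decay_tau_s) - np.exp(-t[pos] / rise_tau_s)) / peak
    return h


def recovery_fraction(dt_s: float, recovery_tau_s: float) -> float:
    """Fraction of releasable amplitude recovered ``dt_s`` after a train."""
    if dt_s < 0:
        raise ValueError("dt_s must be >= 0")
    return float(1.0 - math.exp(-dt_s / recovery_tau_s))


def pulse_amplitudes(
    kinetics: RegionKinetics,
    protocol: StimulusProtocol,
    calcium_mM: float = 2.4,
    time_since_prev_train_s: float | None = None,
) -> np.ndarray:
    """True per-pulse %dF/F amplitudes A_p.

    ``A_p = amplitude * hill(Ca) * recovery * (1 + f * sum_{q<p}
    exp(-(t_p - t_q)/tau_f))``. The facilitation sum makes amplitude
    frequency-dependent: the shorter the inter-pulse intervals, the larger
    every pairwise term, so the train total strictly increases with frequency
    whenever ``facilitation_per_pulse > 0``.
    """
    ca = hill_saturation(calcium_mM, kinetics.ca_ec50_mM, kinetics.ca_hill)
    rec = (
        1.0
        if time_since_prev_train_s is None
        else recovery_fraction(time_since_prev_train_s, kinetics.recovery_tau_s)
    )
    pt = np.asarray(protocol.pulse_times_s, dtype=float)
    fac = np.ones(pt.size)
    if kinetics.facilitation_per_pulse > 0:
        for p in range(1, pt.size):
            fac[p] = 1.0 + kinetics.facilitation_per_pulse * np.sum(
                np.exp(-(pt[p] - pt[:p]) / kinetics.facilitation_tau_s)
            )
    return kinetics.amplitude_per_pulse * ca * rec * fac


def simulate_trace(
    kinetics: RegionKinetics,
    protocol: StimulusProtocol,
    calcium_mM: float = 2.4,
    duration_s: float | None = None,
    frame_rate_hz: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    time_since_prev_train_s: float | None = None,
) -> tuple[RawTrace, GroundTruth]:
    """Simulate a whole-field fluorescence trace for one stimulus train.

    Returns the raw trace (bleaching baseline + evoked transient + Gaussian
    noise, clipped at zero) and the ground truth used to build it. When
    ``duration_s`` is None the recording covers the protocol plus a decay
    tail of five decay time constants.
    """
    if calcium_mM < 0:
        raise ValueError("calcium_mM must be >= 0")
    if duration_s is None:
        duration_s = protocol.last_pulse_s + 5.0 * kinetics.decay_tau_s + 0.5
    if protocol.last_pulse_s >= duration_s:
        raise ValueError("protocol extends beyond the trace duration")
    n = int(round(duration_s * frame_rate_hz))
    times = np.arange(n) / frame_rate_hz
    baseline = kinetics.baseline_f0 * (1.0 - kinetics.bleach_slope * times)
    if np.any(baseline <= 0):
        raise ValueError("bleaching drives the baseline non-positive; shorten trace")
    amps = pulse_amplitudes(kinetics, protocol, calcium_mM, time_since_prev_train_s)
    dff_true = np.zeros(n)
    for a_p, t_p in zip(amps, protocol.pulse_times_s):
        dff_true += a_p * transient_kernel(
            times - t_p, kinetics.rise_tau_s, kinetics.decay_tau_s
        )
    raw = baseline * (1.0 + dff_true / 100.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        raw = raw + rng.normal(0.0, noise_sd, size=n)
        raw = np.clip(raw, 0.0, None)
    truth = GroundTruth(
        amplitudes_pct=tuple(float(a) for a in amps),
        decay_tau_s=kinetics.decay_tau_s,
        noise_sd=float(noise_sd),
        seed=int(seed),
    )
    return RawTrace(times, raw, frame_rate_hz), truth


def _punctum_image(
    shape: tuple[int, int],
    positions: np.ndarray,
    sigma_px: float,
    contrast: float,
) -> np.ndarray:
    """Background-normalized image: 1 + sum of Gaussian puncta of given contrast."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.ones((h, w))
    for x0, y0 in positions:
        img += contrast * np.exp(
            -((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma_px**2)
        )
    return img


def simulate_movie(
    kinetics: RegionKinetics,
    protocol: StimulusProtocol,
    puncta_count: int = 12,
    punctum_sigma_px: float = 1.5,
    punctum_contrast: float = 4.0,
    calcium_mM: float = 2.4,
    shape: tuple[int, int] = (64, 64),
    duration_s: float | None = None,
    frame_rate_hz: float = 10.0,
    noise_model: str = "gaussian",
    noise_sd: float = 0.0,
    seed: int = 0,
    region_label: str = "GPe",
    puncta_positions: np.ndarray | None = None,
) -> tuple[Movie, GroundTruth]:
    """Simulate a 64 x 64 px movie at 10 Hz (defaults).

    The movie is a static punctate baseline image bleaching linearly, plus a
    spatially uniform (diffuse) evoked flash whose frame mean reproduces
    :func:`simulate_trace` exactly at zero noise, plus per-pixel noise.

    ``noise_model`` is one of ``"none"``, ``"gaussian"`` (additive, SD
    ``noise_sd`` per pixel) or ``"poisson"`` (shot noise; pixel values are
    treated as expected photon counts).
    """
    if puncta_count < 0:
        raise ValueError("puncta_count must be >= 0")
    if noise_model not in ("none", "gaussian", "poisson"):
        raise ValueError(f"unknown noise_model: {noise_model!r}")
    h, w = shape
    rng = np.random.default_rng(seed)
    if puncta_positions is None:
        margin = 2.0 * punctum_sigma_px
        if puncta_count > 0 and (margin >= w - 1 - margin or margin >= h - 1 - margin):
            raise ValueError("puncta do not fit inside the frame")
        positions = np.column_stack(
            [
                rng.uniform(margin, w - 1 - margin, size=puncta_count),
                rng.uniform(margin, h - 1 - margin, size=puncta_count),
            ]
        )
    else:
        positions = np.atleast_2d(np.asarray(puncta_positions, dtype=float))
        if positions.shape[0] != puncta_count:
            raise ValueError("puncta_positions length must equal puncta_count")
        if positions.size and (
            positions[:, 0].min() < 0
            or positions[:, 0].max() > w - 1
            or positions[:, 1].min() < 0
            or positions[:, 1].max() > h - 1
        ):
            raise ValueError("punctum placed outside the frame")

    raw, truth = simulate_trace(
        kinetics,
        protocol,
        calcium_mM=calcium_mM,
        duration_s=duration_s,
        frame_rate_hz=frame_rate_hz,
        noise_sd=0.0,
        seed=seed,
    )
    times = raw.times_s
    f0 = kinetics.baseline_f0
    bleach_t = 1.0 - kinetics.bleach_slope * times
    base = _punctum_image((h, w), positions, punctum_sigma_px, punctum_contrast)
    base *= f0 / base.mean()  # frame mean of the resting image is exactly F0
    evoked = raw.values - f0 * bleach_t  # diffuse flash component, per frame
    frames = (
        base[None, :, :] * bleach_t[:, None, None]
        + np.ones((h, w))[None, :, :] * evoked[:, None, None]
    )
    if noise_model == "gaussian" and noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
        frames = np.clip(frames, 0.0, None)
    elif noise_model == "poisson":
        frames = rng.poisson(np.clip(frames, 0.0, None)).astype(float)
    movie = Movie(
        frames,
        frame_rate_hz=frame_rate_hz,
        region_label=region_label,
        protocol=protocol,
    )
    truth = replace(
        truth,
        noise_sd=float(noise_sd),
        puncta_positions_px=tuple((float(x), float(y)) for x, y in positions),
    )
    return movie, truth


def simulate_slice_session(
    n_fovs: int,
    hotspot_fraction: float = 0.06,
    placement: str = "uniform",
    extent_um: tuple[float, float] = (1000.0, 600.0),
    auc_distributions: dict[str, tuple[float, float]] | None = None,
    cluster_radius_frac: float = 0.1,
    seed: int = 0,
    slice_id: str = "sim-slice",
    region: str = "GPe",
) -> SliceSession:
    """Simulate one slice's fields of view with known hotspot labels.

    Each FOV gets a position within ``extent_um``; ``hotspot_fraction`` of
    them draw their AUC from the high distribution, the rest from the low
    one. ``placement="uniform"`` scatters everything uniformly;
    ``"clustered"`` co-locates the hotspots within ``cluster_radius_frac`` of
    the extent around a random centre. Canny edge sums and initial
    fluorescence are drawn independently of AUC, mirroring the observed
    decoupling between transient size and punctate structure.
    """
    if n_fovs < 1:
        raise ValueError("n_fovs must be >= 1")
    if not 0.0 <= hotspot_fraction <= 1.0:
        raise ValueError("hotspot_fraction must be in [0, 1]")
    if placement not in ("uniform", "clustered"):
        raise ValueError(f"unknown placement: {placement!r}")
    ex, ey = extent_um
    if ex <= 0 or ey <= 0:
        raise ValueError("extent_um dimensions must be positive")
    dists = auc_distributions or {"low": (1.5, 0.6), "high": (8.0, 2.0)}
    rng = np.random.default_rng(seed)
    n_hot = int(round(hotspot_fraction * n_fovs))
    hot = np.zeros(n_fovs, dtype=bool)
    hot[rng.choice(n_fovs, size=n_hot, replace=False)] = True
    pos = np.column_stack(
        [rng.uniform(0, ex, size=n_fovs), rng.uniform(0, ey, size=n_fovs)]
    )
    if placement == "clustered" and n_hot > 0:
        center = rng.uniform([0.2 * ex, 0.2 * ey], [0.8 * ex, 0.8 * ey])
        radius = cluster_radius_frac * min(ex, ey)
        offsets = rng.normal(0.0, radius / 2.0, size=(n_hot, 2))
        pos[hot] = np.clip(center + offsets, [0, 0], [ex, ey])
    mlow, slow = dists["low"]
    mhigh, shigh = dists["high"]
    aucs = np.where(
        hot,
        rng.normal(mhigh, shigh, size=n_fovs),
        rng.normal(mlow, slow, size=n_fovs),
    )
    aucs = np.clip(aucs, 0.0, None)
    canny = rng.poisson(80.0, size=n_fovs)
    initial_f = np.clip(rng.normal(600.0, 50.0, size=n_fovs), 1.0, None)
    fovs = [
        FieldOfViewRecord(
            fov_id=f"{slice_id}-{i:03d}",
            slice_id=slice_id,
            x_um=float(pos[i, 0]),
            y_um=float(pos[i, 1]),
            auc=float(aucs[i]),
            canny_sum=int(canny[i]),
            initial_f=float(initial_f[i]),
            region=region,
            is_hotspot=bool(hot[i]),
        )
        for i in range(n_fovs)
    ]
    return SliceSession(slice_id, region, fovs, extent_um)
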