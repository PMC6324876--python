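"""Electrical stimulation protocols.

A protocol is a train of brief current pulses delivered through a bipolar
electrode placed on the slice. The pulse train timing is the anchor for
every downstream analysis window (baseline fit, AUC window, derivative
landmarks), so the protocol object is shared by all modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StimulusProtocol", "make_stimulus_protocol"]

_TIME_TOL = 1e-9


@dataclass(frozen=True)
class StimulusProtocol:
    """A regular pulse train.

    Parameters
    ----------
    onset_s
        Time of the first pulse, in seconds from the start of the recording.
    pulse_times_s
        Strictly increasing pulse times; consecutive spacing must equal
        ``1 / frequency_hz`` and the first entry must equal ``onset_s``.
    frequency_hz
        Within-train pulse frequency.
    n_pulses
        Number of pulses in the train.
    pulse_width_us, current_uA
        Electrical pulse shape metadata (600 us x 200 uA by default); carried
        for provenance, not used by the analysis itself.
    """

    onset_s: float
    pulse_times_s: tuple[float, ...]
    frequency_hz: float
    n_pulses: int
    pulse_width_us: float = 600.0
    current_uA: float = 200.0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        times = np.asarray(self.pulse_times_s, dtype=float)
        if times.size != self.n_pulses:
            raise ValueError("pulse_times_s length must equal n_pulses")
        if abs(times[0] - self.onset_s) > _TIME_TOL:
            raise ValueError("first pulse time must equal onset_s")
        if times.size > 1:
            gaps = np.diff(times)
            if np.any(gaps <= 0):
                raise ValueError("pulse_times_s must be strictly increasing")
            if np.max(np.abs(gaps - 1.0 / self.frequency_hz)) > _TIME_TOL:
                raise ValueError(
                    "consecutive pulse spacing must equal 1/frequency_hz"
                )

    @property
    def last_pulse_s(self) -> float:
        return self.pulse_times_s[-1]

    @property
    def train_duration_s(self) -> float:
        """Span from first to last pulse (0 for a single pulse)."""
        return self.pulse_times_s[-1] - self.pulse_times_s[0]

    def to_dict(self) -> dict:
        return {
            "onset_s": self.onset_s,
            "frequency_hz": self.frequency_hz,
            "n_pulses": self.n_pulses,
            "pulse_width_us": self.pulse_width_us,
            "current_uA": self.current_uA,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return make_stimulus_protocol(
            frequency_hz=d["frequency_hz"],
            n_pulses=int(d["n_pulses"]),
            onset_s=d["onset_s"],
            pulse_width_us=d.get("pulse_width_us", 600.0),
            current_uA=d.get("current_uA", 200.0),
        )


def make_stimulus_protocol(
    frequency_hz: float,
    n_pulses: int,
    onset_s: float = 1.0,
    pulse_width_us: float = 600.0,
    current_uA: float = 200.0,
) -> StimulusProtocol:
    """Build a regular pulse train: pulses at ``onset_s + k/frequency_hz``.

    Raises
    ------
    ValueError
        If ``frequency_hz <= 0`` or ``n_pulses < 1``.
    """
    if frequency_hz <= 0:
        raise ValueError(f"frequency_hz must be positive, got {frequency_hz}")
    if n_pulses < 1:
        raise ValueError(f"n_pulses must be >= 1, got {n_pulses}")
    times = onset_s + np.arange(int(n_pulses)) / float(frequency_hz)
    return StimulusProtocol(
        onset_s=float(onset_s),
        pulse_times_s=tuple(float(t) for t in times),
        frequency_hz=float(frequency_hz),
        n_pulses=int(n_pulses),
        pulse_width_us=float(pulse_width_us),
        current_uA=float(current_uA),
    )
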