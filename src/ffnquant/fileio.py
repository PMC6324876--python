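"""File formats: multi-page TIFF movies with JSON sidecars, CSV traces/tables.

Movies are stored as float32 multi-page TIFFs with a ``<name>.json`` sidecar
carrying frame rate, pixel size, region label and the stimulus protocol.
Traces are plain CSVs with a ``time_s`` column and one or more value columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .extraction import DFFTrace, RawTrace
from .protocols import StimulusProtocol
from .puncta import EdgeMask
from .spatial import FieldOfViewRecord, SliceSession
from .synthetic import Movie

__all__ = [
    "write_movie",
    "read_movie",
    "write_trace",
    "read_traces",
    "write_mask",
    "read_config",
    "session_to_frame",
    "frame_to_session",
]

_TIME_STEP_RTOL = 1e-3


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: Movie, path) -> Path:
    """Write a movie as multi-page float32 TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    meta = {
        "frame_rate_hz": movie.frame_rate_hz,
        "pixel_size_um": movie.pixel_size_um,
        "region_label": movie.region_label,
        "n_frames": int(movie.frames.shape[0]),
        "protocol": movie.protocol.to_dict() if movie.protocol else None,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_movie(path) -> Movie:
    """Read a movie written by :func:`write_movie`; validates the sidecar."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar: {sidecar}")
    meta = json.loads(sidecar.read_text())
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # corrupt/truncated file
        raise ValueError(f"cannot read TIFF stack {path}: {exc}") from exc
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] != meta["n_frames"]:
        raise ValueError(
            f"{path}: sidecar declares {meta['n_frames']} frames, "
            f"file has {frames.shape[0]}"
        )
    protocol = (
        StimulusProtocol.from_dict(meta["protocol"]) if meta.get("protocol") else None
    )
    return Movie(
        frames,
        frame_rate_hz=meta["frame_rate_hz"],
        pixel_size_um=meta.get("pixel_size_um", 50.0 / 64.0),
        region_label=meta.get("region_label", "unknown"),
        protocol=protocol,
    )


def write_trace(trace, path, column: str = "value") -> Path:
    """Write one trace (RawTrace or DFFTrace) as a two-column CSV."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.times_s, column: trace.values}).to_csv(
        path, index=False
    )
    return path


def read_traces(path, kind: str = "raw", time_column: str = "time_s") -> list:
    """Read one trace per value column from a wide CSV.

    ``kind`` selects the container: ``"raw"`` (RawTrace, frame rate inferred
    from the time step) or ``"dff"`` (DFFTrace). Raises on a non-monotone or
    irregular time column.
    """
    df = pd.read_csv(path)
    if time_column not in df.columns:
        raise ValueError(f"{path}: missing time column {time_column!r}")
    t = df[time_column].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    if np.max(np.abs(steps - steps[0])) > _TIME_STEP_RTOL * steps[0]:
        raise ValueError(f"{path}: irregular time step beyond tolerance")
    rate = 1.0 / steps[0]
    traces = []
    for col in df.columns:
        if col == time_column:
            continue
        v = df[col].to_numpy(dtype=float)
        if kind == "raw":
            traces.append(RawTrace(t.copy(), v, rate))
        elif kind == "dff":
            traces.append(DFFTrace(t.copy(), v))
        else:
            raise ValueError(f"unknown trace kind: {kind!r}")
    if not traces:
        raise ValueError(f"{path}: no value columns found")
    return traces


def write_mask(mask: EdgeMask, path) -> Path:
    """Write a binary edge mask as a single-page 0/255 uint8 TIFF."""
    path = Path(path)
    tifffile.imwrite(path, (mask.pixels.astype(np.uint8) * 255))
    return path


def read_config(path) -> dict:
    """Read a plain-text ``key: value`` (YAML) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping of key: value pairs")
    return cfg


_SESSION_COLUMNS = [
    "fov_id",
    "slice_id",
    "x_um",
    "y_um",
    "auc",
    "canny_sum",
    "initial_f",
    "region",
    "drug",
    "calcium_mM",
    "frequency_hz",
    "hemisphere",
    "is_hotspot",
]


def session_to_frame(session: SliceSession) -> pd.DataFrame:
    return pd.DataFrame(
        [[getattr(f, c) for c in _SESSION_COLUMNS] for f in session.fovs],
        columns=_SESSION_COLUMNS,
    )


def frame_to_session(
    df: pd.DataFrame, extent_um: tuple[float, float] = (1000.0, 600.0)
) -> SliceSession:
    fovs = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in _SESSION_COLUMNS if c in df.columns}
        if "is_hotspot" in kwargs and pd.isna(kwargs["is_hotspot"]):
            kwargs["is_hotspot"] = None
        fovs.append(FieldOfViewRecord(**kwargs))
    slice_id = fovs[0].slice_id if fovs else "unknown"
    region = fovs[0].region if fovs else "unknown"
    return SliceSession(str(slice_id), str(region), fovs, extent_um)
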