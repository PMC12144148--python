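"""Gaze-table loading, velocity computation, normalization and segmentation.

The preprocessing chain turns timestamped 2-D gaze positions (screen pixels,
nominally sampled at 1000 Hz) into the fixed-length, [0, 1]-scaled speed
sequences that the generative models train on:

    positions -> speed (px/ms) -> min-max normalize -> length-L segments
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (DegenerateRangeError, DuplicateTimestampError, FormatError,
                     InsufficientDataError, ZeroTimeGapError)

REQUIRED_COLUMNS = ("time_ms", "x_px", "y_px")


@dataclass
class GazeRecording:
    """One eye's timestamped 2-D gaze positions (times in ms, positions in px)."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    eye: str = "unspecified"
    n_dropped: int = 0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.time) < 2:
            raise InsufficientDataError("a recording needs at least 2 samples")
        if not (len(self.time) == len(self.x) == len(self.y)):
            raise FormatError("time, x and y must have equal lengths")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()
                and np.isfinite(self.time).all()):
            raise FormatError("non-finite values in recording")
        if np.any(np.diff(self.time) <= 0):
            raise DuplicateTimestampError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class VelocitySeries:
    """1-D gaze speed series in px/ms sampled every `dt` milliseconds."""

    values: np.ndarray
    dt: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("speeds must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class NormalizationParams:
    min: float
    max: float

    def __post_init__(self):
        if not self.max > self.min:
            raise DegenerateRangeError(
                f"max ({self.max}) must exceed min ({self.min})")


@dataclass
class SequenceDataset:
    """Matrix of non-overlapping, length-L, [0, 1]-scaled speed segments."""

    sequences: np.ndarray
    seq_len: int
    provenance: NormalizationParams | None = None
    n_discarded: int = 0

    def __post_init__(self):
        self.sequences = np.asarray(self.sequences, dtype=float)
        if self.sequences.ndim != 2 or self.sequences.shape[1] != self.seq_len:
            raise ValueError("sequences must be a (n_seq, seq_len) matrix")
        if self.sequences.min() < 0.0 or self.sequences.max() > 1.0:
            raise ValueError("sequence entries must lie in [0, 1]")

    @property
    def n_seq(self) -> int:
        return self.sequences.shape[0]


def load_gaze_table(path, eye: str = "unspecified") -> GazeRecording:
    """Read a CSV/TSV gaze table with columns time_ms, x_px, y_px [, eye].

    Rows with non-finite coordinates are dropped (and counted on the returned
    recording); rows are sorted by timestamp and duplicate timestamps raise.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # unparsable file
        raise FormatError(f"cannot parse gaze table {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gaze table {path} is missing columns: {missing}")
    if eye != "unspecified" and "eye" in df.columns:
        label = {"left": "L", "right": "R"}.get(eye, eye)
        df = df[df["eye"].astype(str).str.upper() == label.upper()]
    sub = df[list(REQUIRED_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    keep = np.isfinite(sub.to_numpy(dtype=float)).all(axis=1)
    n_dropped = int((~keep).sum())
    sub = sub[keep].sort_values("time_ms")
    if len(sub) < 2:
        raise InsufficientDataError(
            f"gaze table {path} has {len(sub)} valid rows; need at least 2")
    t = sub["time_ms"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise DuplicateTimestampError(f"duplicate timestamps in {path}")
    return GazeRecording(t, sub["x_px"].to_numpy(dtype=float),
                         sub["y_px"].to_numpy(dtype=float), eye=eye,
                         n_dropped=n_dropped)


def compute_velocity(rec: GazeRecording) -> VelocitySeries:
    """Speed series: Euclidean distance between consecutive positions divided
    by the time gap (1 ms at the nominal 1000 Hz sampling)."""
    dt = np.diff(rec.time)
    zero = np.nonzero(dt == 0)[0]
    if zero.size:
        raise ZeroTimeGapError(int(zero[0]))
    speed = np.hypot(np.diff(rec.x), np.diff(rec.y)) / dt
    step = float(dt[0]) if np.allclose(dt, dt[0]) else 1.0
    return VelocitySeries(speed, dt=step)


def _values(v) -> np.ndarray:
    return v.values if isinstance(v, VelocitySeries) else np.asarray(v, dtype=float)


def minmax_normalize(v) -> tuple[np.ndarray, NormalizationParams]:
    """Scale a speed series to [0, 1]; returns the scaled series and the
    (min, max) parameters needed to invert the transform."""
    x = _values(v)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise DegenerateRangeError("constant series cannot be normalized")
    params = NormalizationParams(lo, hi)
    return (x - lo) / (hi - lo), params


def apply_normalization(v, params: NormalizationParams, clip: bool = True) -> np.ndarray:
    """Apply previously fitted min-max parameters (e.g. training-split fit)
    to another series; values outside the fitted range are clipped by default."""
    y = (_values(v) - params.min) / (params.max - params.min)
    return np.clip(y, 0.0, 1.0) if clip else y


def denormalize(y, params: NormalizationParams) -> np.ndarray:
    """Inverse of :func:`minmax_normalize`."""
    return np.asarray(y, dtype=float) * (params.max - params.min) + params.min


def segment_sequences(y, seq_len: int = 200,
                      provenance: NormalizationParams | None = None) -> SequenceDataset:
    """Cut a normalized series into non-overlapping length-`seq_len` windows;
    the trailing remainder is discarded and counted."""
    y = np.asarray(y, dtype=float)
    if len(y) < seq_len:
        raise InsufficientDataError(
            f"series of length {len(y)} is shorter than one segment ({seq_len})")
    n_seq = len(y) // seq_len
    n_discarded = len(y) - n_seq * seq_len
    seqs = y[:n_seq * seq_len].reshape(n_seq, seq_len)
    return SequenceDataset(seqs, seq_len, provenance=provenance,
                           n_discarded=n_discarded)


def pool_datasets(*datasets: SequenceDataset) -> SequenceDataset:
    """Concatenate segment sets (e.g. left and right eye) sharing one length."""
    if not datasets:
        raise ValueError("need at least one dataset")
    L = datasets[0].seq_len
    if any(d.seq_len != L for d in datasets):
        raise ValueError("all datasets must share seq_len")
    return SequenceDataset(np.vstack([d.sequences for d in datasets]), L,
                           provenance=datasets[0].provenance,
                           n_discarded=sum(d.n_discarded for d in datasets))
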