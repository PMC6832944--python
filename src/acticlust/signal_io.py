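"""Raw signal and label-bout I/O, transition trimming and tumbling windows.

Signals are plain delimited text with header ``time,x,y,z`` — time in seconds
from the start of the recording, axes in g (already calibrated).  Label files
carry ``start,end,label`` rows in seconds.  Windows are fixed-width,
non-overlapping ("tumbling") slices; a trailing partial window is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "LabelBout",
    "WindowSlice",
    "read_raw_signal",
    "write_raw_signal",
    "read_labels",
    "write_labels",
    "trim_transitions",
    "make_windows",
    "stack_windows",
]

_WRISTS = ("left", "right", "unknown")


@dataclass
class RawRecording:
    """Uniformly sampled triaxial acceleration in g.

    Parameters
    ----------
    time : (n,) array of sample times in seconds, strictly increasing and
        uniform to within half a sample period.
    xyz : (n, 3) array of accelerations in g (columns x, y, z).
    fs : sampling rate in Hz, in [10, 160].
    wrist : wrist of wear, one of {"left", "right", "unknown"}.
    """

    time: np.ndarray
    xyz: np.ndarray
    fs: float
    wrist: str = "unknown"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        if self.time.shape[0] != self.xyz.shape[0]:
            raise ValueError("time and xyz lengths differ")
        if not 10.0 <= self.fs <= 160.0:
            raise ValueError(f"sampling rate {self.fs} Hz outside [10, 160]")
        if self.wrist not in _WRISTS:
            raise ValueError(f"wrist must be one of {_WRISTS}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite acceleration values")
        if self.time.size > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise ValueError(f"non-monotone time at row {row}")
            tol = 0.5 / self.fs
            if np.any(np.abs(dt - 1.0 / self.fs) > tol):
                row = int(np.argmax(np.abs(dt - 1.0 / self.fs) > tol)) + 1
                raise ValueError(f"non-uniform sampling at row {row}")

    @property
    def n_samples(self) -> int:
        return self.xyz.shape[0]

    @property
    def duration(self) -> float:
        """Recording span in seconds (n_samples / fs)."""
        return self.n_samples / self.fs


@dataclass(frozen=True)
class LabelBout:
    """A contiguous labelled activity bout, [start, end) in seconds."""

    start: float
    end: float
    label: str

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"bout end {self.end} not after start {self.start}")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class WindowSlice:
    """Half-open, 0-based sample range of one tumbling window."""

    window_index: int
    start_sample: int
    stop_sample: int
    label: str | None = None

    @property
    def n_samples(self) -> int:
        return self.stop_sample - self.start_sample


def read_raw_signal(path: str | Path, fs: float, wrist: str = "unknown") -> RawRecording:
    """Read a delimited-text signal file (header ``time,x,y,z``, units g)."""
    df = pd.read_csv(path)
    for col in ("time", "x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    for col in ("time", "x", "y", "z"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 1
            raise ValueError(f"non-numeric value in column {col} at row {row}")
        df[col] = vals
    return RawRecording(
        time=df["time"].to_numpy(),
        xyz=df[["x", "y", "z"]].to_numpy(),
        fs=fs,
        wrist=wrist,
    )


def write_raw_signal(rec: RawRecording, path: str | Path) -> None:
    """Write a recording back to the ``time,x,y,z`` text dialect."""
    df = pd.DataFrame(
        {"time": rec.time, "x": rec.xyz[:, 0], "y": rec.xyz[:, 1], "z": rec.xyz[:, 2]}
    )
    df.to_csv(path, index=False, float_format="%.6f")


def _validate_bouts(bouts: Sequence[LabelBout]) -> list[LabelBout]:
    out = sorted(bouts, key=lambda b: b.start)
    for a, b in zip(out, out[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping bouts: ({a.start}, {a.end}, {a.label}) and "
                f"({b.start}, {b.end}, {b.label})"
            )
    return out


def read_labels(path: str | Path) -> list[LabelBout]:
    """Read a label file (header ``start,end,label``), sorted and validated."""
    df = pd.read_csv(path)
    for col in ("start", "end", "label"):
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
    bouts = [
        LabelBout(float(r.start), float(r.end), str(r.label))
        for r in df.itertuples(index=False)
    ]
    return _validate_bouts(bouts)


def write_labels(bouts: Sequence[LabelBout], path: str | Path) -> None:
    df = pd.DataFrame(
        {"start": [b.start for b in bouts], "end": [b.end for b in bouts],
         "label": [b.label for b in bouts]}
    )
    df.to_csv(path, index=False)


def trim_transitions(bouts: Sequence[LabelBout], margin: float = 30.0) -> list[LabelBout]:
    """Shrink each bout by ``margin`` seconds at both ends.

    Removes transitional movement at activity boundaries.  Bouts whose
    residual duration is non-positive are dropped.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if margin == 0:
        return list(bouts)
    out = []
    for b in bouts:
        if b.duration > 2 * margin:
            out.append(LabelBout(b.start + margin, b.end - margin, b.label))
    return out


def make_windows(
    rec: RawRecording,
    bouts: Sequence[LabelBout] | None = None,
    width: float = 10.0,
) -> list[WindowSlice]:
    """Cut a recording into consecutive non-overlapping windows.

    A window is labelled iff it lies entirely inside a single bout
    (half-open containment on sample times); otherwise its label is None.
    The trailing partial window is dropped.
    """
    if width <= 0:
        raise ValueError("window width must be > 0")
    n_per = width * rec.fs
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(f"width * fs = {n_per} is not a whole number of samples")
    n_per = int(round(n_per))
    n_windows = rec.n_samples // n_per
    sorted_bouts = _validate_bouts(bouts) if bouts is not None else []
    slices: list[WindowSlice] = []
    for i in range(n_windows):
        lo, hi = i * n_per, (i + 1) * n_per
        label = None
        t_first, t_last = rec.time[lo], rec.time[hi - 1]
        for b in sorted_bouts:
            if b.start <= t_first and t_last < b.end:
                label = b.label
                break
        slices.append(WindowSlice(i, lo, hi, label))
    return slices


def stack_windows(
    rec: RawRecording, slices: Sequence[WindowSlice]
) -> tuple[np.ndarray, list[str | None]]:
    """Stack window samples into an (n_windows, n_samples, 3) array.

    Returns the array together with the per-window labels, in slice order.
    """
    if not slices:
        return np.empty((0, 0, 3)), []
    X = np.stack([rec.xyz[s.start_sample:s.stop_sample] for s in slices])
    labels = [s.label for s in slices]
    return X, labels
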