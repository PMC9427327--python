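"""Recording I/O, zero-phase low-pass filtering and sliding-window segmentation.

A recording is a channels x samples signal with an optional per-sample movement
label (0 = rest) and repetition id. Windowing produces the fixed-shape
(window_len, channels) samples the model consumes; the canonical experiment
shape is (200, 12).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy import signal as _sig

__all__ = [
    "RawRecording", "WindowSet",
    "load_recording", "save_recording",
    "lowpass_filter", "sliding_windows", "standardize",
    "MissingFileError", "RaggedRowsError", "NonNumericCellError",
    "MissingSamplingRateError", "NyquistError", "WindowTooLongError",
    "ZeroVarianceChannelError",
]


class MissingFileError(FileNotFoundError):
    """Input path does not exist."""


class RaggedRowsError(ValueError):
    """Delimited rows have inconsistent column counts."""


class NonNumericCellError(ValueError):
    """A signal cell is missing or not a finite number."""


class MissingSamplingRateError(KeyError):
    """Container lacks the sampling_rate attribute."""


class NyquistError(ValueError):
    """Filter cutoff at or above the Nyquist frequency."""


class WindowTooLongError(ValueError):
    """Requested window exceeds the recording length."""


class ZeroVarianceChannelError(ValueError):
    """A channel has zero variance; z-scoring is undefined."""


@dataclass
class RawRecording:
    """Labeled multichannel signal as acquired, before windowing."""

    data: np.ndarray                      # channels x samples
    sampling_rate: float                  # Hz
    labels: np.ndarray | None = None      # per-sample movement id, 0 = rest
    repetition: np.ndarray | None = None  # per-sample repetition id

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("data must be a channels x samples matrix")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        for name in ("labels", "repetition"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=int)
                if arr.shape != (self.n_samples,):
                    raise ValueError(f"{name} length must equal sample count")
                setattr(self, name, arr)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class WindowSet:
    """Stack of fixed-length multichannel windows with per-window labels."""

    windows: np.ndarray           # n_windows x window_len x channels
    labels: np.ndarray            # per-window movement id
    window_len: int
    stride: int
    repetition: np.ndarray | None = None
    channel_mean: np.ndarray | None = None  # standardization stats actually applied
    channel_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.windows.ndim != 3:
            raise ValueError("windows must be n x window_len x channels")
        if self.windows.shape[1] != self.window_len:
            raise ValueError("window_len does not match window shape")
        if self.window_len <= 0 or self.stride <= 0:
            raise ValueError("window_len and stride must be positive")
        if len(self.labels) != self.n_windows:
            raise ValueError("labels length must equal window count")
        if self.channel_std is not None and np.any(self.channel_std <= 0):
            raise ZeroVarianceChannelError("recorded channel_std must be positive")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[2]

    def flat(self) -> np.ndarray:
        """Windows flattened to n x (window_len * channels), time-major."""
        return self.windows.reshape(self.n_windows, -1)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_recording(path, format: str = "delimited",
                   sampling_rate: float | None = None) -> RawRecording:
    """Load a recording from delimited text or an HDF5 array container.

    Delimited files have one column per channel (header row with channel
    names) plus optional "label" and "repetition" columns; the sampling rate
    must then be supplied by the caller. Containers store "data"
    (channels x samples), optional "labels"/"repetition" datasets and a
    "sampling_rate" attribute.
    """
    import os

    if not os.path.exists(path):
        raise MissingFileError(f"no such recording file: {path}")
    if format == "delimited":
        return _load_delimited(path, sampling_rate)
    if format == "array-container":
        return _load_container(path)
    raise ValueError(f"unknown format {format!r}")


def _load_delimited(path, sampling_rate: float | None) -> RawRecording:
    if sampling_rate is None:
        raise MissingSamplingRateError(
            "delimited recordings carry no sampling rate; pass sampling_rate=")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise RaggedRowsError(f"inconsistent column counts in {path}: {exc}") from exc
    labels = rep = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=int)
    if "repetition" in df.columns:
        rep = df.pop("repetition").to_numpy(dtype=int)
    values = df.to_numpy()
    bad = ~np.isfinite(values.astype(float, casting="unsafe")) \
        if np.issubdtype(values.dtype, np.number) else None
    if bad is None:
        raise NonNumericCellError(f"non-numeric signal cells in {path}")
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise NonNumericCellError(f"non-finite signal cell at row {row} in {path}")
    return RawRecording(values.T.astype(float), sampling_rate, labels, rep)


def _load_container(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        if "sampling_rate" not in f.attrs:
            raise MissingSamplingRateError(
                f"container {path} lacks the sampling_rate attribute")
        data = f["data"][...]
        labels = f["labels"][...] if "labels" in f else None
        rep = f["repetition"][...] if "repetition" in f else None
        sr = float(f.attrs["sampling_rate"])
    return RawRecording(data, sr, labels, rep)


def save_recording(rec: RawRecording, path) -> None:
    """Write a recording to the HDF5 array container (lossless round trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        if rec.labels is not None:
            f.create_dataset("labels", data=rec.labels)
        if rec.repetition is not None:
            f.create_dataset("repetition", data=rec.repetition)
        f.attrs["sampling_rate"] = rec.sampling_rate


# ---------------------------------------------------------------------------
# Filtering and windowing
# ---------------------------------------------------------------------------

def lowpass_filter(rec: RawRecording, cutoff_hz: float, order: int = 4) -> RawRecording:
    """Zero-phase (forward-backward) Butterworth low-pass, per channel.

    Labels and repetition ids pass through unchanged; the output has the same
    length as the input.
    """
    nyq = rec.sampling_rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise NyquistError(
            f"cutoff {cutoff_hz} Hz must lie in (0, {nyq}) Hz (Nyquist)")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = _sig.butter(order, cutoff_hz, btype="low", fs=rec.sampling_rate,
                      output="sos")
    filtered = _sig.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered)


def sliding_windows(rec: RawRecording, window_len: int, stride: int,
                    label_rule: str = "majority") -> WindowSet:
    """Segment into half-open windows [k*stride, k*stride + window_len).

    n_windows = floor((n_samples - window_len) / stride) + 1. Per-window label
    by majority vote (ties -> smallest label id) or the center sample;
    unlabeled recordings get label 0 everywhere. Per-window repetition id,
    when present, follows the same rule.
    """
    if window_len > rec.n_samples:
        raise WindowTooLongError(
            f"window of {window_len} samples exceeds recording of {rec.n_samples}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if label_rule not in ("majority", "center"):
        raise ValueError(f"unknown label_rule {label_rule!r}")
    n = (rec.n_samples - window_len) // stride + 1
    starts = np.arange(n) * stride
    idx = starts[:, None] + np.arange(window_len)[None, :]
    windows = rec.data.T[idx]  # n x window_len x channels

    def window_ids(per_sample: np.ndarray) -> np.ndarray:
        chunks = per_sample[idx]
        if label_rule == "center":
            return chunks[:, window_len // 2]
        out = np.empty(n, dtype=int)
        for k in range(n):
            vals, counts = np.unique(chunks[k], return_counts=True)
            out[k] = vals[counts == counts.max()].min()
        return out

    labels = (window_ids(rec.labels) if rec.labels is not None
              else np.zeros(n, dtype=int))
    rep = window_ids(rec.repetition) if rec.repetition is not None else None
    return WindowSet(windows, labels, window_len, stride, repetition=rep)


def standardize(ws: WindowSet,
                stats: tuple[np.ndarray, np.ndarray] | None = None) -> WindowSet:
    """Per-channel z-scoring over all windows and samples.

    When ``stats`` (mean, std per channel) is given — the test-time path —
    they are applied instead of re-fitting; the applied statistics are
    recorded on the returned WindowSet either way.
    """
    if stats is None:
        mean = ws.windows.mean(axis=(0, 1))
        std = ws.windows.std(axis=(0, 1))
    else:
        mean = np.asarray(stats[0], dtype=float)
        std = np.asarray(stats[1], dtype=float)
        if mean.shape != (ws.n_channels,) or std.shape != (ws.n_channels,):
            raise ValueError("stats must be per-channel (mean, std)")
    bad = np.flatnonzero(~(std > 0))
    if bad.size:
        raise ZeroVarianceChannelError(
            f"channel {int(bad[0])} has non-positive std; cannot z-score")
    return WindowSet((ws.windows - mean) / std, ws.labels, ws.window_len,
                     ws.stride, repetition=ws.repetition,
                     channel_mean=mean.copy(), channel_std=std.copy())
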