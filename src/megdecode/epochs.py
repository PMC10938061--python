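"""Epoched data container, stratified splitting, sliding-window bookkeeping.

The universal input of the package is a trials x channels x timepoints
array of epoched (stimulus-locked) data with integer class labels, a
sampling rate and a :class:`~megdecode.layout.SensorLayout`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np

from .layout import SensorLayout


@dataclass
class Epochs:
    """Epoched multichannel time series.

    Attributes
    ----------
    data : (n_trials, n_channels, n_times) float array
    labels : (n_trials,) int array
        Class labels in ``[0, n_classes)``.
    sfreq : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample relative to stimulus onset, seconds.
    layout : SensorLayout or None
    """

    data: np.ndarray
    labels: np.ndarray
    sfreq: float
    t0: float = 0.0
    layout: SensorLayout | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x times")
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels must have one entry per trial")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to stimulus onset."""
        return self.t0 + np.arange(self.n_times) / self.sfreq

    # ------------------------------------------------------------------ io
    def save(self, path) -> None:
        """Write to an HDF5 container (float32 data, layout, labels)."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float32))
            f.create_dataset("labels", data=self.labels)
            f.attrs["sfreq"] = self.sfreq
            f.attrs["t0"] = self.t0
            if self.layout is not None:
                g = f.create_group("layout")
                g.create_dataset("positions", data=self.layout.positions)
                g.create_dataset("channel_site", data=self.layout.channel_site)
                g.attrs["channel_types"] = json.dumps(self.layout.channel_types)
                g.attrs["neighborhoods"] = json.dumps(
                    [n.tolist() for n in self.layout.neighborhoods]
                )

    @classmethod
    def load(cls, path) -> "Epochs":
        with h5py.File(path, "r") as f:
            layout = None
            if "layout" in f:
                g = f["layout"]
                layout = SensorLayout(
                    positions=g["positions"][()],
                    channel_site=g["channel_site"][()],
                    channel_types=json.loads(g.attrs["channel_types"]),
                    neighborhoods=[
                        np.asarray(n) for n in json.loads(g.attrs["neighborhoods"])
                    ],
                )
            return cls(
                data=f["data"][()],
                labels=f["labels"][()],
                sfreq=float(f.attrs["sfreq"]),
                t0=float(f.attrs["t0"]),
                layout=layout,
            )


@dataclass
class SplitIndices:
    """Disjoint train/validation trial indices covering all trials."""

    train: np.ndarray
    validation: np.ndarray


def stratified_split(
    labels: Sequence[int], ratio: float = 0.2, seed: int = 0
) -> SplitIndices:
    """Per-class train/validation split (default 4:1).

    Every class contributes ``max(1, floor(ratio * n_c))`` validation
    trials, drawn by a seeded shuffle of that class's trials; the split is
    deterministic given ``(labels, ratio, seed)``.

    Raises
    ------
    ValueError
        If any class has fewer than 2 trials (no split possible).
    """
    labels = np.asarray(labels)
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train, val = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            raise ValueError(f"class {c} has {idx.size} trial(s); need >= 2")
        idx = rng.permutation(idx)
        n_val = max(1, int(np.floor(ratio * idx.size)))
        val.append(idx[:n_val])
        train.append(idx[n_val:])
    return SplitIndices(
        train=np.sort(np.concatenate(train)),
        validation=np.sort(np.concatenate(val)),
    )


@dataclass
class WindowSpec:
    """Sliding-window partition: half-open windows ``[s, s + length)``.

    The number of windows is ``floor((n_times - length) / step)``; the
    final placement flush with the end of the epoch is dropped, so 100
    samples with 10-sample windows at step 1 give 90 windows.
    """

    length: int
    step: int
    start_offsets: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_windows(self) -> int:
        return len(self.start_offsets)

    def centers(self, sfreq: float, t0: float = 0.0) -> np.ndarray:
        """Window-centre times in seconds relative to stimulus onset."""
        return t0 + (self.start_offsets + self.length / 2.0) / sfreq


def sliding_windows(n_times: int, length: int, step: int = 1) -> WindowSpec:
    """Build the sliding-window partition of an epoch.

    Raises
    ------
    ValueError
        If ``length > n_times`` or ``length < 1`` or ``step < 1``.
    """
    if length < 1 or step < 1:
        raise ValueError("length and step must be >= 1")
    if length > n_times:
        raise ValueError(f"window length {length} exceeds n_times {n_times}")
    count = (n_times - length) // step
    starts = np.arange(count) * step
    return WindowSpec(length=length, step=step, start_offsets=starts)


def flatten_epoch(reduced: np.ndarray) -> np.ndarray:
    """Row-major flatten of a [n_times x n_components] matrix.

    ``flatten_epoch(x).reshape(x.shape)`` recovers the input bit-exactly.
    """
    reduced = np.asarray(reduced)
    if not np.all(np.isfinite(reduced)):
        raise ValueError("non-finite values in input")
    return reduced.reshape(-1)
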