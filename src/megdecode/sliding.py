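"""Sliding-window decoding time courses and per-sensor accuracy maps.

These are the classical MVPA comparators for the PFI maps: one LDA per
100 ms window gives an accuracy time course, and one LDA per sensor
triplet (2 gradiometers + 1 magnetometer at the same position, trained
on that site's full epoch) gives a spatial accuracy map — a
"search-light" across time and across space respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .base import validate_epoch_array
from .epochs import Epochs, SplitIndices, WindowSpec, sliding_windows
from .layout import SensorLayout
from .lda import fit_lda
from .nn import LinearDecodingNetwork
from .whitening import ChannelWhitener


@dataclass
class AccuracyTimecourse:
    """Validation accuracy per sliding window."""

    centers: np.ndarray      # window-centre times, seconds
    accuracy: np.ndarray     # fraction correct per window
    chance: float            # 1 / n_classes

    def __post_init__(self):
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("window centers must be strictly increasing")


@dataclass
class SensorAccuracyMap:
    """Validation accuracy of per-site full-epoch decoders."""

    accuracy: np.ndarray     # one value per site
    positions: np.ndarray    # (n_sites, 2)
    chance: float


def peak_accuracy(tc: AccuracyTimecourse):
    """Window centre and value of the accuracy maximum.

    Ties break toward the earliest window.
    """
    if tc.accuracy.size == 0:
        raise ValueError("empty timecourse")
    i = int(np.argmax(tc.accuracy))
    return float(tc.centers[i]), float(tc.accuracy[i])


class SlidingWindowLDA:
    """Independent shrinkage LDAs on consecutive windows of projected data.

    The channel projection (PCA directions or the network's bottleneck
    matrix, together with its whitener) is fitted once on full-epoch
    training data and shared across windows; each window's LDA sees the
    flattened [window x components] block and nothing else.

    Parameters
    ----------
    spec : WindowSpec
    projection : "pca" | (channels x components) array | fitted
        LinearDecodingNetwork (whose whitener and bottleneck are reused)
    n_components : used when projection="pca"
    shrinkage, whiten : as in the full-epoch decoders
    """

    def __init__(self, spec: WindowSpec, projection="pca", n_components=80,
                 shrinkage="auto", whiten=True):
        self.spec = spec
        self.projection = projection
        self.n_components = n_components
        self.shrinkage = shrinkage
        self.whiten = whiten

    def _resolve(self, X):
        if isinstance(self.projection, LinearDecodingNetwork):
            net = self.projection
            return net.whitener_, net.W_dr_
        if isinstance(self.projection, np.ndarray):
            w = ChannelWhitener().fit(X) if self.whiten else None
            return w, self.projection
        if self.projection == "pca":
            from sklearn.decomposition import PCA

            w = ChannelWhitener().fit(X) if self.whiten else None
            Xw = w.transform(X) if w is not None else X
            pooled = np.transpose(Xw, (0, 2, 1)).reshape(-1, X.shape[1])
            pca = PCA(n_components=self.n_components, svd_solver="full")
            return w, pca.fit(pooled).components_.T
        raise ValueError(f"unknown projection {self.projection!r}")

    def _reduced(self, X):
        X = validate_epoch_array(X)
        if self.whitener_ is not None:
            X = self.whitener_.transform(X)
        return np.transpose(X, (0, 2, 1)) @ self.projection_  # (n, t, k)

    def fit(self, X, y):
        if self.spec.n_windows == 0:
            raise ValueError("empty WindowSpec: use the full-epoch decoder")
        self.whitener_, self.projection_ = self._resolve(
            validate_epoch_array(X))
        R = self._reduced(X)
        self.models_ = []
        L = self.spec.length
        for s in self.spec.start_offsets:
            F = R[:, s:s + L, :].reshape(len(R), -1)
            self.models_.append(fit_lda(F, y, shrinkage=self.shrinkage))
        self.classes_ = self.models_[0].classes_
        return self

    def window_accuracies(self, X, y):
        """Per-window fraction correct on ``(X, y)``."""
        R = self._reduced(X)
        y = np.asarray(y)
        L = self.spec.length
        out = np.empty(self.spec.n_windows)
        for i, s in enumerate(self.spec.start_offsets):
            F = R[:, s:s + L, :].reshape(len(R), -1)
            out[i] = np.mean(self.models_[i].predict(F) == y)
        return out


def train_windowed(epochs: Epochs, split: SplitIndices, spec: WindowSpec,
                   projection="pca", n_components=80, shrinkage="auto",
                   whiten=True) -> AccuracyTimecourse:
    """Fit per-window LDAs on the training split and score validation.

    Returns the validation-accuracy time course with window-centre
    times; chance level is 1/n_classes.
    """
    model = SlidingWindowLDA(spec, projection=projection,
                             n_components=n_components,
                             shrinkage=shrinkage, whiten=whiten)
    model.fit(epochs.data[split.train], epochs.labels[split.train])
    acc = model.window_accuracies(
        epochs.data[split.validation], epochs.labels[split.validation])
    return AccuracyTimecourse(
        centers=spec.centers(epochs.sfreq, epochs.t0),
        accuracy=acc, chance=1.0 / epochs.n_classes)


def per_sensor_lda(epochs: Epochs, split: SplitIndices,
                   layout: SensorLayout | None = None,
                   shrinkage="auto") -> SensorAccuracyMap:
    """Full-epoch LDA per sensor triplet — a spatial search-light.

    Each site's model sees only the flattened [n_times x 3] block of its
    own co-located channels, in raw sensor space (no whitening, which
    would mix channels across sites).
    """
    layout = layout or epochs.layout
    if layout is None:
        raise ValueError("no sensor layout available")
    if layout.n_channels != epochs.n_channels:
        raise ValueError("layout does not match the data")
    acc = np.empty(layout.n_sites)
    ytr = epochs.labels[split.train]
    yva = epochs.labels[split.validation]
    for s in range(layout.n_sites):
        ch = layout.site_channels(s)
        if ch.size != 3:
            raise ValueError(f"site {s} has {ch.size} channels, expected 3")
        Ftr = np.transpose(
            epochs.data[np.ix_(split.train, ch)], (0, 2, 1)).reshape(
            len(ytr), -1)
        Fva = np.transpose(
            epochs.data[np.ix_(split.validation, ch)], (0, 2, 1)).reshape(
            len(yva), -1)
        lda = fit_lda(Ftr, ytr, shrinkage=shrinkage)
        acc[s] = np.mean(lda.predict(Fva) == yva)
    return SensorAccuracyMap(accuracy=acc, positions=layout.positions,
                             chance=1.0 / epochs.n_classes)
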