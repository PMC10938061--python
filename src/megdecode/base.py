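"""Shared decoder plumbing.

Every fitted decoder in this package is, at evaluation time, an affine
map from a (possibly whitened, possibly channel-projected) flattened
epoch to class scores, followed by an argmax.  :class:`AffineDecoder`
is that canonical evaluation form; trained models can be collapsed to
it and it is the on-disk model format.
"""

from __future__ import annotations

import numpy as np


def validate_epoch_array(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 3:
        raise ValueError("X must have shape (n_trials, n_channels, n_times)")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


def project_epochs(X: np.ndarray, projection: np.ndarray | None) -> np.ndarray:
    """Per-timepoint channel projection: (n, ch, t) -> (n, t, k).

    With ``projection=None`` the channel dimension is kept (k = ch).
    Right-multiplies the [time x channels] view of each trial, i.e. the
    projection is shared across timepoints.
    """
    E = np.transpose(X, (0, 2, 1))
    if projection is None:
        return E
    return E @ projection


def flatten_features(reduced: np.ndarray) -> np.ndarray:
    """Row-major flatten (n, t, k) -> (n, t * k)."""
    return reduced.reshape(reduced.shape[0], -1)


class AffineDecoder:
    """Evaluation-form decoder: whiten -> project -> flatten -> affine.

    Parameters
    ----------
    weights : (n_features, n_classes) array
    bias : (n_classes,) array
    classes : (n_classes,) int array
    whiten_mean, whiten_matrix : optional channel whitening, applied as
        ``W @ (x - mean)`` per timepoint.
    projection : optional (n_channels, n_components) matrix applied per
        timepoint after whitening.

    Ties in the class-score argmax break toward the lowest class index.
    """

    def __init__(self, weights, bias, classes, whiten_mean=None,
                 whiten_matrix=None, projection=None):
        self.weights = np.asarray(weights, dtype=np.float64)
        self.bias = np.asarray(bias, dtype=np.float64)
        self.classes_ = np.asarray(classes)
        self.whiten_mean = None if whiten_mean is None else np.asarray(whiten_mean)
        self.whiten_matrix = (
            None if whiten_matrix is None else np.asarray(whiten_matrix))
        self.projection = None if projection is None else np.asarray(projection)

    def _features(self, X):
        X = validate_epoch_array(X)
        if self.whiten_matrix is not None:
            X = np.einsum("wc,nct->nwt", self.whiten_matrix,
                          X - self.whiten_mean[None, :, None])
        return flatten_features(project_epochs(X, self.projection))

    def decision_function(self, X):
        return self._features(X) @ self.weights + self.bias

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def accuracy(model, epochs, idx=None) -> float:
    """Fraction of correct top-1 predictions of ``model`` on ``epochs``.

    ``model`` is anything with ``predict(X)`` over (n, ch, t) arrays;
    ``epochs`` an :class:`~megdecode.epochs.Epochs`; ``idx`` an optional
    trial subset (default: all trials).
    """
    data, labels = epochs.data, epochs.labels
    if idx is not None:
        idx = np.asarray(idx)
        if idx.size == 0:
            raise ValueError("idx is empty")
        data, labels = data[idx], labels[idx]
    return float(np.mean(model.predict(data) == labels))
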