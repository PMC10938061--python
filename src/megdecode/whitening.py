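"""Channel whitening by PCA with all components retained.

Decorrelates channels by rotating into the eigenbasis of the pooled
training-timepoint covariance and rescaling by inverse square-root
eigenvalues.  Fit on training trials only and applied unchanged to
validation trials; the transform is square and invertible (a ridge of
``1e-12 * trace / n`` is added when the covariance is rank deficient).
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .epochs import Epochs


class ChannelWhitener(BaseEstimator, TransformerMixin):
    """Whitening transform over the channel dimension of epoched data.

    Operates on arrays of shape ``(n_trials, n_channels, n_times)``; all
    timepoints of all trials passed to :meth:`fit` are pooled into one
    sample of channel vectors.

    Attributes
    ----------
    mean_ : (n_channels,) array
        Pooled channel mean, removed before rotation.
    transform_ : (n_channels, n_channels) array
        Whitening matrix ``W``; whitened vectors are ``W @ (x - mean_)``.
    eigenvalues_ : (n_channels,) array
        Eigenvalues of the pooled covariance (descending).
    """

    def __init__(self, ridge: float = 0.0):
        self.ridge = ridge

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("X must be trials x channels x times")
        n_ch = X.shape[1]
        pooled = X.transpose(0, 2, 1).reshape(-1, n_ch)
        self.mean_ = pooled.mean(axis=0)
        cov = np.cov(pooled - self.mean_, rowvar=False, bias=True)
        cov = np.atleast_2d(cov)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        tiny = 1e-12 * np.trace(cov) / n_ch
        if evals[-1] <= tiny or self.ridge > 0:
            add = max(self.ridge, tiny)
            if self.ridge == 0:
                warnings.warn(
                    "rank-deficient channel covariance; adding ridge "
                    f"{add:.3e}", RuntimeWarning,
                )
            evals = evals + add
        self.eigenvalues_ = evals
        self.transform_ = (evecs / np.sqrt(evals)).T  # D^{-1/2} E^T
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        centered = X - self.mean_[None, :, None]
        return np.einsum("wc,nct->nwt", self.transform_, centered)


def fit_whitener(epochs: Epochs, train_idx) -> ChannelWhitener:
    """Fit a :class:`ChannelWhitener` on the training trials of ``epochs``."""
    train_idx = np.asarray(train_idx)
    if train_idx.size == 0:
        raise ValueError("train_idx is empty")
    return ChannelWhitener().fit(epochs.data[train_idx])


def apply_whitener(whitener: ChannelWhitener, epochs: Epochs) -> Epochs:
    """Return a new :class:`Epochs` with whitened data (labels shared)."""
    return Epochs(
        data=whitener.transform(epochs.data),
        labels=epochs.labels,
        sfreq=epochs.sfreq,
        t0=epochs.t0,
        layout=epochs.layout,
    )
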