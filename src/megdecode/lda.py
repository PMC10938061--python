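"""Shrinkage-LDA decoders on unsupervised (PCA) or supervised (NN)
channel projections.

Both decoders share the same evaluation pipeline: optional channel
whitening, a fixed [channels x components] projection applied per
timepoint, row-major flattening of the [timepoints x components] matrix,
and a multiclass LDA with a shared covariance shrunk toward scaled
identity ("auto" = Ledoit-Wolf analytic intensity).  They differ only in
where the projection comes from: variance-ranked principal directions
(LDA-PCA) versus the bottleneck matrix of a classification-trained
linear network (LDA-NN).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .base import AffineDecoder, flatten_features, project_epochs, validate_epoch_array
from .epochs import Epochs
from .nn import LinearDecodingNetwork
from .whitening import ChannelWhitener


def fit_lda(features, labels, shrinkage="auto") -> LinearDiscriminantAnalysis:
    """Multiclass shrinkage LDA on flat feature vectors.

    ``shrinkage="auto"`` uses the Ledoit-Wolf analytic intensity; any
    fraction in [0, 1] is accepted (1 shrinks the shared covariance all
    the way to scaled identity, making the rule nearest-class-mean under
    equal priors).  Prediction argmax ties break toward the lowest class
    index.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 classes")
    if shrinkage != "auto" and not 0.0 <= float(shrinkage) <= 1.0:
        raise ValueError("shrinkage must be 'auto' or a fraction in [0, 1]")
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    return lda.fit(np.asarray(features), labels)


def predict(model, features):
    """Top-1 class predictions of a fitted LDA on flat features."""
    return model.predict(np.asarray(features))


def fit_channel_pca(epochs, train_idx=None, n_components=80) -> np.ndarray:
    """Variance-ordered principal directions of the channel dimension.

    Pools every timepoint of every (training) trial into one
    timepoint-by-channel matrix and returns the top ``n_components``
    eigenvectors as a [channels x components] projection matrix.
    ``epochs`` may be an :class:`~megdecode.epochs.Epochs` or a raw
    (n, ch, t) array.
    """
    X = epochs.data if isinstance(epochs, Epochs) else np.asarray(epochs)
    if train_idx is not None:
        X = X[np.asarray(train_idx)]
    n_ch = X.shape[1]
    if n_components > n_ch:
        raise ValueError("n_components cannot exceed n_channels")
    pooled = np.transpose(X, (0, 2, 1)).reshape(-1, n_ch)
    pca = PCA(n_components=n_components, svd_solver="full").fit(pooled)
    return pca.components_.T


class _ProjectedLDABase(BaseEstimator, ClassifierMixin):
    """Common fit/predict machinery for the projected-LDA decoders."""

    def _fit_lda_on(self, X, y, whitener, projection):
        self.whitener_ = whitener
        self.projection_ = projection
        F = flatten_features(project_epochs(X, projection))
        self.lda_ = fit_lda(F, y, shrinkage=self.shrinkage)
        self.classes_ = self.lda_.classes_
        return self

    def _features(self, X):
        X = validate_epoch_array(X)
        if self.whitener_ is not None:
            X = self.whitener_.transform(X)
        return flatten_features(project_epochs(X, self.projection_))

    def decision_function(self, X):
        return self._features(X) @ self.lda_.coef_.T + self.lda_.intercept_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def collapse(self) -> AffineDecoder:
        """Evaluation-form affine decoder (for serialization / PFI)."""
        wm = None if self.whitener_ is None else self.whitener_.transform_
        mu = None if self.whitener_ is None else self.whitener_.mean_
        return AffineDecoder(
            weights=self.lda_.coef_.T, bias=self.lda_.intercept_,
            classes=self.classes_, whiten_mean=mu, whiten_matrix=wm,
            projection=self.projection_)


class LDAPCADecoder(_ProjectedLDABase):
    """Full-epoch LDA on a variance-ranked (PCA) channel projection.

    Attributes (fitted): ``whitener_``, ``projection_`` (channels x
    components), ``lda_``, ``captured_variance_`` (fraction of pooled
    variance retained by the projection).
    """

    def __init__(self, n_components=80, shrinkage="auto", whiten=True):
        self.n_components = n_components
        self.shrinkage = shrinkage
        self.whiten = whiten

    def fit(self, X, y):
        X = validate_epoch_array(X)
        whitener = ChannelWhitener().fit(X) if self.whiten else None
        Xw = whitener.transform(X) if whitener is not None else X
        pooled = np.transpose(Xw, (0, 2, 1)).reshape(-1, Xw.shape[1])
        pca = PCA(n_components=self.n_components, svd_solver="full").fit(pooled)
        self.captured_variance_ = float(pca.explained_variance_ratio_.sum())
        return self._fit_lda_on(Xw, y, whitener, pca.components_.T)


class LDANNDecoder(_ProjectedLDABase):
    """Full-epoch LDA on the projection learned by the linear network.

    Parameters
    ----------
    network : LinearDecodingNetwork
        Either already fitted (its whitener and bottleneck matrix are
        reused; LDA training data is expected in the same raw space the
        network was fitted on) or unfitted (a clone is trained on the
        data passed to :meth:`fit`, then its projection is extracted).
    shrinkage : "auto" or fraction in [0, 1].
    """

    def __init__(self, network=None, shrinkage="auto"):
        self.network = network
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X = validate_epoch_array(X)
        net = self.network if self.network is not None else LinearDecodingNetwork()
        if not hasattr(net, "W_dr_"):
            net = clone(net).fit(X, y)
        self.network_ = net
        Xw = net.whitener_.transform(X) if net.whitener_ is not None else X
        return self._fit_lda_on(Xw, y, net.whitener_, net.W_dr_.copy())
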