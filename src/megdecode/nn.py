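"""Deep linear network with learnable channel-dimensionality reduction.

A four-layer fully connected *linear* network: the first layer multiplies
the [timepoints x channels] epoch by a learnable [channels x components]
matrix (a supervised counterpart of channel PCA), the result is flattened
and passed through three affine layers ending in class logits.  Because
no nonlinearity is used, the evaluation-mode model is a single affine
map; training nevertheless benefits from the deep parametrisation (deep
linear networks have nonlinear gradient dynamics) and from the heavy
dropout regularisation in front of each affine layer.

Trained with softmax cross-entropy and Adam, implemented in NumPy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .base import AffineDecoder, flatten_features, project_epochs, validate_epoch_array
from .epochs import Epochs, SplitIndices
from .whitening import ChannelWhitener


@dataclass
class TrainConfig:
    """Optimisation settings for the network.

    2000 full passes with Adam lets training accuracy converge without
    early stopping; validation data is used for reporting only.
    """

    n_epochs: int = 2000
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class LinearDecodingNetwork(BaseEstimator, ClassifierMixin):
    """Linear NN decoder with supervised dimensionality reduction.

    Parameters
    ----------
    n_components : int
        Width of the channel-projection bottleneck (default 80).
    hidden_sizes : (int, int)
        Sizes of the two intermediate affine layers (default 1000, 300,
        roughly geometrically spaced between a 4000-dim input and ~100
        classes).
    dropout : float
        Drop probability of the inverted-dropout masks applied before
        each of the three affine layers during training (default 0.7).
        No dropout is applied to the projection-layer input.
    n_epochs, learning_rate, batch_size : optimisation settings; the
        full training set is one batch when smaller than ``batch_size``.
    whiten : bool
        Fit a :class:`~megdecode.whitening.ChannelWhitener` on the
        training data and apply it inside the model (default True).
    random_state : int
        Seeds initialisation, batch shuffling and dropout.

    Attributes
    ----------
    W_dr_ : (n_channels, n_components) learned projection matrix.
    layers_ : list of (weights, bias) for the three affine layers.
    classes_ : class labels.
    history_ : list of (epoch, loss, train_accuracy) log records.
    whitener_ : fitted whitener or None.
    """

    def __init__(self, n_components=80, hidden_sizes=(1000, 300), dropout=0.7,
                 n_epochs=2000, learning_rate=1e-3, batch_size=64,
                 whiten=True, random_state=0, log_every=100):
        self.n_components = n_components
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.n_epochs = n_epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.whiten = whiten
        self.random_state = random_state
        self.log_every = log_every

    # ---------------------------------------------------------------- fit
    def fit(self, X, y):
        X = validate_epoch_array(X)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        n, n_ch, n_t = X.shape
        n_cls = self.classes_.size
        if n_cls < 2:
            raise ValueError("need at least 2 classes")
        if self.n_components > n_ch:
            raise ValueError("n_components cannot exceed n_channels")

        self.whitener_ = None
        if self.whiten:
            self.whitener_ = ChannelWhitener().fit(X)
            X = self.whitener_.transform(X)

        rng = np.random.default_rng(self.random_state)
        h1, h2 = self.hidden_sizes
        d_in = n_t * self.n_components

        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-lim, lim, size=shape).astype(np.float32)

        W_dr = glorot((n_ch, self.n_components))
        W1, b1 = glorot((d_in, h1)), np.zeros(h1, np.float32)
        W2, b2 = glorot((h1, h2)), np.zeros(h2, np.float32)
        W3, b3 = glorot((h2, n_cls)), np.zeros(n_cls, np.float32)
        params = [W_dr, W1, b1, W2, b2, W3, b3]
        opt = _Adam(params, self.learning_rate)

        E = np.transpose(X, (0, 2, 1)).astype(np.float32)  # (n, t, ch)
        keep = 1.0 - self.dropout
        batch = n if n < self.batch_size else self.batch_size
        self.history_ = []

        for ep in range(self.n_epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            ep_correct = 0
            for start in range(0, n, batch):
                sel = order[start:start + batch]
                Eb, yb = E[sel], y_enc[sel]
                B = len(sel)
                P = Eb @ W_dr                       # (B, t, k)
                F = P.reshape(B, -1)
                masks = [
                    (rng.random((B, d)) < keep).astype(np.float32) / keep
                    for d in (d_in, h1, h2)
                ] if self.dropout > 0 else [1.0, 1.0, 1.0]
                D0 = F * masks[0]
                H1 = D0 @ W1 + b1
                D1 = H1 * masks[1]
                H2 = D1 @ W2 + b2
                D2 = H2 * masks[2]
                logits = D2 @ W3 + b3

                logits64 = logits.astype(np.float64)
                logits64 -= logits64.max(axis=1, keepdims=True)
                expl = np.exp(logits64)
                probs = expl / expl.sum(axis=1, keepdims=True)
                loss = -np.mean(np.log(probs[np.arange(B), yb] + 1e-300))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged at epoch {ep}: loss={loss}")
                ep_loss += loss * B
                ep_correct += int(np.sum(np.argmax(logits, axis=1) == yb))

                dlogits = probs
                dlogits[np.arange(B), yb] -= 1.0
                dlogits = (dlogits / B).astype(np.float32)
                gW3 = D2.T @ dlogits
                gb3 = dlogits.sum(0)
                dH2 = (dlogits @ W3.T) * masks[2]
                gW2 = D1.T @ dH2
                gb2 = dH2.sum(0)
                dH1 = (dH2 @ W2.T) * masks[1]
                gW1 = D0.T @ dH1
                gb1 = dH1.sum(0)
                dF = (dH1 @ W1.T) * masks[0]
                dP = dF.reshape(B, n_t, self.n_components)
                gW_dr = np.einsum("btc,btk->ck", Eb, dP)
                opt.step([gW_dr, gW1, gb1, gW2, gb2, gW3, gb3])

            if (ep + 1) % self.log_every == 0 or ep == self.n_epochs - 1:
                self.history_.append((ep + 1, ep_loss / n, ep_correct / n))

        self.W_dr_ = W_dr.astype(np.float64)
        self.layers_ = [
            (W1.astype(np.float64), b1.astype(np.float64)),
            (W2.astype(np.float64), b2.astype(np.float64)),
            (W3.astype(np.float64), b3.astype(np.float64)),
        ]
        self.n_times_ = n_t
        self.n_channels_in_ = n_ch
        return self

    # ------------------------------------------------------------ forward
    def _eval_features(self, X):
        X = validate_epoch_array(X)
        if self.whitener_ is not None:
            X = self.whitener_.transform(X)
        return flatten_features(project_epochs(X, self.W_dr_))

    def decision_function(self, X):
        """Evaluation-mode class logits (no dropout)."""
        F = self._eval_features(X)
        for W, b in self.layers_:
            F = F @ W + b
        return F

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))

    # ----------------------------------------------------------- collapse
    def collapse(self) -> AffineDecoder:
        """Fold the evaluation-mode model into a single affine map.

        The returned :class:`AffineDecoder` applies the same whitening
        and projection and reproduces ``decision_function`` to floating
        point accuracy (the composition of affine maps is affine).
        """
        (W1, b1), (W2, b2), (W3, b3) = self.layers_
        W = W1 @ W2 @ W3
        b = (b1 @ W2 + b2) @ W3 + b3
        wm = None if self.whitener_ is None else self.whitener_.transform_
        mu = None if self.whitener_ is None else self.whitener_.mean_
        return AffineDecoder(weights=W, bias=b, classes=self.classes_,
                             whiten_mean=mu, whiten_matrix=wm,
                             projection=self.W_dr_)


def train_nn(epochs: Epochs, split: SplitIndices, cfg: TrainConfig | None = None,
             **net_params) -> LinearDecodingNetwork:
    """Train a :class:`LinearDecodingNetwork` on the training split."""
    cfg = cfg or TrainConfig()
    net = LinearDecodingNetwork(
        n_epochs=cfg.n_epochs, learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size, random_state=cfg.seed, **net_params)
    return net.fit(epochs.data[split.train], epochs.labels[split.train])


def collapse_nn(model: LinearDecodingNetwork) -> AffineDecoder:
    """Single affine map equivalent to the evaluation-mode network."""
    return model.collapse()


def extract_projection(model: LinearDecodingNetwork) -> np.ndarray:
    """The learned [channels x components] projection matrix (a copy)."""
    return model.W_dr_.copy()
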