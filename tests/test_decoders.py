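"""Network training, affine collapse, projections and shrinkage LDA."""

import numpy as np
import pytest

import megdecode as md
from megdecode.lda import fit_lda


class TestNetwork:
    def test_separable_toy_reaches_perfect_training_accuracy(self):
        """Two noiseless constant spatial patterns are linearly separable
        and learned within 200 passes."""
        rng = np.random.default_rng(0)
        pat = rng.standard_normal((2, 6))
        y = np.repeat([0, 1], 20)
        X = pat[y][:, :, None] * np.ones((1, 1, 30))
        net = md.LinearDecodingNetwork(
            n_components=3, hidden_sizes=(20, 10), dropout=0.0,
            n_epochs=200, whiten=False, random_state=0, log_every=200)
        net.fit(X, y)
        assert net.history_[-1][2] == 1.0
        assert net.score(X, y) == 1.0

    def test_collapse_matches_eval_forward(self, trained_net, benchmark,
                                           rng):
        """Evaluation-mode logits equal the single collapsed affine map
        (composition of affine maps) to 1e-5 relative tolerance."""
        cfg, epochs, truth, split = benchmark
        X = epochs.data[split.validation[:20]]
        aff = md.collapse_nn(trained_net)
        a = trained_net.decision_function(X)
        b = aff.decision_function(X)
        assert np.max(np.abs(a - b)) <= 1e-5 * np.max(np.abs(a))
        # and on arbitrary random inputs
        Xr = rng.standard_normal((50,) + X.shape[1:])
        a, b = trained_net.decision_function(Xr), aff.decision_function(Xr)
        assert np.max(np.abs(a - b)) <= 1e-5 * np.max(np.abs(a))

    def test_zero_input_maps_to_collapsed_bias(self, trained_net):
        aff = trained_net.collapse()
        X = np.zeros((1, trained_net.n_channels_in_, trained_net.n_times_))
        np.testing.assert_allclose(
            trained_net.decision_function(X)[0],
            aff.decision_function(X)[0], rtol=1e-9, atol=1e-9)

    def test_projection_extraction_stable_and_nonintrusive(self,
                                                           trained_net,
                                                           benchmark):
        cfg, epochs, truth, split = benchmark
        X = epochs.data[split.validation[:8]]
        before = trained_net.decision_function(X)
        P1 = md.extract_projection(trained_net)
        P2 = md.extract_projection(trained_net)
        assert P1.shape == (epochs.n_channels, trained_net.n_components)
        np.testing.assert_array_equal(P1, P2)
        P1[:] = 0.0  # a copy: mutating it must not touch the model
        np.testing.assert_array_equal(trained_net.decision_function(X),
                                      before)

    def test_training_divergence_raises(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((16, 4, 20)) * 1e3
        y = np.arange(16) % 2
        net = md.LinearDecodingNetwork(
            n_components=2, hidden_sizes=(8, 4), learning_rate=1e18,
            n_epochs=50, whiten=False, random_state=0)
        with pytest.raises(RuntimeError, match="diverged"):
            net.fit(X, y)

    def test_component_count_validated(self):
        X = np.zeros((8, 3, 10))
        net = md.LinearDecodingNetwork(n_components=5, n_epochs=1)
        with pytest.raises(ValueError):
            net.fit(X, np.arange(8) % 2)


class TestShrinkageLDA:
    def test_well_separated_gaussians(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.standard_normal((200, 2)) + [5, 0],
                       rng.standard_normal((200, 2)) - [5, 0]])
        y = np.repeat([0, 1], 200)
        Xv = np.vstack([rng.standard_normal((100, 2)) + [5, 0],
                        rng.standard_normal((100, 2)) - [5, 0]])
        yv = np.repeat([0, 1], 100)
        lda = fit_lda(X, y, shrinkage="auto")
        assert np.mean(lda.predict(Xv) == yv) >= 0.99

    def test_full_shrinkage_equals_nearest_class_mean(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 5)) + rng.integers(0, 3, 60)[:, None]
        y = np.repeat(np.arange(3), 20)
        lda = fit_lda(X, y, shrinkage=1.0)
        probes = rng.standard_normal((40, 5)) * 2
        means = np.stack([X[y == c].mean(0) for c in range(3)])
        nearest = np.argmin(
            ((probes[:, None] - means[None]) ** 2).sum(-1), axis=1)
        np.testing.assert_array_equal(lda.predict(probes), nearest)

    def test_two_dim_toy_matches_hand_computed_discriminant(self):
        """4 points per class with identity-proportional within-class
        scatter: the decision boundary is the midline x = 3."""
        X = np.array([[0, 0], [1, 0], [0, 1], [1, 1],
                      [5, 0], [6, 0], [5, 1], [6, 1]], dtype=float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        lda = fit_lda(X, y, shrinkage=0.0)
        # hand computation: Sigma = 0.25 I, w = Sigma^-1 (mu1-mu0) = (20, 0)
        w = lda.coef_[1] - lda.coef_[0] if lda.coef_.shape[0] == 2 else None
        probes = np.array([[2.9, 0.5], [3.1, 0.5], [-1, 0], [7, 1]])
        np.testing.assert_array_equal(lda.predict(probes), [0, 1, 0, 1])
        np.testing.assert_allclose(
            lda.decision_function(np.array([[3.0, 0.5]])), 0.0, atol=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_lda(np.zeros((5, 2)), np.zeros(5))

    def test_shrinkage_fraction_validated(self):
        with pytest.raises(ValueError):
            fit_lda(np.zeros((4, 2)), [0, 0, 1, 1], shrinkage=1.5)


class TestChannelPCA:
    def test_complete_basis_preserves_variance(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 5, 40)) * np.arange(1, 6)[None, :, None]
        P = md.fit_channel_pca(X, n_components=5)
        pooled = X.transpose(0, 2, 1).reshape(-1, 5)
        pooled = pooled - pooled.mean(0)
        total = pooled.var(axis=0).sum()
        projected = (pooled @ P).var(axis=0).sum()
        assert projected == pytest.approx(total, rel=1e-8)

    def test_rank_one_data_captured_by_first_component(self):
        rng = np.random.default_rng(5)
        u = rng.standard_normal(6)
        src = rng.standard_normal((20, 1, 50))
        X = u[None, :, None] * src
        P = md.fit_channel_pca(X, n_components=1)
        pooled = X.transpose(0, 2, 1).reshape(-1, 6)
        pooled = pooled - pooled.mean(0)
        frac = (pooled @ P).var(axis=0).sum() / pooled.var(axis=0).sum()
        assert frac >= 0.99999

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            md.fit_channel_pca(np.zeros((4, 3, 5)), n_components=4)

    def test_captured_variance_reported_by_decoder(self, benchmark):
        cfg, epochs, truth, split = benchmark
        dec = md.LDAPCADecoder(n_components=10, whiten=False).fit(
            epochs.data[split.train], epochs.labels[split.train])
        assert 0.0 < dec.captured_variance_ <= 1.0


class _Fixed:
    def __init__(self, out):
        self.out = np.asarray(out)

    def predict(self, X):
        return self.out[: len(X)]


def test_accuracy_fractions():
    epochs = md.Epochs(np.zeros((4, 2, 5)), np.array([0, 1, 0, 1]), 100.0)
    assert md.accuracy(_Fixed([0, 1, 0, 1]), epochs) == 1.0
    assert md.accuracy(_Fixed([1, 0, 1, 0]), epochs) == 0.0
    assert md.accuracy(_Fixed([0, 1, 0, 0]), epochs) == 0.75
    with pytest.raises(ValueError):
        md.accuracy(_Fixed([0]), epochs, idx=np.array([], dtype=int))
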