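"""Splitting, whitening, window bookkeeping and flattening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import megdecode as md
from megdecode.whitening import ChannelWhitener


class TestStratifiedSplit:
    def test_four_to_one_counts_per_class(self):
        labels = np.repeat(np.arange(8), 30)
        split = md.stratified_split(labels, 0.2, seed=0)
        for c in range(8):
            assert np.sum(labels[split.validation] == c) == 6
            assert np.sum(labels[split.train] == c) == 24

    def test_minimum_two_trials_splits_one_one(self):
        labels = np.array([0, 0, 1, 1])
        split = md.stratified_split(labels, 0.2, seed=0)
        assert len(split.train) == 2 and len(split.validation) == 2

    def test_deterministic_and_exhaustive(self):
        labels = np.repeat(np.arange(5), 13)
        a = md.stratified_split(labels, 0.2, seed=3)
        b = md.stratified_split(labels, 0.2, seed=3)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.validation, b.validation)
        union = np.sort(np.concatenate([a.train, a.validation]))
        np.testing.assert_array_equal(union, np.arange(labels.size))
        assert np.intersect1d(a.train, a.validation).size == 0

    def test_single_trial_class_rejected(self):
        with pytest.raises(ValueError):
            md.stratified_split(np.array([0, 0, 1]), 0.2, seed=0)


class TestWhitening:
    def test_toy_two_channel_covariance_whitened_exactly(self):
        # oracle: eigendecomposition of [[2,1],[1,2]] drives a known
        # transform; whitened covariance must be identity to 1e-10
        rng = np.random.default_rng(0)
        root = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 2.0]]))
        X = np.einsum("cd,ndt->nct", root, rng.standard_normal((50, 2, 40)))
        w = ChannelWhitener().fit(X)
        Xw = w.transform(X)
        pooled = Xw.transpose(0, 2, 1).reshape(-1, 2)
        cov = np.cov(pooled - pooled.mean(0), rowvar=False, bias=True)
        np.testing.assert_allclose(cov, np.eye(2), atol=1e-10)

    def test_train_covariance_identity_on_benchmark(self, benchmark):
        cfg, epochs, truth, split = benchmark
        w = md.fit_whitener(epochs, split.train)
        ew = md.apply_whitener(w, epochs)
        pooled = ew.data[split.train].transpose(0, 2, 1).reshape(
            -1, epochs.n_channels)
        cov = np.cov(pooled - pooled.mean(0), rowvar=False, bias=True)
        assert np.linalg.norm(cov - np.eye(epochs.n_channels)) < \
            1e-6 * epochs.n_channels

    def test_whitening_already_white_data_gives_orthogonal_transform(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((60, 4, 50))
        first = ChannelWhitener().fit(X)
        Xw = first.transform(X)
        second = ChannelWhitener().fit(Xw)
        WWt = second.transform_ @ second.transform_.T
        np.testing.assert_allclose(WWt, np.eye(4), atol=1e-6)

    def test_rank_deficient_covariance_ridged_with_warning(self):
        X = np.zeros((10, 3, 20))
        X[:, 0] = np.random.default_rng(2).standard_normal((10, 20))
        X[:, 1] = X[:, 0]  # duplicated channel -> singular covariance
        with pytest.warns(RuntimeWarning):
            w = ChannelWhitener().fit(X)
        assert np.all(np.isfinite(w.transform_))


class TestWindows:
    @pytest.mark.parametrize("n_times,length,step,expected", [
        (100, 10, 1, 90),   # the convention anchor
        (10, 10, 1, 0),     # boundary: full-epoch path must be used
        (50, 10, 1, 40),
        (90, 10, 1, 80),
        (100, 10, 2, 45),
    ])
    def test_window_count_convention(self, n_times, length, step, expected):
        spec = md.sliding_windows(n_times, length, step)
        assert spec.n_windows == expected
        if expected:
            assert spec.start_offsets[0] == 0
            assert spec.start_offsets[-1] <= n_times - length - 1

    def test_window_too_long_rejected(self):
        with pytest.raises(ValueError):
            md.sliding_windows(9, 10, 1)

    def test_step_one_covers_all_but_tail(self):
        spec = md.sliding_windows(40, 5, 1)
        covered = np.zeros(40, bool)
        for s in spec.start_offsets:
            covered[s:s + 5] = True
        assert covered[:-5].all()

    def test_centers_in_seconds(self):
        spec = md.sliding_windows(100, 10, 1)
        centers = spec.centers(sfreq=100.0)
        assert centers[0] == pytest.approx(0.05)
        assert centers[1] - centers[0] == pytest.approx(0.01)


class TestFlatten:
    @given(st.integers(1, 12), st.integers(1, 12))
    @settings(max_examples=20, deadline=None)
    def test_round_trip_bit_identical(self, t, k):
        rng = np.random.default_rng(t * 100 + k)
        x = rng.standard_normal((t, k))
        flat = md.flatten_epoch(x)
        assert flat.shape == (t * k,)
        np.testing.assert_array_equal(flat.reshape(t, k), x)

    def test_fifty_by_eighty_gives_4000(self):
        assert md.flatten_epoch(np.zeros((50, 80))).shape == (4000,)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            md.flatten_epoch(np.array([[np.nan]]))


def test_epochs_hdf5_round_trip(tmp_path, benchmark):
    cfg, epochs, truth, split = benchmark
    path = tmp_path / "epochs.h5"
    epochs.save(path)
    loaded = md.Epochs.load(path)
    np.testing.assert_allclose(loaded.data, epochs.data, atol=1e-6)
    np.testing.assert_array_equal(loaded.labels, epochs.labels)
    assert loaded.sfreq == epochs.sfreq
    np.testing.assert_allclose(loaded.layout.positions,
                               epochs.layout.positions)
    assert [list(n) for n in loaded.layout.neighborhoods] == \
        [list(n) for n in epochs.layout.neighborhoods]
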