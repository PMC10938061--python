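"""PFI invariants: zero loss on invariant blocks, reversibility,
determinism, model agnosticism, and transform exactness."""

import numpy as np
import pytest
import scipy.signal

import megdecode as md
from megdecode.pfi import STFTConfig, _ola_denominator, istft, stft


class _MeanSign:
    """Tiny deterministic decoder: label = sign of the trial mean."""

    def predict(self, X):
        return (X.mean(axis=(1, 2)) > 0).astype(int)


def _toy_epochs(data, labels=None):
    n = data.shape[0]
    labels = np.arange(n) % 2 if labels is None else labels
    return md.Epochs(data, labels, 100.0, layout=md.make_sensor_layout(
        data.shape[1] // 3, seed=0))


class TestZeroLossOnInvariantBlocks:
    def test_channel_constant_data_immune_to_temporal_pfi(self):
        """Data identical across channels: a channel permutation is a
        no-op, so the loss is exactly zero."""
        rng = np.random.default_rng(0)
        per_time = rng.standard_normal((12, 1, 40))
        epochs = _toy_epochs(np.repeat(per_time, 6, axis=1))
        pmap = md.temporal_pfi(_MeanSign(), epochs, window=10,
                               plan=md.PermutationPlan(3, seed=0))
        np.testing.assert_array_equal(pmap.losses, 0.0)

    def test_time_constant_data_immune_to_spatial_pfi(self):
        rng = np.random.default_rng(1)
        per_chan = rng.standard_normal((12, 6, 1))
        epochs = _toy_epochs(np.repeat(per_chan, 40, axis=2))
        pmap = md.spatial_pfi(_MeanSign(), epochs,
                              plan=md.PermutationPlan(3, seed=0))
        np.testing.assert_array_equal(pmap.losses, 0.0)

    def test_constant_block_immune_to_spatiotemporal_pfi(self):
        epochs = _toy_epochs(np.ones((8, 6, 40)) *
                             np.linspace(-1, 1, 8)[:, None, None])
        pmap = md.spatiotemporal_pfi(_MeanSign(), epochs, window=10,
                                     plan=md.PermutationPlan(2, seed=0))
        np.testing.assert_array_equal(pmap.losses, 0.0)

    def test_empty_band_near_zero_loss(self, benchmark, lda_nn):
        """A band above the generator's lowpass carries only white
        noise: permuting it costs nothing beyond evaluation noise."""
        cfg, epochs, truth, split = benchmark
        pmap = md.spectral_pfi(lda_nn, epochs, split.validation,
                               bands=[(30.0, 45.0)],
                               plan=md.PermutationPlan(10, seed=2))
        assert abs(pmap.mean_loss()[0]) <= 0.05


class TestBookkeeping:
    def test_input_data_never_modified(self, benchmark, lda_nn):
        cfg, epochs, truth, split = benchmark
        before = epochs.data.copy()
        idx = split.validation[:16]
        plan = md.PermutationPlan(2, seed=3)
        md.temporal_pfi(lda_nn, epochs, idx, plan=plan)
        md.spatial_pfi(lda_nn, epochs, idx, plan=plan)
        md.spectral_pfi(lda_nn, epochs, idx, bands=[(8.0, 12.0)], plan=plan)
        md.temporospectral_pfi(lda_nn, epochs, idx, bands=[(10.0, 10.0)],
                               plan=plan)
        np.testing.assert_array_equal(epochs.data, before)

    def test_fixed_plan_seed_bitwise_reproducible(self, benchmark, lda_nn):
        cfg, epochs, truth, split = benchmark
        idx = split.validation[:16]
        a = md.temporal_pfi(lda_nn, epochs, idx,
                            plan=md.PermutationPlan(3, seed=11))
        b = md.temporal_pfi(lda_nn, epochs, idx,
                            plan=md.PermutationPlan(3, seed=11))
        np.testing.assert_array_equal(a.losses, b.losses)
        c = md.temporal_pfi(lda_nn, epochs, idx,
                            plan=md.PermutationPlan(3, seed=12))
        assert not np.array_equal(a.losses, c.losses)

    def test_loss_bounded_by_baseline(self, temporal_map):
        assert np.all(temporal_map.losses <= temporal_map.baseline + 1e-12)

    def test_tidy_frame_layout(self, temporal_map):
        df = temporal_map.to_frame()
        assert set(df.columns) == {"time", "repetition", "accuracy_loss"}
        assert len(df) == temporal_map.losses.size


class TestModelAgnosticism:
    def test_collapsed_model_gives_identical_maps(self, benchmark, lda_nn):
        """The PFI functions see models only through predict(): the
        collapsed affine form must give bit-identical maps."""
        cfg, epochs, truth, split = benchmark
        idx = split.validation[:24]
        plan = md.PermutationPlan(3, seed=5)
        a = md.temporal_pfi(lda_nn, epochs, idx, plan=plan)
        b = md.temporal_pfi(lda_nn.collapse(), epochs, idx, plan=plan)
        np.testing.assert_array_equal(a.losses, b.losses)

    def test_runs_against_the_network_decoder(self, benchmark, trained_net):
        cfg, epochs, truth, split = benchmark
        pmap = md.spatial_pfi(trained_net, epochs, split.validation[:16],
                              plan=md.PermutationPlan(2, seed=6))
        assert pmap.losses.shape == (10, 2)


class TestSpectralMachinery:
    def test_dft_round_trip_identity(self, rng):
        x = rng.standard_normal((5, 3, 90))
        xr = np.fft.irfft(np.fft.rfft(x, axis=-1), n=90, axis=-1)
        assert np.max(np.abs(x - xr)) < 1e-8 * np.max(np.abs(x))

    def test_stft_round_trip_exact(self, rng):
        cfg = STFTConfig()
        for n_times in (90, 100, 37):
            x = rng.standard_normal((4, 3, n_times))
            xr = istft(stft(x, cfg), cfg, n_times)
            assert np.max(np.abs(x - xr)) < 1e-8 * np.max(np.abs(x))

    def test_stft_band_centers_10hz_apart(self):
        cfg = STFTConfig(length=10)
        np.testing.assert_allclose(cfg.freqs(100.0),
                                   [0, 10, 20, 30, 40, 50])

    def test_interior_frames_match_scipy_short_time_fft(self, rng):
        """Independent cross-check of the frame coefficients against
        scipy's ShortTimeFFT at matching frame positions."""
        x = rng.standard_normal(60)
        cfg = STFTConfig(length=10)
        L = cfg.length
        ours = stft(x, cfg)
        win = cfg.win()
        sft = scipy.signal.ShortTimeFFT(win, hop=1, fs=100.0,
                                        fft_mode="onesided")
        theirs = sft.stft(x)
        # scipy references phases to the window centre (m_mid = L//2);
        # our frames use the window start, a factor exp(2*pi*i*q*mid/L)
        phase = np.exp(2j * np.pi * np.arange(L // 2 + 1) * (L // 2) / L)
        for start in (0, 17, 50):
            f = cfg.frame_of_start(start)
            np.testing.assert_allclose(ours[f], theirs[:, f] * phase,
                                       atol=1e-10)

    def test_ola_weights_uniform_over_epoch(self):
        cfg = STFTConfig(length=10)
        denom = _ola_denominator(cfg, 90)
        interior = denom[cfg.length - 1:cfg.length - 1 + 90]
        np.testing.assert_allclose(interior, interior[0])

    def test_band_outside_nyquist_rejected(self, benchmark, lda_nn):
        cfg, epochs, truth, split = benchmark
        with pytest.raises(ValueError):
            md.spectral_pfi(lda_nn, epochs, split.validation[:8],
                            bands=[(40.0, 80.0)],
                            plan=md.PermutationPlan(1, seed=0))


def test_mean_loss_nonnegative_on_planted_blocks(temporal_map, benchmark):
    """Blocks overlapping the planted burst lose accuracy on average."""
    cfg, epochs, truth, split = benchmark
    t = temporal_map.axes["time"]
    inside = (t >= 0.10) & (t <= 0.20)
    assert np.all(temporal_map.mean_loss()[inside] >= 0.0)
    assert temporal_map.mean_loss()[inside].max() > 0.1
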