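"""Permutation feature importance for full-epoch decoders.

A single trained full-epoch model is interrogated by disrupting one
block of the input at a time — a time window, a sensor site, a
spatiotemporal block, a frequency band, or products of these — and
measuring the drop in validation accuracy relative to the intact data
(the *accuracy loss*).  Blocks whose contents are invariant under the
applied permutation yield exactly zero loss; informative blocks yield
positive loss in expectation.

All variants permute *within* trials, across the complementary
dimension of the block (e.g. a time window is disrupted by shuffling
the channel dimension inside it), as opposed to the across-trials PFI
of the general machine-learning literature.  One permutation is drawn
per (block, repetition) and applied identically to every evaluated
trial, so repetitions are interpretable as plan-level samples; the
evaluated dataset itself is never modified in place.

The spectral variants move Fourier (or short-time Fourier)
coefficients between channels and invert the transform, so disrupted
trials remain real time series with unchanged per-channel spectra
outside the targeted band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from .base import validate_epoch_array
from .epochs import Epochs, sliding_windows
from .layout import SensorLayout


@dataclass
class PermutationPlan:
    """How many permutation repetitions to run, and their seed."""

    n_permutations: int = 10
    seed: int = 0
    scope: str = ""

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class PFIMap:
    """Accuracy-loss map over one or two block axes.

    ``losses`` has shape ``(*axis lengths, n_permutations)``; the
    per-permutation repetitions are retained so confidence intervals
    can be computed across them.
    """

    axes: dict                 # axis name -> coordinate array
    losses: np.ndarray
    baseline: float
    plan: PermutationPlan = field(default_factory=PermutationPlan)

    def mean_loss(self) -> np.ndarray:
        """Mean accuracy loss across permutation repetitions."""
        return self.losses.mean(axis=-1)

    def ci(self, level: float = 0.95):
        """Percentile interval across permutation repetitions."""
        a = 100 * (1 - level) / 2
        return (np.percentile(self.losses, a, axis=-1),
                np.percentile(self.losses, 100 - a, axis=-1))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (coordinates, repetition)."""
        names = list(self.axes)
        grids = np.meshgrid(*[self.axes[n] for n in names],
                            np.arange(self.losses.shape[-1]), indexing="ij")
        cols = {n: g.ravel() for n, g in zip(names + ["repetition"], grids)}
        cols["accuracy_loss"] = self.losses.ravel()
        return pd.DataFrame(cols)


def _setup(model, epochs: Epochs, idx):
    X = epochs.data if idx is None else epochs.data[np.asarray(idx)]
    y = epochs.labels if idx is None else epochs.labels[np.asarray(idx)]
    X = validate_epoch_array(X).copy()  # never touch the caller's array
    baseline = float(np.mean(model.predict(X) == y))
    return X, y, baseline


def _acc(model, X, y) -> float:
    return float(np.mean(model.predict(X) == y))


# ----------------------------------------------------------------- temporal
def temporal_pfi(model, epochs: Epochs, idx=None, window: int = 10,
                 step: int = 1, plan: PermutationPlan | None = None,
                 per_timepoint: bool = False) -> PFIMap:
    """Accuracy loss per time window, disrupted by channel shuffling.

    For each window a random permutation of all channel indices is
    applied to every timepoint inside the window (the rest of the trial
    is untouched).  With ``per_timepoint=True`` an independent channel
    permutation is drawn for every timepoint in the window instead of
    one shared permutation per repetition.
    """
    plan = plan or PermutationPlan(scope="temporal")
    X, y, baseline = _setup(model, epochs, idx)
    n_ch, n_t = X.shape[1], X.shape[2]
    spec = sliding_windows(n_t, window, step)
    rng = np.random.default_rng(plan.seed)
    losses = np.empty((spec.n_windows, plan.n_permutations))
    for i, s in enumerate(spec.start_offsets):
        for r in range(plan.n_permutations):
            Xp = X.copy()
            if per_timepoint:
                for t in range(s, s + window):
                    Xp[:, :, t] = X[:, rng.permutation(n_ch), t]
            else:
                perm = rng.permutation(n_ch)
                Xp[:, :, s:s + window] = X[:, perm, s:s + window]
            losses[i, r] = baseline - _acc(model, Xp, y)
    return PFIMap(axes={"time": spec.centers(epochs.sfreq, epochs.t0)},
                  losses=losses, baseline=baseline, plan=plan)


# ------------------------------------------------------------------ spatial
def spatial_pfi(model, epochs: Epochs, idx=None,
                layout: SensorLayout | None = None,
                plan: PermutationPlan | None = None) -> PFIMap:
    """Accuracy loss per sensor site, disrupted by timepoint shuffling.

    For each site the timepoint order of each of its 3 co-located
    channels is independently permuted (each channel draws its own
    permutation), destroying that site's temporal structure while
    leaving every other channel intact.
    """
    plan = plan or PermutationPlan(scope="spatial")
    layout = layout or epochs.layout
    if layout is None:
        raise ValueError("no sensor layout available")
    X, y, baseline = _setup(model, epochs, idx)
    n_t = X.shape[2]
    rng = np.random.default_rng(plan.seed)
    losses = np.empty((layout.n_sites, plan.n_permutations))
    for s in range(layout.n_sites):
        chans = layout.site_channels(s)
        for r in range(plan.n_permutations):
            Xp = X.copy()
            for ch in chans:
                Xp[:, ch, :] = X[:, ch, rng.permutation(n_t)]
            losses[s, r] = baseline - _acc(model, Xp, y)
    return PFIMap(axes={"site": np.arange(layout.n_sites)},
                  losses=losses, baseline=baseline, plan=plan)


# ----------------------------------------------------------- spatiotemporal
def spatiotemporal_pfi(model, epochs: Epochs, idx=None,
                       layout: SensorLayout | None = None, window: int = 10,
                       step: int = 1,
                       plan: PermutationPlan | None = None) -> PFIMap:
    """Accuracy loss per (site neighbourhood x time window) block.

    The block is the 12 channels of a site's neighbourhood (the site
    plus its 3 nearest sites) by the window's timepoints; all values in
    the block are shuffled jointly (flatten, permute, reshape).
    """
    plan = plan or PermutationPlan(scope="spatiotemporal")
    layout = layout or epochs.layout
    if layout is None:
        raise ValueError("no sensor layout available")
    X, y, baseline = _setup(model, epochs, idx)
    spec = sliding_windows(X.shape[2], window, step)
    rng = np.random.default_rng(plan.seed)
    losses = np.empty((layout.n_sites, spec.n_windows, plan.n_permutations))
    for s in range(layout.n_sites):
        chans = layout.neighborhood_channels(s)
        for i, w0 in enumerate(spec.start_offsets):
            for r in range(plan.n_permutations):
                perm = rng.permutation(chans.size * window)
                Xp = X.copy()
                block = X[np.ix_(np.arange(len(X)), chans,
                                 np.arange(w0, w0 + window))]
                flat = block.reshape(len(X), -1)[:, perm]
                Xp[np.ix_(np.arange(len(X)), chans,
                          np.arange(w0, w0 + window))] = flat.reshape(
                    block.shape)
                losses[s, i, r] = baseline - _acc(model, Xp, y)
    return PFIMap(
        axes={"site": np.arange(layout.n_sites),
              "time": spec.centers(epochs.sfreq, epochs.t0)},
        losses=losses, baseline=baseline, plan=plan)


# ----------------------------------------------------------------- spectral
def default_bands(freqs: np.ndarray) -> list:
    """One band per DFT bin."""
    return [(f, f) for f in freqs]


def _band_bins(freqs, band):
    lo, hi = band
    if lo < 0 or hi > freqs[-1] + 1e-9:
        raise ValueError(f"band {band} outside [0, Nyquist]")
    return np.flatnonzero((freqs >= lo - 1e-9) & (freqs <= hi + 1e-9))


def spectral_pfi(model, epochs: Epochs, idx=None, bands=None,
                 plan: PermutationPlan | None = None,
                 channels: np.ndarray | None = None) -> PFIMap:
    """Accuracy loss per frequency band, disrupted in the Fourier domain.

    Each trial's channels are DFT'd over the whole epoch (no padding;
    with 100 Hz sampling and a 500 ms epoch the resolution is 2 Hz).
    For a given band, one random channel permutation moves all
    coefficient bins of the band between channels; the inverse DFT then
    yields a real disrupted trial.  ``channels`` restricts the
    permutation to a channel subset (used by spatio-spectral PFI).
    """
    plan = plan or PermutationPlan(scope="spectral")
    X, y, baseline = _setup(model, epochs, idx)
    n_t = X.shape[2]
    freqs = np.fft.rfftfreq(n_t, 1.0 / epochs.sfreq)
    bands = default_bands(freqs) if bands is None else list(bands)
    chans = np.arange(X.shape[1]) if channels is None else np.asarray(channels)
    F = np.fft.rfft(X, axis=-1)
    rng = np.random.default_rng(plan.seed)
    losses = np.empty((len(bands), plan.n_permutations))
    for b, band in enumerate(bands):
        sel = _band_bins(freqs, band)
        for r in range(plan.n_permutations):
            perm = chans[rng.permutation(chans.size)]
            Fp = F.copy()
            Fp[np.ix_(np.arange(len(X)), chans, sel)] = F[
                np.ix_(np.arange(len(X)), perm, sel)]
            Xp = np.fft.irfft(Fp, n=n_t, axis=-1)
            losses[b, r] = baseline - _acc(model, Xp, y)
    centers = np.array([(lo + hi) / 2 for lo, hi in bands])
    return PFIMap(axes={"freq": centers}, losses=losses,
                  baseline=baseline, plan=plan)


def spatiospectral_pfi(model, epochs: Epochs, idx=None,
                       layout: SensorLayout | None = None, bands=None,
                       plan: PermutationPlan | None = None) -> PFIMap:
    """Spectral PFI restricted to each site's 12-channel neighbourhood.

    One (site, band) block at a time: the band's Fourier coefficients
    are permuted among the neighbourhood's channels only.
    """
    plan = plan or PermutationPlan(scope="spatiospectral")
    layout = layout or epochs.layout
    if layout is None:
        raise ValueError("no sensor layout available")
    maps = []
    for s in range(layout.n_sites):
        sub = PermutationPlan(plan.n_permutations, seed=plan.seed + s,
                              scope=plan.scope)
        maps.append(spectral_pfi(model, epochs, idx, bands=bands, plan=sub,
                                 channels=layout.neighborhood_channels(s)))
    losses = np.stack([m.losses for m in maps])
    return PFIMap(
        axes={"site": np.arange(layout.n_sites), "freq": maps[0].axes["freq"]},
        losses=losses, baseline=maps[0].baseline, plan=plan)


# ----------------------------------------------------------- temporospectral
@dataclass
class STFTConfig:
    """Short-time Fourier transform settings for temporo-spectral PFI.

    A Hamming window of 100 ms slid by 1 sample ("maximal overlap").
    With 10-sample windows at 100 Hz the band centres are
    0, 10, ..., 50 Hz; the 0 Hz band contains solely the window means.

    The signal is zero-padded by ``length - 1`` samples on both sides
    before framing, so every true sample is covered by the full
    complement of ``length`` overlapping frames: the weighted
    overlap-add inverse is exact (to floating point) and a coefficient
    disruption is attenuated uniformly across the epoch, with no
    edge-sample amplification by near-zero window tails.
    """

    length: int = 10            # window length in samples (100 ms @ 100 Hz)
    window: str = "hamming"

    def win(self) -> np.ndarray:
        return scipy.signal.get_window(self.window, self.length)

    def freqs(self, sfreq: float) -> np.ndarray:
        return np.fft.rfftfreq(self.length, 1.0 / sfreq)

    def n_frames(self, n_times: int) -> int:
        return n_times + self.length - 1

    def frame_of_start(self, start: int) -> int:
        """Frame whose support is the epoch samples [start, start+length)."""
        return start + self.length - 1


def stft(X: np.ndarray, cfg: STFTConfig) -> np.ndarray:
    """Frame-indexed STFT along the last axis (hop 1, zero-padded edges).

    Frame ``f`` covers epoch samples ``[f - length + 1, f + 1)``; frame
    ``cfg.frame_of_start(s)`` is the window on samples ``[s, s+length)``.
    Returns coefficients with shape ``(..., n_frames, length//2 + 1)``.
    """
    win = cfg.win()
    L = cfg.length
    pad = [(0, 0)] * (X.ndim - 1) + [(L - 1, L - 1)]
    Xp = np.pad(X, pad)
    frames = np.lib.stride_tricks.sliding_window_view(Xp, L, axis=-1)
    return np.fft.rfft(frames * win, axis=-1)


def _ola_denominator(cfg: STFTConfig, n_times: int) -> np.ndarray:
    """Accumulated squared window per padded sample."""
    win2 = cfg.win() ** 2
    L = cfg.length
    denom = np.zeros(n_times + 2 * (L - 1))
    for f in range(cfg.n_frames(n_times)):
        denom[f:f + L] += win2
    return denom


def istft(S: np.ndarray, cfg: STFTConfig, n_times: int) -> np.ndarray:
    """Weighted overlap-add inverse of :func:`stft` (exact)."""
    win = cfg.win()
    L = cfg.length
    if S.shape[-2] != cfg.n_frames(n_times):
        raise ValueError("frame count inconsistent with n_times")
    frames = np.fft.irfft(S, n=L, axis=-1)
    n_pad = n_times + 2 * (L - 1)
    out = np.zeros(S.shape[:-2] + (n_pad,))
    for f in range(S.shape[-2]):
        out[..., f:f + L] += frames[..., f, :] * win
    out /= _ola_denominator(cfg, n_times)
    return out[..., L - 1:L - 1 + n_times]


def temporospectral_pfi(model, epochs: Epochs, idx=None,
                        stft_cfg: STFTConfig | None = None, bands=None,
                        plan: PermutationPlan | None = None,
                        smooth: bool = True) -> PFIMap:
    """Accuracy loss per (time window x frequency band) STFT block.

    For each block, one random channel permutation is applied to the
    band's STFT coefficients in the target window and (with
    ``smooth=True``) the windows immediately before and after (clamped
    at the epoch edges, for a smoother temporal profile); the full
    epoch is then inverse-transformed and evaluated.
    """
    plan = plan or PermutationPlan(scope="temporospectral")
    cfg = stft_cfg or STFTConfig()
    X, y, baseline = _setup(model, epochs, idx)
    n, n_ch, n_t = X.shape
    L = cfg.length
    freqs = cfg.freqs(epochs.sfreq)
    bands = default_bands(freqs) if bands is None else list(bands)
    spec = sliding_windows(n_t, L, 1)
    S = stft(X, cfg)
    n_frames = S.shape[-2]
    x0 = istft(S, cfg, n_t)  # baseline reconstruction (== X to fp error)
    win = cfg.win()
    denom = _ola_denominator(cfg, n_t)

    rng = np.random.default_rng(plan.seed)
    losses = np.empty((spec.n_windows, len(bands), plan.n_permutations))
    for i, w0 in enumerate(spec.start_offsets):
        f0 = cfg.frame_of_start(int(w0))
        lo = max(0, f0 - 1) if smooth else f0
        hi = min(n_frames - 1, f0 + 1) if smooth else f0
        frame_ids = np.arange(lo, hi + 1)
        for b, band in enumerate(bands):
            sel = _band_bins(freqs, band)
            for r in range(plan.n_permutations):
                perm = rng.permutation(n_ch)
                # istft is linear: add the overlap-added delta of the
                # few modified frames instead of re-inverting everything
                sub = S[np.ix_(np.arange(n), np.arange(n_ch), frame_ids)]
                dsub = sub[:, perm][..., sel] - sub[..., sel]
                dS = np.zeros_like(sub)
                dS[..., sel] = dsub
                dframes = np.fft.irfft(dS, n=L, axis=-1)
                dpad = np.zeros(X.shape[:-1] + (n_t + 2 * (L - 1),))
                for j, f in enumerate(frame_ids):
                    dpad[..., f:f + L] += dframes[..., j, :] * win
                dpad /= denom
                Xp = x0 + dpad[..., L - 1:L - 1 + n_t]
                losses[i, b, r] = baseline - _acc(model, Xp, y)
    centers = np.array([(b[0] + b[1]) / 2 for b in bands])
    return PFIMap(
        axes={"time": spec.centers(epochs.sfreq, epochs.t0), "freq": centers},
        losses=losses, baseline=baseline, plan=plan)
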