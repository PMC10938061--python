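"""MEG-like synthetic epoched data with planted discriminative structure.

Every trial is the sum of

* a spatially mixed 1/f ("pink") background, band limited like lowpass
  filtered MEG (default 0.1-25 Hz at 100 Hz sampling),
* white sensor noise,
* the trial's class-specific planted patterns: Hann-windowed sinusoidal
  bursts localised in time (centre/duration), space (a set of sensor
  sites) and frequency (the carrier), with per-class amplitude loadings,
* optionally, high-variance *non-discriminative* spatial components
  confined to directions orthogonal to the planted signal subspace.

The planted coordinates form the ground truth that decoding and
permutation-feature-importance analyses are expected to recover.  The
adversarial components reproduce the regime in which variance-ranked PCA
truncation discards the discriminative subspace while a supervised
(classification-trained) projection retains it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .epochs import Epochs
from .layout import SensorLayout, make_sensor_layout


@dataclass
class PlantedPattern:
    """A class-discriminative Gabor-like burst.

    Parameters
    ----------
    center_time : float
        Burst centre in seconds from epoch start.
    duration : float
        Full support of the Hann envelope, seconds.
    carrier_freq : float
        Sinusoidal carrier frequency, Hz (must be below Nyquist).
    site_indices : tuple of int
        Sensor sites carrying the burst.
    class_loadings : (n_classes, len(site_indices)) array
        Amplitude of the burst on each site, per class.  At least two
        rows must differ, otherwise the pattern is non-discriminative.
    class_latencies : optional (n_classes,) array, seconds
        Per-class shift of the burst centre, emulating stimulus-specific
        response timing (default: no shift).
    """

    center_time: float
    duration: float
    carrier_freq: float
    site_indices: tuple
    class_loadings: np.ndarray
    class_latencies: np.ndarray | None = None

    def latency(self, c: int) -> float:
        return 0.0 if self.class_latencies is None else float(
            self.class_latencies[c])

    def time_window(self):
        """(start, stop) of the burst support in seconds, over classes."""
        lats = (np.asarray(self.class_latencies)
                if self.class_latencies is not None else np.zeros(1))
        return (self.center_time + lats.min() - self.duration / 2,
                self.center_time + lats.max() + self.duration / 2)

    def freq_band(self):
        """Approximate spectral support: carrier +/- 1/duration Hz."""
        bw = 1.0 / self.duration
        return (max(0.0, self.carrier_freq - bw), self.carrier_freq + bw)


@dataclass
class SimConfig:
    """Full description of one synthetic dataset.

    ``snr`` is the amplitude ratio between the peak of a unit-loading
    burst and the per-channel background RMS (which is ~1 by
    construction).  ``adversarial_variance`` is the per-direction
    variance of ``n_adversarial`` non-discriminative spatial components.

    Evoked responses vary from presentation to presentation, which is
    the main reason single-trial decoding of real data is hard:
    ``trial_amp_jitter`` (sd of a multiplicative amplitude factor,
    clipped at zero), ``trial_latency_jitter`` (sd in seconds of a
    per-trial shift of the burst centre) and ``trial_loading_jitter``
    (sd of additive per-trial noise on the class loading vector, scaled
    by each site's gain) emulate that variability and set a genuine
    Bayes limit on single-trial accuracy.
    """

    n_classes: int = 8
    n_trials_per_class: int = 20
    n_sites: int = 10
    sfreq: float = 100.0
    epoch_len: float = 0.9
    noise_exponent: float = 1.0
    snr: float = 5.0
    planted_patterns: list = field(default_factory=list)
    adversarial_variance: float = 0.0
    n_adversarial: int = 12
    band: tuple = (0.1, 25.0)
    white_noise: float = 0.1
    trial_amp_jitter: float = 0.2
    trial_latency_jitter: float = 0.008
    trial_loading_jitter: float = 0.12
    seed: int = 0

    @property
    def n_times(self) -> int:
        n = self.epoch_len * self.sfreq
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_len * sfreq must be an integer")
        return int(round(n))

    @property
    def n_channels(self) -> int:
        return 3 * self.n_sites

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.sfreq <= 0 or self.snr < 0:
            raise ValueError("sfreq must be > 0 and snr >= 0")
        if self.n_times < 10:
            raise ValueError("epoch must contain at least 10 samples")
        for p in self.planted_patterns:
            lo, hi = p.time_window()
            if lo < -1e-9 or hi > self.epoch_len + 1e-9:
                raise ValueError(f"pattern at {p.center_time}s outside epoch")
            if p.carrier_freq >= self.sfreq / 2:
                raise ValueError("carrier frequency at or above Nyquist")
            L = np.asarray(p.class_loadings, dtype=float)
            if L.shape != (self.n_classes, len(p.site_indices)):
                raise ValueError("class_loadings must be n_classes x n_sites")
            if np.allclose(L, L[0]) and p.class_latencies is None:
                raise ValueError("pattern is non-discriminative "
                                 "(all class loadings equal)")
            if (p.class_latencies is not None
                    and np.shape(p.class_latencies) != (self.n_classes,)):
                raise ValueError("class_latencies must have one entry "
                                 "per class")


@dataclass
class GroundTruth:
    """Planted coordinates of the discriminative structure."""

    time_windows: list          # (start, stop) seconds per pattern
    site_sets: list             # tuple of sites per pattern
    freq_bands: list            # (lo, hi) Hz per pattern
    signal_subspace: np.ndarray  # (n_channels, k) orthonormal basis


def _pink_sources(rng, n_series, n_times, sfreq, exponent, band):
    """Band-limited 1/f series, unit variance, shape (n_series, n_times)."""
    freqs = np.fft.rfftfreq(n_times, 1.0 / sfreq)
    amp = np.zeros_like(freqs)
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi) & (freqs > 0)
    amp[sel] = freqs[sel] ** (-exponent / 2.0)
    coef = amp * (rng.standard_normal((n_series, freqs.size))
                  + 1j * rng.standard_normal((n_series, freqs.size))) / np.sqrt(2)
    if n_times % 2 == 0:
        # the Nyquist bin must be real (irfft discards its imaginary
        # part); fold both gaussian components in to keep full power
        coef[:, -1] = coef[:, -1].real + coef[:, -1].imag
    x = np.fft.irfft(coef, n=n_times, axis=-1)
    # analytic variance of the irfft given the coefficient magnitudes
    var = (2 * np.sum(amp[1:-1] ** 2) + amp[0] ** 2
           + (amp[-1] ** 2 if n_times % 2 == 0 else 2 * amp[-1] ** 2)) / n_times**2
    if var > 0:
        x /= np.sqrt(var)
    return x


def _burst_waveform(pattern: PlantedPattern, n_times: int, sfreq: float,
                    shift: float = 0.0):
    """Hann-windowed sinusoid, peak envelope 1, zero outside support."""
    t = np.arange(n_times) / sfreq
    center = pattern.center_time + shift
    w = np.zeros(n_times)
    inside = np.abs(t - center) <= pattern.duration / 2 + 1e-12
    tau = (t[inside] - center) / pattern.duration  # in [-1/2, 1/2]
    env = np.cos(np.pi * tau) ** 2  # Hann, peak 1 at centre
    w[inside] = env * np.sin(2 * np.pi * pattern.carrier_freq
                             * (t[inside] - center))
    return w


def _signal_subspace(cfg: SimConfig) -> np.ndarray:
    """Orthonormal basis of channel space spanned by planted loadings."""
    cols = []
    for p in cfg.planted_patterns:
        L = np.asarray(p.class_loadings, dtype=float)
        chans = np.concatenate(
            [3 * np.asarray(p.site_indices) + k for k in range(3)])
        for row in L:
            v = np.zeros(cfg.n_channels)
            v[chans] = np.concatenate([row, row, row])
            cols.append(v)
    if not cols:
        return np.zeros((cfg.n_channels, 0))
    q, r = np.linalg.qr(np.column_stack(cols))
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep]


def generate_epochs(config: SimConfig) -> tuple[Epochs, GroundTruth]:
    """Simulate one epoched dataset with known planted structure.

    Returns balanced-label :class:`~megdecode.epochs.Epochs` of shape
    ``[n_classes * n_trials_per_class, 3 * n_sites, n_times]`` together
    with the :class:`GroundTruth`.  Bit-identical output for identical
    configs (including ``seed``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_trials = config.n_classes * config.n_trials_per_class
    n_ch, n_t = config.n_channels, config.n_times

    layout = make_sensor_layout(config.n_sites, seed=config.seed)
    labels = np.repeat(np.arange(config.n_classes), config.n_trials_per_class)

    # spatially mixed 1/f background: random orthonormal mixing of sources
    # with lognormal variances gives a non-trivial channel covariance
    mix, _ = np.linalg.qr(rng.standard_normal((n_ch, n_ch)))
    src_var = rng.lognormal(mean=0.0, sigma=0.5, size=n_ch)
    src_var *= n_ch / src_var.sum()
    sources = _pink_sources(rng, n_trials * n_ch, n_t, config.sfreq,
                            config.noise_exponent, config.band)
    sources = sources.reshape(n_trials, n_ch, n_t)
    data = np.einsum("cs,nst->nct", mix * np.sqrt(src_var), sources)
    data += config.white_noise * rng.standard_normal(data.shape)

    # planted class-discriminative bursts with trial-to-trial variability;
    # amplitude, latency and representation jitter are drawn once per
    # trial and shared by all patterns: a weak, late, or atypical
    # response is so everywhere, as under global attention/arousal
    # fluctuations and per-trial representational variability
    amp_j = np.clip(1.0 + config.trial_amp_jitter
                    * rng.standard_normal(n_trials), 0.0, None)
    lat_j = config.trial_latency_jitter * rng.standard_normal(n_trials)
    delta = config.trial_loading_jitter * rng.standard_normal((n_trials, 2))
    for p in config.planted_patterns:
        L = np.asarray(p.class_loadings, dtype=float)
        gains = np.abs(L).max(axis=0)  # per-site scale of the pattern
        parity = np.arange(len(p.site_indices)) % 2
        load_j = gains[None, :] * delta[:, parity]
        lo = p.duration / 2 - p.center_time
        hi = config.epoch_len - p.duration / 2 - p.center_time
        chans = {s: layout.site_channels(s) for s in p.site_indices}
        for n in range(n_trials):
            c = labels[n]
            shift = float(np.clip(p.latency(c) + lat_j[n], lo, hi))
            wave = _burst_waveform(p, n_t, config.sfreq, shift=shift)
            loading = L[c] + load_j[n]
            for j, site in enumerate(p.site_indices):
                amp = config.snr * amp_j[n] * loading[j]
                data[n, chans[site], :] += amp * wave[None, :]

    # high-variance non-discriminative components orthogonal to the signal
    basis = _signal_subspace(config)
    if config.adversarial_variance > 0 and config.n_adversarial > 0:
        proj = np.eye(n_ch) - basis @ basis.T
        raw = proj @ rng.standard_normal((n_ch, config.n_adversarial))
        q, _ = np.linalg.qr(raw)
        q = q[:, : config.n_adversarial]
        adv = _pink_sources(rng, n_trials * q.shape[1], n_t, config.sfreq,
                            config.noise_exponent, config.band)
        adv = adv.reshape(n_trials, q.shape[1], n_t)
        data += np.sqrt(config.adversarial_variance) * np.einsum(
            "ck,nkt->nct", q, adv)

    epochs = Epochs(data=data, labels=labels, sfreq=config.sfreq,
                    t0=0.0, layout=layout)
    truth = GroundTruth(
        time_windows=[p.time_window() for p in config.planted_patterns],
        site_sets=[tuple(p.site_indices) for p in config.planted_patterns],
        freq_bands=[p.freq_band() for p in config.planted_patterns],
        signal_subspace=basis,
    )
    return epochs, truth


def psd_check(epochs: Epochs):
    """Mean power spectral density across trials and channels.

    Returns ``(freqs, power)`` from a per-trial/channel periodogram;
    used to verify the 1/f shape of the generator's background.
    """
    if epochs.n_trials == 0:
        raise ValueError("empty epochs")
    freqs, pxx = scipy.signal.periodogram(
        epochs.data, fs=epochs.sfreq, axis=-1)
    return freqs, pxx.mean(axis=(0, 1))


# ----------------------------------------------------------------- presets
def _circle_loadings(n_classes, gains, group=None):
    """Distinct per-class loadings: unit circle spread over site gains.

    ``group`` maps each class to an angle index (defaults to identity),
    letting two patterns carry complementary label information.
    """
    gains = np.asarray(gains, dtype=float)
    g = np.arange(n_classes) if group is None else np.asarray(group)
    n_angles = g.max() + 1
    theta = 2 * np.pi * g / n_angles
    phases = np.where(np.arange(gains.size) % 2 == 0,
                      np.cos(theta)[:, None], np.sin(theta)[:, None])
    return gains[None, :] * phases


def benchmark_config(seed: int = 0, snr: float = 16.0, **kw) -> SimConfig:
    """Default recovery benchmark: one strong early burst plus a weak
    sustained follower, emulating the morphology of a visual evoked
    response (sharp transient then a graded, spatially spread tail).

    The strong burst (10 Hz, 100-200 ms, sites 2 and 3) is the target
    every PFI variant should localise; the weak follower (the same
    same 10 Hz carrier ringing on over 200-600 ms, graded gains over
    neighbouring sites) creates genuine spatial/temporal gradients in
    the importance maps without introducing a second spectral target.
    """
    kw.setdefault("n_trials_per_class", 30)
    cfg = SimConfig(seed=seed, snr=snr, **kw)
    n = cfg.n_classes
    early = PlantedPattern(
        center_time=0.15, duration=0.1, carrier_freq=10.0,
        site_indices=(2, 3),
        class_loadings=_circle_loadings(n, (1.0, 0.8)),
    )
    sustained = PlantedPattern(
        center_time=0.4, duration=0.4, carrier_freq=10.0,
        site_indices=(2, 3, 4, 5, 6, 7),
        class_loadings=_circle_loadings(
            n, (0.06, 0.06, 0.1, 0.075, 0.05, 0.03)),
    )
    cfg.planted_patterns = [early, sustained]
    return cfg


def null_config(seed: int = 0, **kw) -> SimConfig:
    """Chance-floor benchmark: the default patterns at snr = 0, with
    the smaller 20-trials-per-class sample."""
    kw.setdefault("n_trials_per_class", 20)
    return benchmark_config(seed=seed, snr=0.0, **kw)


def adversarial_config(seed: int = 0, snr: float = 5.0,
                       adversarial_variance: float = 25.0) -> SimConfig:
    """Low-variance-signal benchmark for supervised vs PCA reduction.

    The discriminative burst lives on 2 sites while 12 orthogonal spatial
    directions carry variance 25 of non-discriminative 1/f activity, so a
    variance-ranked projection to ~10 components discards the signal.
    """
    cfg = SimConfig(seed=seed, snr=snr,
                    adversarial_variance=adversarial_variance,
                    n_adversarial=12)
    cfg.planted_patterns = [PlantedPattern(
        center_time=0.15, duration=0.1, carrier_freq=10.0,
        site_indices=(2, 3),
        class_loadings=_circle_loadings(cfg.n_classes, (1.0, 0.8)),
    )]
    return cfg


def two_burst_config(seed: int = 0, snr: float = 5.0) -> SimConfig:
    """Two temporally disjoint bursts carrying complementary label bits.

    The early burst distinguishes class mod 4, the late burst class
    div 4: no single 100 ms window suffices for full discrimination, so a
    full-epoch decoder should beat the best sliding-window decoder.
    """
    cfg = SimConfig(seed=seed, snr=snr)
    n = cfg.n_classes
    g_early, g_late = np.arange(n) % 4, np.arange(n) // 4
    early = PlantedPattern(
        center_time=0.15, duration=0.1, carrier_freq=10.0,
        site_indices=(2, 3),
        class_loadings=_circle_loadings(n, (1.0, 0.8), group=g_early),
    )
    late = PlantedPattern(
        center_time=0.45, duration=0.1, carrier_freq=8.0,
        site_indices=(6, 7),
        class_loadings=_circle_loadings(n, (1.0, 0.8), group=g_late),
    )
    cfg.planted_patterns = [early, late]
    return cfg
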