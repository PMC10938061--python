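# Methods

## The decoding problem

The package addresses many-class decoding of epoched, stimulus-locked
electrophysiology: given trials `X ∈ R^{channels × times}` with class
labels (one label per presented stimulus), learn a classifier and then
explain *which* times, sensors and frequencies carry the
discriminative signal. Two families are implemented:

- **Sliding-window decoding**: one multiclass shrinkage LDA per 100 ms
  window (step 1 sample), giving an accuracy time course; and one LDA
  per co-located sensor triplet trained on that site's full epoch,
  giving an accuracy sensor map. These are classical MVPA readouts.
- **Full-epoch decoding**: a single model sees the whole epoch.
  Feature importance is then obtained post hoc by permutation
  (PFI, below) at any temporal/spatial/spectral granularity, without
  retraining.

## Decoders

**Linear network with supervised dimensionality reduction.** The first
layer multiplies the `[times × channels]` epoch by a learnable
`[channels × components]` matrix shared across timepoints — the
supervised counterpart of channel-wise PCA. The projected matrix is
flattened and passed through three affine layers (hidden sizes 1000
and 300 by default, sized for a ~4000-dimensional input and ~100
classes; narrower layers are used on the 30-channel synthetic
benchmark) ending in class logits. No nonlinearity is used anywhere,
so the trained model is exactly equivalent to one affine map
(`collapse()` returns it, and the equivalence is asserted to 1e-5
relative tolerance in the tests). Training still benefits from the
deep parametrisation and from inverted dropout (drop probability 0.7)
in front of each of the three affine layers. Optimisation: softmax
cross-entropy, Adam (learning rate 1e-3, batch 64, full batch when the
training set is smaller), a fixed number of full passes (default
2000), no early stopping; validation data is used for reporting only.
The implementation is NumPy throughout; gradients are hand-derived
(they are compositions of linear maps and dropout masks).

**Projected shrinkage LDA.** Multiclass LDA with the shared covariance
shrunk toward scaled identity; the "auto" intensity is the
Ledoit–Wolf analytic estimate (scikit-learn's `lsqr` solver), any
fraction in [0, 1] is accepted, and at intensity 1 the rule reduces to
nearest class mean. Features are the row-major flattening of the
`[times × components]` projected epoch. `LDAPCADecoder` takes the top
variance-ranked principal directions of the pooled training
timepoint-by-channel matrix; `LDANNDecoder` takes the trained
network's bottleneck matrix. Argmax ties break toward the lowest
class index.

**Whitening.** PCA whitening over channels (all components retained,
channel means removed, eigendecomposition of the pooled
training-timepoint covariance; a ridge of `1e-12·trace/n` is added
with a warning if the covariance is rank deficient). The whitener is
fitted on training trials only and is carried *inside* each decoder
(`whiten=True`), so a decoder's `predict` consumes raw sensor-space
data. This matters for PFI: sensor- and triplet-level permutations
are only meaningful before channels are mixed by the whitening
rotation. The adversarial method-ordering study (below) runs with
`whiten=False`, because whitening equalises per-direction variances
and would neutralise the variance-ranking failure mode that study is
designed to exhibit.

## Permutation feature importance

All six variants share one template: copy the evaluation trials,
disrupt one block, evaluate the fixed trained model, record
`accuracy loss = baseline − disrupted accuracy`, restore, repeat for
`n_permutations` (default 10) independent draws. Losses are kept per
repetition so percentile intervals can be formed. Disruptions are
*within-trial*, across the complementary dimension of the block; one
permutation is drawn per (block, repetition) and applied to every
evaluated trial, making repetitions interpretable as plan-level
samples (a per-trial redraw of the permutation is a defensible
alternative; the shared draw is the default). Blocks whose contents
are invariant under the permutation provably yield exactly zero loss,
which the tests assert.

- **Temporal**: one channel permutation applied to all timepoints of a
  100 ms window (a per-timepoint-independent variant is available).
- **Spatial**: per sensor triplet, an independent shuffle of the
  timepoint order within each of its 3 channels.
- **Spatiotemporal**: joint shuffle of all values in a 12-channel
  (site + 3 nearest sites) × 100 ms block.
- **Spectral**: full-epoch DFT per channel (no padding, so a 500 ms /
  100 Hz epoch gives 2 Hz resolution and the 0.9 s benchmark 1.1 Hz);
  one channel permutation moves all coefficient bins of a band between
  channels; the inverse transform is real by construction. Default
  granularity is one band per bin; arbitrary band edges are accepted.
- **Spatio-spectral**: the spectral permutation restricted to a
  site's 12-channel neighbourhood.
- **Temporo-spectral**: STFT with a 100 ms Hamming window and hop 1
  ("maximal overlap"); with 10-sample windows the band centres are
  0, 10, ..., 50 Hz and the 0 Hz band contains solely the window
  means. For each (window, band), one channel permutation is applied
  to that band's coefficients in the window and its immediate
  neighbours (for a smoother profile; clamped at epoch edges), and the
  full epoch is inverse-transformed.

**STFT details.** The transform frames the signal at every sample
after zero-padding `length−1` samples on each side, so every true
sample is covered by exactly `length` frames; the weighted overlap-add
inverse (division by the accumulated squared window) is then exact to
floating point *and* the attenuation of a coefficient disruption is
uniform across the epoch. Without the padding, samples near the epoch
edges are covered by few frames and the division by near-zero Hamming
tails amplifies disruptions ~100-fold, producing spurious edge
importance — this motivated the boundary handling. The inner loop
exploits linearity of the inverse: only the overlap-added delta of the
few modified frames is recomputed. scipy's `ShortTimeFFT` serves as an
independent cross-check of the frame coefficients in the tests, not as
the implementation, because the disruption needs frame-indexed
coefficient control aligned with the package's window convention.

**Interpretation caveat.** PFI measures the model's *reliance* on a
block, which lower-bounds but does not equal the block's information
content: evidence that is redundant with other blocks can receive
little loss, and when the model classifies at ceiling, small
disruptions (especially the heavily diluted temporo-spectral ones,
whose losses are an order of magnitude smaller than temporal ones)
may flip no validation trial at all.

## Statistics

Paired method comparisons use Wilcoxon signed-rank tests with
zero-differences discarded, the exact null for n ≤ 25 without ties and
the tie-corrected normal approximation otherwise, and Bonferroni
correction `min(1, p·m)` across comparisons (e.g. ×90 across sliding
windows). Chance bands are exact two-sided binomial intervals for the
accuracy of a chance classifier. In simulation studies, replicate
datasets (distinct seeds) play the role subjects play in real studies:
one mean validation accuracy per replicate per method enters the
paired test.

## Synthetic data generator

Each trial is the sum of: (i) a 1/f background — per-source spectra
`∝ f^{-exponent/2}` band-limited to 0.1–25 Hz (emulating lowpass
filtered MEG at 100 Hz), unit variance, mixed into channels by a
random orthonormal matrix with lognormal source variances so the
channel covariance is non-trivial; (ii) white sensor noise (sd 0.1);
(iii) the planted class-discriminative patterns: Hann-windowed
sinusoidal bursts with per-class amplitude loadings on a set of sensor
sites, all three channels of a site receiving the same loading;
(iv) optionally, high-variance 1/f components on directions orthogonal
to the planted signal subspace. `snr` is the peak amplitude of a
unit-loading burst relative to the per-channel background RMS (~1).

Trial-to-trial variability is what makes single-trial decoding of real
data hard, so the generator jitters each presentation: multiplicative
amplitude (sd 0.2, clipped at zero), burst latency (sd 8 ms), and the
loading vector itself: a per-trial 2-D perturbation of the
class's coordinate on the loading circle (sd 0.12), expressed by every
pattern on its sites scaled by the site gains. The
loading jitter imposes a genuine Bayes limit: class loadings sit on a
unit circle in site space, and the per-trial topography scatter makes
neighbouring classes overlap, holding the best achievable accuracy
near (not at) ceiling. This operating point was chosen deliberately:
a decoder at machine-precision margins shows empty temporo-spectral
PFI maps (no disruption flips any trial), which is not the regime the
method is meant for.

**Benchmark presets** (the study conditions; defaults are not
per-test knobs):

- `benchmark_config` — 8 classes × 30 trials, 10 sites (30 channels),
  0.9 s at 100 Hz, snr 16. Pattern 1: 10 Hz burst, 100–200 ms, sites
  {2, 3}, gains (1.0, 0.8) — the recovery target. Pattern 2: the same
  carrier ringing on weakly over 200–600 ms with graded gains over
  sites 2–7 (max 0.1), emulating the sustained tail of a visual evoked
  response; it gives the importance maps genuine spatial and temporal
  gradients so rank-correlation comparisons against per-sensor and
  sliding-window decoding are meaningful, without adding a second
  spectral target.
- `null_config` — the same at snr 0 with 20 trials/class; the
  chance-floor condition.
- `adversarial_config` — a single burst on sites {2, 3} plus 12
  orthogonal spatial directions carrying variance 25 of
  non-discriminative 1/f activity: variance-ranked PCA truncation to
  ~10 components discards the signal, supervised reduction keeps it.
- `two_burst_config` — two temporally disjoint bursts carrying
  complementary label bits (class mod 4 at 100–200 ms, class div 4 at
  400–500 ms): no single 100 ms window suffices, so full-epoch
  decoding must beat the best sliding window.

**What the generator does not emulate**: forward-model (leadfield)
physics and real gradiometer/magnetometer transfer functions (the
channel types are tags only), ocular/cardiac artifacts, across-subject
anatomical variability, and any calibration of the noise parameters to
the public image-decoding datasets. Passing tests therefore show that
the pipeline recovers planted structure under realistic statistics,
not that effect sizes match any particular real dataset.

## Numerical and design choices

- Window convention: half-open `[start, start+length)`, 0-based;
  window count `floor((n_times − length)/step)` with the final
  flush placement dropped — 100 samples / 10-sample windows / step 1
  give 90 windows; a window is reported at its centre time.
- Validation split: per class, `max(1, floor(ratio·n_c))` trials,
  seeded shuffle, default ratio 0.2 (4:1).
- The sliding-window projection (PCA or network bottleneck) is fitted
  once on full-epoch training data and shared across windows; for
  sliding-window LDA-NN the full-epoch network's bottleneck is used
  rather than per-window networks.
- Per-sensor LDAs run in raw sensor space (no whitening): site-local
  models handle their own 3-channel covariance via shrinkage.
- The test suite and the acceptance script run a narrower, shorter
  configuration of the network (8 components, hidden sizes 200/100,
  1000 passes) sized to the 30-channel benchmark; problem sizes were
  chosen so the full suite completes in minutes on one CPU.
- Adam moments: standard (0.9, 0.999, eps 1e-8); Glorot-uniform
  initialisation; all randomness flows from explicit seeds
  (`numpy.random.default_rng`), and fixed seeds give bit-identical
  datasets, models and PFI maps.

## Known limitations

- Accuracy-loss maps are granular at `1/n_validation`; with few
  validation trials, weak blocks produce losses indistinguishable from
  zero. Temporo-spectral PFI is affected most (overlap-add dilutes a
  3-frame disruption roughly 10-fold), so near ceiling its argmax can
  land on whichever planted component happens to govern the few
  boundary trials at a given seed; the fixed-seed recovery tests pin a
  representative operating point and the across-seed variability is a
  property of the statistic, not of the implementation.
- Ledoit–Wolf shrinkage at ~200 trials × ~700 features leaves LDA-NN a
  few accuracy points behind or ahead of the network depending on the
  realisation; the two agree to within 5 points on the benchmark, as
  they should when the projection carries the class structure.
- PFI underestimates the importance of redundant evidence (see
  caveat above); the per-sensor comparison is therefore a rank
  comparison, not a calibration.
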