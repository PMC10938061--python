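# megdecode

Interpretable many-class, full-epoch decoding of epoched M/EEG data.

Sliding-window MVPA — training one linear classifier per 100 ms window —
is the standard way to learn *when* and *where* stimulus information
lives in MEG/EEG recordings, but it leaves accuracy on the table
because no single window sees all of the signal. `megdecode` takes the
opposite route: train **one** multiclass decoder on the whole
post-stimulus epoch, then recover the temporal, spatial and spectral
structure afterwards with **permutation feature importance (PFI)** —
no retraining, any window size, and the approach works for any
black-box decoder that exposes `predict`.

The package provides, as scikit-learn-style estimators over
`(n_trials, n_channels, n_times)` arrays:

- **`LinearDecodingNetwork`** — a four-layer *linear* network whose
  first layer is a learnable `[channels x components]` projection
  (supervised dimensionality reduction, the counterpart of channel
  PCA but optimised for the classification objective). Trained with
  softmax cross-entropy, Adam, and dropout `p = 0.7` in front of each
  affine layer; because the model is linear it collapses to a single
  affine map for evaluation (`.collapse()`).
- **`LDAPCADecoder` / `LDANNDecoder`** — multiclass shrinkage LDA
  (Ledoit–Wolf "auto" intensity) on the flattened
  `[timepoints x components]` matrix, with the projection taken from
  variance-ranked PCA or from the trained network's bottleneck.
- **`SlidingWindowLDA` / `per_sensor_lda`** — the classical
  comparators: independent LDAs per time window and per co-located
  sensor triplet (2 gradiometers + 1 magnetometer).
- **Six PFI variants** — `temporal_pfi`, `spatial_pfi`,
  `spatiotemporal_pfi`, `spectral_pfi`, `spatiospectral_pfi`,
  `temporospectral_pfi`. Each disrupts one block of the input per
  evaluation (a time window by shuffling channels, a sensor site by
  shuffling time, a frequency band by permuting Fourier coefficients
  across channels, ...) and records the accuracy loss relative to the
  intact data. The temporo-spectral variant uses a 100 ms Hamming-window
  STFT with maximal overlap and an exact weighted overlap-add inverse.
- **`generate_epochs`** — a synthetic MEG generator (1/f spatially
  mixed background, white sensor noise, Gabor-like class-discriminative
  bursts with trial-to-trial amplitude/latency/topography jitter, and
  optional high-variance non-discriminative components) whose planted
  ground truth makes every recovery claim testable.
- **`wilcoxon_signed_rank` / `bonferroni` / `chance_band`** — paired
  statistics across replicates and exact binomial chance intervals.

## Worked example

```python
import megdecode as md

cfg = md.benchmark_config(seed=7)            # 8 classes, 30 trials/class,
epochs, truth = md.generate_epochs(cfg)      # 30 channels, 0.9 s @ 100 Hz
split = md.stratified_split(epochs.labels, ratio=0.2, seed=8)

net = md.LinearDecodingNetwork(n_components=8, hidden_sizes=(200, 100),
                               n_epochs=1000, random_state=0)
net.fit(epochs.data[split.train], epochs.labels[split.train])
lda_nn = md.LDANNDecoder(network=net).fit(
    epochs.data[split.train], epochs.labels[split.train])
print("validation accuracy:", md.accuracy(lda_nn, epochs, split.validation))

tmap = md.temporal_pfi(lda_nn, epochs, split.validation,
                       plan=md.PermutationPlan(10, seed=0))
peak = tmap.axes["time"][tmap.mean_loss().argmax()]
print("temporal PFI peak at %.0f ms" % (1000 * peak))
```

prints

```
validation accuracy: 0.8958333333333334
temporal PFI peak at 150 ms
```

The benchmark plants a 10 Hz burst on sensor sites 2 and 3 at
100–200 ms: the decoder classifies well above the 0.125 chance level
and the PFI peak falls inside the planted window. The other PFI
variants localise the burst's sites, its 10 Hz carrier, and the joint
time–frequency coordinates the same way.

A thin CLI mirrors the library:

```bash
megdecode simulate --config sim.yaml --out data.h5 --seed 1
megdecode train    --data data.h5 --model lda-nn --out model.h5
megdecode pfi      --model model.h5 --data data.h5 --mode temporal --out pfi.csv
megdecode experiment --config experiment.yaml
```

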