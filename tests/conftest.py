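"""Shared fixtures: pinned synthetic benchmarks and trained decoders.

Expensive fixtures (trained networks, PFI maps) are session scoped and
shared between the module tests and the acceptance suite.  All seeds
are pinned; the benchmark datasets are the package's study conditions,
not per-test knobs.
"""

import numpy as np
import pytest

import megdecode as md

# test-scale network settings: a narrower configuration of the same
# architecture sized to the 30-channel benchmark; the pinned benchmark
# model trains for the full 2000 passes, replicate-level analyses use
# 1000 to keep the suite within minutes on one CPU
NET_KW = dict(n_components=8, hidden_sizes=(200, 100), n_epochs=1000,
              random_state=0)
BENCH_NET_KW = dict(NET_KW, n_epochs=2000)
BENCH_SEED = 49
REPLICATE_SEEDS = (7, 21, 35, 49, 63)


@pytest.fixture(scope="session")
def benchmark():
    """Pinned recovery benchmark dataset with ground truth and split."""
    cfg = md.benchmark_config(seed=BENCH_SEED)
    epochs, truth = md.generate_epochs(cfg)
    split = md.stratified_split(epochs.labels, 0.2, seed=BENCH_SEED + 1)
    return cfg, epochs, truth, split


@pytest.fixture(scope="session")
def trained_net(benchmark):
    cfg, epochs, truth, split = benchmark
    net = md.LinearDecodingNetwork(**BENCH_NET_KW)
    return net.fit(epochs.data[split.train], epochs.labels[split.train])


@pytest.fixture(scope="session")
def lda_nn(benchmark, trained_net):
    cfg, epochs, truth, split = benchmark
    return md.LDANNDecoder(network=trained_net).fit(
        epochs.data[split.train], epochs.labels[split.train])


@pytest.fixture(scope="session")
def temporal_map(benchmark, lda_nn):
    cfg, epochs, truth, split = benchmark
    return md.temporal_pfi(lda_nn, epochs, split.validation,
                           plan=md.PermutationPlan(10, seed=0))


@pytest.fixture(scope="session")
def spatial_map(benchmark, lda_nn):
    cfg, epochs, truth, split = benchmark
    return md.spatial_pfi(lda_nn, epochs, split.validation,
                          plan=md.PermutationPlan(20, seed=1))


@pytest.fixture(scope="session")
def window_timecourse(benchmark, trained_net):
    cfg, epochs, truth, split = benchmark
    spec = md.sliding_windows(epochs.n_times, 10, 1)
    return md.train_windowed(epochs, split, spec, projection=trained_net)


@pytest.fixture(scope="session")
def sensor_map(benchmark):
    cfg, epochs, truth, split = benchmark
    return md.per_sensor_lda(epochs, split)


@pytest.fixture(scope="session")
def averaged_maps():
    """Replicate-averaged importance and comparator maps.

    The comparison between PFI profiles and classical search-light
    decoding is made on maps averaged over replicate datasets, the way
    such maps are averaged over subjects in real studies: single-
    replicate maps carry binomial evaluation noise at uninformative
    coordinates that has nothing to do with either method.
    """
    tms, sps, tcs, smaps = [], [], [], []
    for seed in REPLICATE_SEEDS:
        cfg = md.benchmark_config(seed=seed)
        epochs, _ = md.generate_epochs(cfg)
        split = md.stratified_split(epochs.labels, 0.2, seed=seed + 1)
        Xtr, ytr = epochs.data[split.train], epochs.labels[split.train]
        net = md.LinearDecodingNetwork(**NET_KW).fit(Xtr, ytr)
        model = md.LDANNDecoder(network=net).fit(Xtr, ytr)
        tms.append(md.temporal_pfi(
            model, epochs, split.validation,
            plan=md.PermutationPlan(10, seed=0)).mean_loss())
        sps.append(md.spatial_pfi(
            model, epochs, split.validation,
            plan=md.PermutationPlan(20, seed=1)).mean_loss())
        spec = md.sliding_windows(epochs.n_times, 10, 1)
        tcs.append(md.train_windowed(epochs, split, spec,
                                     projection=net).accuracy)
        smaps.append(md.per_sensor_lda(epochs, split).accuracy)
    return {
        "temporal_pfi": np.mean(tms, axis=0),
        "spatial_pfi": np.mean(sps, axis=0),
        "window_accuracy": np.mean(tcs, axis=0),
        "sensor_accuracy": np.mean(smaps, axis=0),
    }


@pytest.fixture(scope="session")
def null_benchmark():
    """snr = 0 dataset: no class signal anywhere."""
    cfg = md.null_config(seed=131)
    epochs, _ = md.generate_epochs(cfg)
    split = md.stratified_split(epochs.labels, 0.2, seed=132)
    return cfg, epochs, split


@pytest.fixture(scope="session")
def net_kw():
    """Reference test-scale network settings."""
    return dict(NET_KW)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
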