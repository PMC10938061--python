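"""Config-driven experiment runner: simulate -> train -> evaluate -> report.

A single YAML config declares the dataset preset, the decoders, the
analyses (full-epoch accuracies, sliding-window time courses, PFI
maps) and the paired comparisons.  Each replicate re-simulates the
dataset with a derived seed and stands in for one subject in the
paired signed-rank tests.  A manifest recording every seed, the config
and package versions is written next to the outputs, so a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .base import accuracy
from .epochs import sliding_windows, stratified_split
from .lda import LDANNDecoder, LDAPCADecoder
from .nn import LinearDecodingNetwork
from .pfi import (PermutationPlan, spatial_pfi, spatiospectral_pfi,
                  spatiotemporal_pfi, spectral_pfi, temporal_pfi,
                  temporospectral_pfi)
from .simulate import (SimConfig, PlantedPattern, adversarial_config,
                       benchmark_config, generate_epochs, null_config,
                       two_burst_config)
from .sliding import peak_accuracy, per_sensor_lda, train_windowed
from .stats import wilcoxon_signed_rank

_PRESETS = {
    "benchmark": benchmark_config,
    "null": null_config,
    "adversarial": adversarial_config,
    "two_burst": two_burst_config,
}

_PFI_FUNCS = {
    "temporal": temporal_pfi,
    "spatial": spatial_pfi,
    "spatiotemporal": spatiotemporal_pfi,
    "spectral": spectral_pfi,
    "spatiospectral": spatiospectral_pfi,
    "temporospectral": temporospectral_pfi,
}


def dataset_config(spec: dict, seed: int) -> SimConfig:
    """Build a SimConfig from the ``dataset`` section of an experiment
    config: either a named preset (with keyword overrides) or explicit
    :class:`~megdecode.simulate.SimConfig` fields plus pattern dicts."""
    spec = dict(spec or {})
    preset = spec.pop("preset", "benchmark")
    if preset == "custom":
        patterns = [PlantedPattern(**{**p, "class_loadings":
                                      np.asarray(p["class_loadings"])})
                    for p in spec.pop("planted_patterns", [])]
        return SimConfig(seed=seed, planted_patterns=patterns, **spec)
    if preset not in _PRESETS:
        raise ValueError(f"unknown dataset preset {preset!r}")
    return _PRESETS[preset](seed=seed, **spec)


def _make_decoders(cfgs: dict, seed: int, X, y):
    """Fit the declared decoders on training data; LDA-NN reuses the NN."""
    fitted = {}
    net = None
    nn_kw = dict(cfgs.get("nn", cfgs.get("lda_nn", {})))
    needs_nn = "nn" in cfgs or "lda_nn" in cfgs
    if needs_nn:
        nn_kw.setdefault("random_state", seed)
        net = LinearDecodingNetwork(**nn_kw).fit(X, y)
    if "nn" in cfgs:
        fitted["nn"] = net
    if "lda_nn" in cfgs:
        fitted["lda_nn"] = LDANNDecoder(network=net).fit(X, y)
    if "lda_pca" in cfgs:
        fitted["lda_pca"] = LDAPCADecoder(**cfgs["lda_pca"]).fit(X, y)
    return fitted, net


def run_experiment(config, out_dir=None, seed=None) -> dict:
    """Execute one experiment config and write its report.

    ``config`` is a mapping or a path to a YAML file.  Returns the
    report dict (also serialized as JSON/CSV under ``out_dir``).
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    base_seed = int(config.get("seed", 0) if seed is None else seed)
    n_rep = int(config.get("replicates", 1))
    decoder_cfgs = config.get("decoders", {"lda_nn": {}, "lda_pca": {}})
    analyses = config.get("analyses", ["full_epoch"])
    ratio = float(config.get("split", {}).get("ratio", 0.2))
    window = int(config.get("window", {}).get("length", 10))
    pfi_cfg = config.get("pfi", {})
    plan_n = int(pfi_cfg.get("n_permutations", 10))
    pfi_modes = [m for m in analyses if m in _PFI_FUNCS]

    out_dir = Path(out_dir or config.get("output", "megdecode_results"))
    out_dir.mkdir(parents=True, exist_ok=True)

    rep_seeds = [(base_seed * 10007 + 7919 * i) % (2**31) for i in range(n_rep)]
    acc_rows, tc_rows, pfi_frames = [], [], {m: [] for m in pfi_modes}

    for i, rs in enumerate(rep_seeds):
        sim = dataset_config(config.get("dataset", {}), seed=rs)
        epochs, _ = generate_epochs(sim)
        split = stratified_split(epochs.labels, ratio=ratio, seed=rs + 1)
        Xtr, ytr = epochs.data[split.train], epochs.labels[split.train]
        fitted, net = _make_decoders(decoder_cfgs, rs + 2, Xtr, ytr)

        for name, model in fitted.items():
            for part, idx in (("train", split.train),
                              ("validation", split.validation)):
                acc_rows.append(dict(replicate=i, method=name, split=part,
                                     accuracy=accuracy(model, epochs, idx)))

        if "sliding_window" in analyses:
            spec = sliding_windows(epochs.n_times, window, 1)
            proj = net if net is not None else "pca"
            tc = train_windowed(epochs, split, spec, projection=proj)
            for c, a in zip(tc.centers, tc.accuracy):
                tc_rows.append(dict(replicate=i, window_center_s=c,
                                    accuracy=a))

        if "per_sensor" in analyses:
            smap = per_sensor_lda(epochs, split)
            pd.DataFrame(dict(site=np.arange(len(smap.accuracy)),
                              accuracy=smap.accuracy)).to_csv(
                out_dir / f"per_sensor_rep{i}.csv", index=False)

        ref = fitted.get("lda_nn") or next(iter(fitted.values()))
        for mode in pfi_modes:
            plan = PermutationPlan(plan_n, seed=rs + 3, scope=mode)
            pmap = _PFI_FUNCS[mode](ref, epochs, split.validation, plan=plan)
            frame = pmap.to_frame()
            frame.insert(0, "replicate", i)
            pfi_frames[mode].append(frame)

    acc_df = pd.DataFrame(acc_rows)
    acc_df.to_csv(out_dir / "accuracies.csv", index=False)
    if tc_rows:
        pd.DataFrame(tc_rows).to_csv(out_dir / "timecourse.csv", index=False)
    for mode, frames in pfi_frames.items():
        pd.concat(frames).to_csv(out_dir / f"pfi_{mode}.csv", index=False)

    report = {"chance": 1.0 / dataset_config(
        config.get("dataset", {}), seed=rep_seeds[0]).n_classes}
    val = acc_df[acc_df["split"] == "validation"]
    report["mean_validation_accuracy"] = {
        m: float(g["accuracy"].mean()) for m, g in val.groupby("method")}
    if tc_rows:
        tc_df = pd.DataFrame(tc_rows)
        mean_tc = tc_df.groupby("window_center_s")["accuracy"].mean()
        report["peak_window"] = {
            "center_s": float(mean_tc.idxmax()),
            "accuracy": float(mean_tc.max())}

    comparisons = config.get("comparisons", [])
    stats = {}
    for pair in comparisons:
        a, b = pair
        va = val[val["method"] == a].sort_values("replicate")["accuracy"].values
        vb = val[val["method"] == b].sort_values("replicate")["accuracy"].values
        if len(va) >= 5:
            res = wilcoxon_signed_rank(va, vb)
            stats[f"{a}_vs_{b}"] = dict(
                statistic=res.statistic, p=res.p,
                mean_difference=float(np.mean(va - vb)))
    report["tests"] = stats

    manifest = dict(config=_jsonable(config), base_seed=base_seed,
                    replicate_seeds=rep_seeds,
                    versions=dict(megdecode=__version__,
                                  python=sys.version.split()[0],
                                  numpy=np.__version__))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
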