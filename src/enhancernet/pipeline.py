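"""End-to-end workflow stages with on-disk artifacts and a run manifest.

Each stage reads the artifacts of the previous one from the run directory,
so stages can be executed independently (see the command-line interface) or
all at once via :func:`run_full`.  A run directory ends up containing::

    data/                sites_<CLASS>.bed, reads_<mark>_rep<i>.bed
    tracks.npz           RPKM bin tracks per mark/chromosome
    training.npz         features + labels + provenance + scaler
    model.npz            trained network (+ the TrainConfig used)
    loss.tsv             per-epoch training MSE
    ordered_features.tsv connection-weight feature ranking
    mark_importance.tsv  per-mark importance (sum of its window features)
    sweep.tsv            top-k retraining table
    scores.npz           genome-wide bin scores
    predictions.bed      thresholded predictions
    validation.json      validation-rate report
    manifest.json        config + seed + package version

Every stage derives its randomness from the config seed, so re-running a
manifest reproduces the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmark import benchmark_spec, desk_train_config
from .datasets import (
    LabeledDataset,
    build_training_set,
    select_negative_training,
    select_positive_training,
)
from .evaluation import (
    build_tpm_set,
    make_prediction_set,
    threshold_sweep,
    validate_predictions,
)
from .importance import (
    aggregate_by_mark,
    export_feature_table,
    importance_scores,
    rank_features,
    top_k_sweep,
)
from .intervals import ElementClass, ReadSet, SummitIndex, read_bed
from .network import TrainConfig, load_model, predict, save_model, train_best
from .simulate import export, generate, load_sites
from .tracks import (
    BinnedTrack,
    FeatureMatrix,
    FeatureSpec,
    assemble_features,
    average_replicates,
    bin_reads,
    rpkm_normalize,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Plain-text configuration for a full run.

    With ``synthetic=True`` (the default) the run simulates its inputs from
    the benchmark conditions; otherwise ``site_beds`` (class -> BED path) and
    ``read_beds`` (mark -> list of replicate BED paths) must point at
    existing files.
    """

    outdir: str = "enhancernet_run"
    seed: int = 0
    synthetic: bool = True
    n_enhancers: int = 300
    n_tss: int = 250
    n_unknown: int = 600
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    site_beds: dict[str, str] = field(default_factory=dict)
    read_beds: dict[str, list[str]] = field(default_factory=dict)
    marks: list[str] = field(default_factory=list)
    bin_width: int = 100
    flank_bins: int = 10
    min_dist: int = 1000
    radius: int = 2500
    ratio: int = 10
    n_random_bg: int = 3000
    n_predictions: int = 1000
    k_values: list[int] = field(default_factory=list)
    sweep_restarts: int = 3
    train: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def train_config(self) -> TrainConfig:
        cfg = desk_train_config(seed=(self.seed + 3) % 2**31)
        overrides = dict(self.train)
        if "hidden_sizes" in overrides:
            overrides["hidden_sizes"] = tuple(overrides["hidden_sizes"])
        return dataclasses.replace(cfg, **overrides)


def _ensure_outdir(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _log_stage(name: str, t0: float, **counts) -> None:
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s wall=%.1fs %s", name, time.time() - t0, extras)


# ---------------------------------------------------------------- simulate

def stage_simulate(config: RunConfig) -> Path:
    """Generate the synthetic epigenome and export it as BED files."""
    t0 = time.time()
    out = _ensure_outdir(config)
    spec = benchmark_spec(
        config.seed,
        chrom_sizes=config.chrom_sizes or None,
        n_enhancers=config.n_enhancers,
        n_tss=config.n_tss,
        n_unknown=config.n_unknown,
    )
    truth = generate(spec)
    data_dir = out / "data"
    export(truth, data_dir)
    sizes = {"chrom_sizes": dict(spec.chrom_sizes), "marks": list(spec.mark_names)}
    (out / "genome.json").write_text(json.dumps(sizes, indent=1))
    _log_stage("simulate", t0, sites=sum(len(v) for v in truth.sites.values()))
    return data_dir


def _load_inputs(config: RunConfig, out: Path):
    """Site peaks, read paths, genome sizes and mark order for this run."""
    if config.synthetic:
        genome = json.loads((out / "genome.json").read_text())
        chrom_sizes = {c: int(l) for c, l in genome["chrom_sizes"].items()}
        marks = config.marks or genome["marks"]
        data_dir = out / "data"
        sites = {cls: load_sites(data_dir, cls) for cls in ElementClass}
        read_paths = {m: [data_dir / f"reads_{m}_rep0.bed"] for m in marks}
    else:
        if not (config.chrom_sizes and config.read_beds):
            raise ValueError("non-synthetic runs need chrom_sizes and read_beds")
        chrom_sizes = dict(config.chrom_sizes)
        marks = config.marks or sorted(config.read_beds)
        sites = {
            cls: (read_bed(config.site_beds[cls.value], cls)
                  if cls.value in config.site_beds else [])
            for cls in ElementClass
        }
        read_paths = {m: [Path(p) for p in config.read_beds[m]] for m in marks}
    return sites, read_paths, chrom_sizes, marks


def stage_features(config: RunConfig) -> Path:
    """Bin reads, RPKM-normalize, average replicates; persist the tracks."""
    t0 = time.time()
    out = _ensure_outdir(config)
    _, read_paths, chrom_sizes, marks = _load_inputs(config, out)
    arrays: dict[str, np.ndarray] = {}
    for mark in marks:
        replicates = []
        for path in read_paths[mark]:
            rs = ReadSet.from_bed(path)
            counts, _ = bin_reads(rs, chrom_sizes, bin_width=config.bin_width)
            replicates.append(
                rpkm_normalize(counts, rs.total_mapped, config.bin_width, mark)
            )
        track = average_replicates(replicates)
        for chrom, values in track.values.items():
            arrays[f"{mark}|{chrom}"] = values
    header = {"marks": marks, "chrom_sizes": chrom_sizes, "bin_width": config.bin_width}
    np.savez(out / "tracks.npz",
             header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)
    _log_stage("features", t0, marks=len(marks))
    return out / "tracks.npz"


def load_tracks(path: str | Path) -> tuple[dict[str, BinnedTrack], dict[str, int]]:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        tracks: dict[str, BinnedTrack] = {}
        for mark in header["marks"]:
            values = {
                chrom: data[f"{mark}|{chrom}"] for chrom in header["chrom_sizes"]
            }
            tracks[mark] = BinnedTrack(mark=mark, bin_width=header["bin_width"],
                                       values=values)
    return tracks, {c: int(l) for c, l in header["chrom_sizes"].items()}


# ---------------------------------------------------------------- datasets

def stage_build_datasets(config: RunConfig) -> Path:
    """Select positives/negatives and assemble the standardized training set."""
    t0 = time.time()
    out = _ensure_outdir(config)
    sites, _, chrom_sizes, marks = _load_inputs(config, out)
    tracks, _ = load_tracks(out / "tracks.npz")
    spec = FeatureSpec(marks=tuple(marks), flank_bins=config.flank_bins,
                       bin_width=config.bin_width)
    positives = select_positive_training(
        sites[ElementClass.P300], sites[ElementClass.DHS], sites[ElementClass.TSS],
        min_dist=config.min_dist,
    )
    negatives = select_negative_training(
        sites[ElementClass.TSS], sites[ElementClass.DHS], chrom_sizes,
        n_random=config.n_random_bg, min_dist=config.min_dist,
        seed=(config.seed + 1) % 2**31, bin_width=config.bin_width,
    )
    ds = build_training_set(positives, negatives, tracks, spec,
                            ratio=config.ratio, seed=(config.seed + 2) % 2**31)
    mean = ds.features.X.mean(axis=0)
    scale = ds.features.X.std(axis=0)
    scale[scale == 0] = 1.0
    np.savez(
        out / "training.npz",
        X=(ds.features.X - mean) / scale,
        y=ds.labels,
        provenance=ds.provenance.astype("U16"),
        mean=mean,
        scale=scale,
        marks=np.array(marks, dtype="U32"),
        chroms=np.array([c for c, _ in ds.features.locations], dtype="U32"),
        bins=np.array([b for _, b in ds.features.locations]),
    )
    _log_stage("build-datasets", t0, rows=ds.n_samples,
               positives=int(ds.labels.sum()))
    return out / "training.npz"


def _load_training(out: Path, config: RunConfig) -> tuple[LabeledDataset, np.ndarray, np.ndarray]:
    with np.load(out / "training.npz") as data:
        marks = tuple(data["marks"])
        spec = FeatureSpec(marks=marks, flank_bins=config.flank_bins,
                           bin_width=config.bin_width)
        fm = FeatureMatrix(
            X=data["X"],
            locations=list(zip(data["chroms"], data["bins"].astype(int))),
            column_map=[(m, o) for m in marks for o in spec.offsets],
        )
        ds = LabeledDataset(features=fm, labels=data["y"],
                            provenance=data["provenance"])
        return ds, data["mean"], data["scale"]


# ---------------------------------------------------------------- training

def stage_train(config: RunConfig) -> Path:
    t0 = time.time()
    out = _ensure_outdir(config)
    ds, _, _ = _load_training(out, config)
    cfg = config.train_config()
    params, losses = train_best(ds.features.X, ds.labels, cfg, n_restarts=3)
    save_model(out / "model.npz", params, cfg)
    pd.DataFrame({"epoch": np.arange(len(losses)), "train_mse": losses}).to_csv(
        out / "loss.tsv", sep="\t", index=False
    )
    _log_stage("train", t0, final_mse=round(losses[-1], 5))
    return out / "model.npz"


def stage_importance(config: RunConfig) -> Path:
    t0 = time.time()
    out = _ensure_outdir(config)
    params, _ = load_model(out / "model.npz")
    ds, _, _ = _load_training(out, config)
    imp = importance_scores(params)
    ol = rank_features(imp)
    export_feature_table(ol, ds.features.column_map, out / "ordered_features.tsv")
    marks = aggregate_by_mark(imp.per_feature, ds.features.column_map)
    marks.rename_axis("mark").reset_index().to_csv(
        out / "mark_importance.tsv", sep="\t", index=False
    )
    _log_stage("importance", t0, n_features=imp.per_feature.size)
    return out / "ordered_features.tsv"


# ---------------------------------------------------------------- prediction

def _candidate_features(config: RunConfig, out: Path):
    tracks, chrom_sizes = load_tracks(out / "tracks.npz")
    with np.load(out / "training.npz") as data:
        marks = tuple(data["marks"])
        mean, scale = data["mean"], data["scale"]
    spec = FeatureSpec(marks=marks, flank_bins=config.flank_bins,
                       bin_width=config.bin_width)
    locations = [
        (chrom, b)
        for chrom, length in chrom_sizes.items()
        for b in range(length // config.bin_width)
    ]
    fm = assemble_features(tracks, spec, locations)
    fm.X = (fm.X - mean) / scale
    return fm


def stage_predict(config: RunConfig) -> Path:
    """Score every genomic bin and write predictions at the operating point."""
    t0 = time.time()
    out = _ensure_outdir(config)
    params, _ = load_model(out / "model.npz")
    fm = _candidate_features(config, out)
    scores = predict(params, fm.X)
    n_top = min(config.n_predictions, scores.size)
    threshold = float(np.sort(scores)[::-1][n_top]) if n_top < scores.size else float(scores.min() - 1)
    preds = make_prediction_set(fm.locations, scores, threshold,
                                bin_width=config.bin_width)
    preds.to_bed(out / "predictions.bed")
    np.savez(out / "scores.npz",
             scores=scores,
             chroms=np.array([c for c, _ in fm.locations], dtype="U32"),
             bins=np.array([b for _, b in fm.locations]),
             threshold=threshold)
    _log_stage("predict", t0, n_scored=scores.size, n_predicted=len(preds.locations))
    return out / "predictions.bed"


def stage_evaluate(config: RunConfig) -> Path:
    """Validate predictions against the true-positive markers; write the report."""
    t0 = time.time()
    out = _ensure_outdir(config)
    sites, _, _, _ = _load_inputs(config, out)
    tpm = SummitIndex(build_tpm_set(
        sites[ElementClass.DHS], sites[ElementClass.P300], sites[ElementClass.CBP],
        sites[ElementClass.TFBS], sites[ElementClass.TSS], min_dist=config.min_dist,
    ))
    with np.load(out / "scores.npz") as data:
        scores = data["scores"]
        locations = list(zip(data["chroms"], data["bins"].astype(int)))
        threshold = float(data["threshold"])
    preds = make_prediction_set(locations, scores, threshold,
                                bin_width=config.bin_width)
    result = validate_predictions(preds, tpm, radius=config.radius)
    grid = list(np.quantile(scores, np.linspace(0.999, 0.9, 12)))
    grid = sorted(set(grid), reverse=True)
    curve = threshold_sweep(locations, scores, tpm, grid, radius=config.radius,
                            bin_width=config.bin_width)
    curve.to_csv(out / "threshold_sweep.tsv", sep="\t", index=False)
    report = {
        "threshold": threshold,
        "n_predictions": result.n_predictions,
        "n_validated": result.n_validated,
        "validation_rate": result.rate,
        "radius_bp": config.radius,
    }
    (out / "validation.json").write_text(json.dumps(report, indent=1))
    _log_stage("evaluate", t0, rate=result.rate)
    return out / "validation.json"


def stage_sweep(config: RunConfig) -> Path:
    """Top-k reduced-model sweep at the configured operating point."""
    t0 = time.time()
    out = _ensure_outdir(config)
    sites, _, _, _ = _load_inputs(config, out)
    ds, _, _ = _load_training(out, config)
    params, train_cfg = load_model(out / "model.npz")
    ol = rank_features(importance_scores(params))
    fm = _candidate_features(config, out)
    tpm = SummitIndex(build_tpm_set(
        sites[ElementClass.DHS], sites[ElementClass.P300], sites[ElementClass.CBP],
        sites[ElementClass.TFBS], sites[ElementClass.TSS], min_dist=config.min_dist,
    ))
    from .evaluation import EvaluationInputs

    k_values = config.k_values or [ds.features.n_features, 80, 10]
    eval_inputs = EvaluationInputs(features=fm, tpm=tpm,
                                   n_predictions=config.n_predictions,
                                   radius=config.radius, bin_width=config.bin_width)
    table = top_k_sweep(ds, ol, k_values, train_cfg or config.train_config(),
                        eval_inputs, n_restarts=config.sweep_restarts)
    table.to_csv(out / "sweep.tsv", sep="\t", index=False)
    _log_stage("sweep", t0, n_k=len(k_values))
    return out / "sweep.tsv"


STAGES = {
    "simulate": stage_simulate,
    "features": stage_features,
    "build-datasets": stage_build_datasets,
    "train": stage_train,
    "importance": stage_importance,
    "predict": stage_predict,
    "evaluate": stage_evaluate,
    "sweep": stage_sweep,
}

_RUN_ALL_ORDER = ("simulate", "features", "build-datasets", "train",
                  "importance", "sweep", "predict", "evaluate")


def run_full(config: RunConfig) -> Path:
    """Execute every stage in order and write the run manifest."""
    out = _ensure_outdir(config)
    for name in _RUN_ALL_ORDER:
        if name == "simulate" and not config.synthetic:
            continue
        try:
            STAGES[name](config)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def replay_manifest(path: str | Path) -> Path:
    """Re-run a manifest; the config it records suffices to reproduce the run."""
    manifest = json.loads(Path(path).read_text())
    return run_full(RunConfig(**manifest["config"]))
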