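"""End-to-end orchestration: simulate -> extract -> select -> train -> evaluate.

A run is fully described by a :class:`RunConfig`; identical configs (and
seeds) reproduce every report bit-for-bit. The desk-scale training recipe
(epochs 30, batch 16, lr 3e-3) is sized for the bundled simulator, where a
fold sees a few hundred optimiser steps; ``paper_recipe=True`` restores the
reference recipe (Adam, lr 1e-4, 100 epochs, batch 64, gradient threshold
0.02), whose step sizes presume corpus-scale step counts.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, hod, synthetic
from .depth_io import DatasetIndex, load_action_sample
from .evaluation import CrossValidationResult, cross_subject_split, cross_validate
from .hod import HoDConfig
from .network import NetworkConfig, TrainConfig
from .synthetic import SceneConfig

__all__ = ["RunConfig", "DESK_RECIPE", "PAPER_RECIPE", "run", "threshold_sweep",
           "extract_dataset"]

#: Training recipe sized for the bundled simulator (a few hundred steps/fold).
DESK_RECIPE = TrainConfig(lr=3e-3, epochs=30, batch_size=16, grad_clip=0.02)
#: The reference recipe: Adam, lr 1e-4, 100 epochs, mini-batch 64, clip 0.02.
PAPER_RECIPE = TrainConfig(lr=1e-4, epochs=100, batch_size=64, grad_clip=0.02)


@dataclass(frozen=True)
class RunConfig:
    out_dir: str = "run"
    #: directory of PNG sample dirs + manifest.json; None simulates instead
    data_dir: str | None = None
    n_classes: int = 4
    n_per_class: int = 40
    n_frames: int = 20
    threshold: int = 90
    #: |x| <= zero_tol counts as zero when profiling sparsity; the default
    #: absorbs the sensor-noise floor of empty cells (see docs/methods.md)
    zero_tol: float = 0.03
    K: int = 10
    split: str = "kfold"  # or "cross-subject"
    seed: int = 0
    paper_mode: bool = False  # corpus-level mask fitting, as a replication aid
    paper_recipe: bool = False
    averaging: str = "macro"

    def __post_init__(self) -> None:
        if self.split not in ("kfold", "cross-subject"):
            raise ValueError(f"split must be 'kfold' or 'cross-subject', got {self.split!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown run-config keys: {sorted(bad)}")
        return cls(**data)

    def scene(self) -> SceneConfig:
        return SceneConfig(n_frames=self.n_frames)

    def recipe(self) -> TrainConfig:
        base = PAPER_RECIPE if self.paper_recipe else DESK_RECIPE
        return dataclasses.replace(base, seed=self.seed)


class _Log:
    def __init__(self, path: Path | None):
        self.path = path
        if path is not None:
            path.write_text("")

    def __call__(self, stage: str, msg: str) -> None:
        line = f"[{time.strftime('%Y-%m-%d %H:%M:%S')}] {stage}: {msg}"
        if self.path is not None:
            with self.path.open("a") as fh:
                fh.write(line + "\n")


def _load_index(config: RunConfig, log) -> DatasetIndex:
    if config.data_dir is None:
        log("simulate", f"C={config.n_classes} x {config.n_per_class} clips, "
            f"{config.n_frames} frames, seed={config.seed}")
        return synthetic.generate_dataset(
            config.n_per_class, config.n_classes, config.scene(), seed=config.seed)
    data_dir = Path(config.data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    samples = [
        load_action_sample(data_dir / s["sample_id"], s["label"],
                           sample_id=s["sample_id"], subject_id=s["subject_id"])
        for s in manifest["samples"]
    ]
    log("load", f"{len(samples)} samples from {data_dir}")
    return DatasetIndex(samples=samples, class_names=manifest["class_names"])


def extract_dataset(index: DatasetIndex, config: HoDConfig = HoDConfig()) -> np.ndarray:
    """(n_samples, n_frames, n_features) HoD tensor for an equal-length dataset."""
    return np.stack([hod.extract_sequence(s, config) for s in index.samples])


def _evaluate(config: RunConfig, x, y, subject_ids, threshold: int) -> CrossValidationResult:
    split = None
    if config.split == "cross-subject":
        split = cross_subject_split(subject_ids, config.K, config.seed)
    net = NetworkConfig(input_dim=x.shape[2], n_classes=config.n_classes)
    return cross_validate(
        x, y, net, config.recipe(), K=config.K, seed=config.seed,
        threshold=threshold, zero_tol=config.zero_tol,
        paper_mode=config.paper_mode, split=split, averaging=config.averaging)


def _write_reports(out: Path, config: RunConfig, result: CrossValidationResult,
                   class_names) -> None:
    cfg = {k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"}
    payload = {"config": cfg, "results": result.as_dict()}
    (out / "metrics.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    pd.DataFrame(result.pooled_confusion, index=class_names,
                 columns=class_names).to_csv(out / "confusion.csv")
    pd.DataFrame([f.as_dict() for f in result.folds]).to_csv(
        out / "folds.csv", index=False)


def run(config: RunConfig) -> CrossValidationResult:
    """Execute the full pipeline into ``config.out_dir``.

    Writes metrics.json (per-fold and mean metrics), confusion.csv (pooled
    over held-out folds), folds.csv, config.yaml and log.txt.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "log.txt")
    (out / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))
    index = _load_index(config, log)
    x = extract_dataset(index)
    log("extract", f"HoD tensor {x.shape}")
    result = _evaluate(config, x, index.labels,
                       np.array([s.subject_id for s in index.samples]),
                       config.threshold)
    log("evaluate", f"I2I@{config.threshold} mean accuracy "
        f"{result.mean['accuracy']:.4f} (kept {result.kept_counts})")
    _write_reports(out, config, result, index.class_names)
    log("done", f"reports in {out}")
    return result


def threshold_sweep(config: RunConfig, T_list: list[int],
                    write: bool = True) -> pd.DataFrame:
    """One evaluated run per threshold, reusing a single feature extraction.

    Returns a table sorted by T with kept-feature counts (non-decreasing in T)
    and mean cross-validated metrics; optionally writes sweep.csv.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "log.txt")
    index = _load_index(config, log)
    x = extract_dataset(index)  # computed once for the whole sweep
    log("extract", f"HoD tensor {x.shape} (cached for {len(T_list)} thresholds)")
    y = index.labels
    subj = np.array([s.subject_id for s in index.samples])
    rows = []
    for T in sorted(T_list):
        res = _evaluate(config, x, y, subj, T)
        log("sweep", f"I2I@{T}: kept~{int(np.mean(res.kept_counts))}, "
            f"acc {res.mean['accuracy']:.4f}")
        rows.append({"T": T, "scheme": f"I2I@{T}",
                     "kept_mean": float(np.mean(res.kept_counts)),
                     **res.mean})
    table = pd.DataFrame(rows)
    if write:
        table.to_csv(out / "sweep.csv", index=False)
    return table
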