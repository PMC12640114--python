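"""Experiment-grid orchestration.

Runs the full factorial (regimen x LR schedule x seed) for one domain,
evaluates every run under the domain's test conditions, and writes all
results — per-epoch metric CSVs, checkpoint archives, evaluation and
comparison tables, receptive-field tuning scores, weight-dynamics tables —
under an output directory together with a machine-readable manifest.
Re-running with the same config skips completed training cells; a config
hash guards against mixing incompatible partial results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from .degradations import DegradationSpec
from .imagesets import LabeledImageSet, SyntheticSetSpec, generate_dataset, load_imageset
from .network import ArchConfig, ConvLayerSpec, ModelCheckpoint
from .representations import (
    dynamics_frame,
    dynamics_profile,
    extract_first_layer,
    scatter_frame,
    tuning_scores,
)
from .schedules import make_lr_schedule, make_regimen, matched_pairs
from .training import RunRecord, TrainConfig, regimen_degraded_spec, train

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one experiment grid."""

    name: str = "experiment"
    domain: str = "acuity"  # acuity -> blur; color -> grayscale
    dataset: Optional[SyntheticSetSpec] = None
    manifest_path: Optional[str] = None  # user-supplied image directory
    regimens: Tuple[str, ...] = ("F2F", "D2D", "D2F", "F2D")
    lr_schedules: Tuple[str, ...] = ("const1", "dec1")
    seeds: Tuple[int, ...] = (1, 2, 3)
    total_epochs: int = 10
    arch: ArchConfig = field(default_factory=ArchConfig)
    train: Optional[TrainConfig] = None
    eval_sigmas: Tuple[float, ...] = ev.DEFAULT_BLUR_GRID
    eval_angles: Tuple[float, ...] = ev.DEFAULT_HUE_GRID

    def __post_init__(self):
        if self.domain not in ("acuity", "color"):
            raise ValueError("domain must be 'acuity' or 'color'")
        if not self.regimens or not self.lr_schedules or not self.seeds:
            raise ValueError("regimens, lr_schedules and seeds must be non-empty")
        if self.dataset is None and self.manifest_path is None:
            raise ValueError("config needs a dataset spec or a manifest path")

    @property
    def degraded_kind(self) -> str:
        return "blur" if self.domain == "acuity" else "grayscale"

    def train_config(self, seed: int) -> TrainConfig:
        base = self.train or TrainConfig()
        return dataclasses.replace(base, seed=seed, epochs=self.total_epochs)

    def to_json_dict(self) -> dict:
        d = {
            "name": self.name,
            "domain": self.domain,
            "dataset": self.dataset.to_json_dict() if self.dataset else None,
            "manifest_path": self.manifest_path,
            "regimens": list(self.regimens),
            "lr_schedules": list(self.lr_schedules),
            "seeds": list(self.seeds),
            "total_epochs": self.total_epochs,
            "arch": {
                "conv_layers": [list(dataclasses.astuple(c)) for c in self.arch.conv_layers],
                "fc_layers": list(self.arch.fc_layers),
                "n_classes": self.arch.n_classes,
                "input_size": self.arch.input_size,
            },
            "train": dataclasses.asdict(self.train) if self.train else None,
            "eval_sigmas": list(self.eval_sigmas),
            "eval_angles": list(self.eval_angles),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if d.get("dataset"):
            d["dataset"] = SyntheticSetSpec.from_json_dict(d["dataset"])
        if d.get("arch"):
            a = d["arch"]
            d["arch"] = ArchConfig(
                conv_layers=tuple(ConvLayerSpec(*c) for c in a["conv_layers"]),
                fc_layers=tuple(a["fc_layers"]),
                n_classes=a["n_classes"],
                input_size=a["input_size"],
            )
        if d.get("train"):
            d["train"] = TrainConfig(**d["train"])
        for key in ("regimens", "lr_schedules", "seeds", "eval_sigmas", "eval_angles"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_json_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def preset_config(name: str, **overrides) -> ExperimentConfig:
    """Shipped presets mirroring the main experiment grids."""
    from .presets import DESK_EPOCHS, DESK_SEEDS, desk_arch, desk_spec

    base = dict(
        dataset=desk_spec(),
        seeds=DESK_SEEDS,
        total_epochs=DESK_EPOCHS,
        arch=desk_arch(),
    )
    if name == "paper-desk-acuity":
        base.update(name=name, domain="acuity",
                    regimens=("F2F", "D2D", "D2F", "F2D"),
                    lr_schedules=("const1", "dec1"))
    elif name == "paper-desk-color":
        base.update(name=name, domain="color",
                    regimens=("F2F", "D2D", "D2F", "F2D"),
                    lr_schedules=("const1", "dec1"))
    elif name == "timing-sweep":
        base.update(name=name, domain="acuity",
                    regimens=("D2F",), lr_schedules=("dec1",))
    elif name == "gradual-factorial":
        base.update(name=name, domain="acuity",
                    regimens=("D2F", "gradual_blur"),
                    lr_schedules=("dec1", "gradual"))
    else:
        raise ValueError(f"unknown preset: {name!r}")
    base.update(overrides)
    return ExperimentConfig(**base)


# ---------------------------------------------------------------------------
# on-disk layout helpers

def _run_key(regimen: str, schedule: str, seed: int) -> str:
    return f"{regimen}__{schedule}__seed{seed}"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def save_checkpoints(run: RunRecord, path: Path):
    arrays = {}
    for ckpt in run.checkpoints:
        for layer, params in ckpt.layers.items():
            for key, arr in params.items():
                arrays[f"epoch{ckpt.epoch:04d}/{layer}/{key}"] = arr
    np.savez_compressed(path, **arrays)


def load_checkpoints(path: Path, arch: ArchConfig) -> List[ModelCheckpoint]:
    data = np.load(path)
    by_epoch: Dict[int, Dict[str, Dict[str, np.ndarray]]] = {}
    for name in data.files:
        epoch_s, layer, key = name.split("/")
        epoch = int(epoch_s.replace("epoch", ""))
        by_epoch.setdefault(epoch, {}).setdefault(layer, {})[key] = data[name]
    return [
        ModelCheckpoint(epoch=e, layers=by_epoch[e], arch=arch)
        for e in sorted(by_epoch)
    ]


def _load_dataset(config: ExperimentConfig) -> Tuple[LabeledImageSet, LabeledImageSet]:
    if config.dataset is not None:
        return generate_dataset(config.dataset)
    return (
        load_imageset(config.manifest_path, "train"),
        load_imageset(config.manifest_path, "test"),
    )


def run_experiment(config: ExperimentConfig, out_dir) -> dict:
    """Execute (or resume) a full experiment grid; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    cfg_hash = config.content_hash()
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") != cfg_hash:
            raise ValueError(
                f"output directory {out} holds results for a different config "
                f"(hash {manifest.get('config_hash')} != {cfg_hash}); refusing to mix"
            )
    else:
        manifest = {
            "config_hash": cfg_hash,
            "config": config.to_json_dict(),
            "runs": {},
            "files": {},
        }

    train_set, test_set = _load_dataset(config)
    degraded = (
        DegradationSpec(kind="blur", sigma_ref=4.0)
        if config.domain == "acuity"
        else DegradationSpec(kind="grayscale")
    )
    none = DegradationSpec(kind="none")

    def _register(path: Path):
        manifest["files"][str(path.relative_to(out))] = _sha256(path)

    # --- training grid -----------------------------------------------------
    runs: Dict[str, RunRecord] = {}
    for regimen_name in config.regimens:
        for schedule_name in config.lr_schedules:
            for seed in config.seeds:
                key = _run_key(regimen_name, schedule_name, seed)
                ckpt_file = out / f"{key}.checkpoints.npz"
                metrics_file = out / f"{key}.metrics.csv"
                regimen = make_regimen(
                    regimen_name, config.total_epochs, degraded_kind=config.degraded_kind
                )
                schedule = make_lr_schedule(schedule_name, config.total_epochs)
                if key in manifest["runs"] and ckpt_file.exists():
                    logger.info("skipping completed run %s", key)
                    ckpts = load_checkpoints(ckpt_file, config.arch)
                    runs[key] = RunRecord(
                        regimen=regimen, lr_schedule=schedule, seed=seed,
                        checkpoints=ckpts, per_epoch=[], arch=config.arch,
                    )
                    continue
                logger.info("training %s", key)
                run = train(
                    config.arch, train_set, test_set, regimen, schedule,
                    config.train_config(seed),
                )
                runs[key] = run
                run.metrics_frame().to_csv(metrics_file, index=False)
                save_checkpoints(run, ckpt_file)
                _register(metrics_file)
                _register(ckpt_file)
                manifest["runs"][key] = {
                    "regimen": regimen_name, "lr_schedule": schedule_name, "seed": seed,
                }
                manifest_path.write_text(json.dumps(manifest, indent=2))

    # --- evaluation battery -------------------------------------------------
    records = []
    sweep_rows = []
    for key, run in runs.items():
        info = manifest["runs"][key]
        final = run.final_checkpoint()
        common = dict(
            regimen_name=info["regimen"],
            lr_schedule_name=info["lr_schedule"],
            seed=info["seed"],
        )
        for cond_name, cond in (("full", none), ("degraded", degraded)):
            rec = ev.evaluate(final, test_set, cond, **common)
            records.append(rec)
        sweep = (
            ev.blur_sweep(final, test_set, config.eval_sigmas, **common)
            if config.domain == "acuity"
            else ev.hue_sweep(final, test_set, config.eval_angles, **common)
        )
        for r, x in zip(sweep, config.eval_sigmas if config.domain == "acuity" else config.eval_angles):
            sweep_rows.append(
                {**{"regimen": info["regimen"], "lr_schedule": info["lr_schedule"],
                    "seed": info["seed"]},
                 "x": x, "accuracy": r.top1_accuracy}
            )

    eval_file = out / "eval_records.csv"
    ev.records_frame(records).to_csv(eval_file, index=False)
    _register(eval_file)
    agg_file = out / "eval_aggregate.csv"
    ev.aggregate_seeds(records).to_csv(agg_file, index=False)
    _register(agg_file)
    sweep_file = out / "sweep_records.csv"
    pd.DataFrame(sweep_rows).to_csv(sweep_file, index=False)
    _register(sweep_file)

    cells = ev.compare_matched(records, matching_basis="initial")
    if cells:
        cmp_file = out / "comparison_initial.csv"
        ev.comparison_frame(cells).to_csv(cmp_file, index=False)
        _register(cmp_file)

    # --- representational analyses -----------------------------------------
    tuning_rows = []
    dyn_frames = []
    for key, run in runs.items():
        info = manifest["runs"][key]
        scores = tuning_scores(extract_first_layer(run.final_checkpoint()))
        for s in scores:
            tuning_rows.append(
                {"regimen": info["regimen"], "lr_schedule": info["lr_schedule"],
                 "seed": info["seed"], "filter_index": s.filter_index,
                 "color_score": s.color_score, "sf_centroid": s.sf_centroid}
            )
        if len(run.checkpoints) >= 2:
            recs, _ = dynamics_profile(run)
            df = dynamics_frame(recs)
            df.insert(0, "run", key)
            dyn_frames.append(df)
    tuning_file = out / "tuning_scores.csv"
    pd.DataFrame(tuning_rows).to_csv(tuning_file, index=False)
    _register(tuning_file)
    if dyn_frames:
        dyn_file = out / "dynamics.csv"
        pd.concat(dyn_frames, ignore_index=True).to_csv(dyn_file, index=False)
        _register(dyn_file)

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# figure-style tables

def figure_tables(results_dir, figure_id: str) -> Dict[str, pd.DataFrame]:
    """Assemble the table(s) behind one figure-style panel family.

    ``figure_id`` is one of ``accuracy`` (regimen x condition means +- SE),
    ``deltas`` (matched decreasing-minus-constant deltas), ``sweeps``
    (test-degradation sweep curves), ``scatter`` (per-filter tuning-score
    pairs for decreasing vs constant runs), ``dynamics`` (layer x epoch
    weight-change and correlation tables).
    """
    out = Path(results_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    expected = {
        _run_key(r, s, seed)
        for r in manifest["config"]["regimens"]
        for s in manifest["config"]["lr_schedules"]
        for seed in manifest["config"]["seeds"]
    }
    missing = expected - set(manifest["runs"])
    if missing:
        raise ValueError(f"incomplete factorial; missing runs: {sorted(missing)}")

    if figure_id == "accuracy":
        return {"accuracy": pd.read_csv(out / "eval_aggregate.csv")}
    if figure_id == "deltas":
        return {"deltas": pd.read_csv(out / "comparison_initial.csv")}
    if figure_id == "sweeps":
        return {"sweeps": pd.read_csv(out / "sweep_records.csv")}
    if figure_id == "scatter":
        df = pd.read_csv(out / "tuning_scores.csv")
        schedules = set(df["lr_schedule"])
        tables = {}
        for dec_name, const_name, _ in matched_pairs("initial"):
            if dec_name in schedules and const_name in schedules:
                dec = df[df["lr_schedule"] == dec_name]
                const = df[df["lr_schedule"] == const_name]
                merged = dec.merge(
                    const, on=["regimen", "seed", "filter_index"],
                    suffixes=("_decreasing", "_constant"),
                )
                tables[f"{dec_name}_vs_{const_name}"] = merged[
                    ["regimen", "seed", "filter_index",
                     "color_score_decreasing", "color_score_constant",
                     "sf_centroid_decreasing", "sf_centroid_constant"]
                ]
        return tables
    if figure_id == "dynamics":
        return {"dynamics": pd.read_csv(out / "dynamics.csv")}
    raise ValueError(f"unknown figure id: {figure_id!r}")
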