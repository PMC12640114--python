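"""Scaled-down replication grids and their summary statistics.

This module packages the canonical desk-scale experiment: for one domain
(acuity or color) it trains the four stimulus regimens under a constant
learning rate plus the developmental regimen (D2F) under the matched
decreasing rate, across three seeds, and derives the summary quantities of
interest — regimen-ordering contrasts, the decreasing-vs-constant
learning-rate benefit on degraded test images, first-layer color-tuning
scatter pairs, and weight-stabilization dynamics around the LR drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import evaluation as ev
from .degradations import DegradationSpec
from .imagesets import LabeledImageSet, generate_dataset
from .network import ArchConfig
from .presets import DESK_EPOCHS, DESK_SEEDS, desk_arch, desk_spec
from .representations import (
    adjacent_epoch_correlation,
    below_diagonal_count,
    color_tuning_score,
    dynamics_profile,
    extract_first_layer,
)
from .schedules import make_lr_schedule, make_regimen, scale_epoch
from .training import RunRecord, TrainConfig, train

REGIMENS = ("F2F", "D2D", "D2F", "F2D")


@dataclass
class GridResult:
    """All runs and final-checkpoint evaluations for one domain's grid."""

    domain: str
    epochs: int
    seeds: Tuple[int, ...]
    runs: Dict[Tuple[str, str, int], RunRecord]
    eval_records: List[ev.EvalRecord]
    test_set: LabeledImageSet
    degraded_condition: DegradationSpec

    def accuracy(self, regimen: str, schedule: str, condition: str) -> float:
        """Seed-averaged top-1 accuracy for one grid cell."""
        want = "none" if condition == "full" else self.degraded_condition.label()
        vals = [
            r.top1_accuracy
            for r in self.eval_records
            if r.regimen_name == regimen
            and r.lr_schedule_name == schedule
            and r.test_condition.label() == want
        ]
        if not vals:
            raise KeyError((regimen, schedule, condition))
        return float(np.mean(vals))


def run_replication_grid(
    domain: str,
    seeds: Sequence[int] = DESK_SEEDS,
    dataset_seed: int = 1,
    epochs: int = DESK_EPOCHS,
    arch: Optional[ArchConfig] = None,
) -> GridResult:
    """Train the canonical desk grid for one domain and evaluate it.

    Cells: every regimen under ``const1`` plus ``D2F`` under ``dec1``
    (the matched decreasing schedule), for every seed.  D2F runs keep
    per-epoch checkpoints for representational analyses.
    """
    if domain not in ("acuity", "color"):
        raise ValueError("domain must be 'acuity' or 'color'")
    degraded_kind = "blur" if domain == "acuity" else "grayscale"
    degraded_condition = (
        DegradationSpec("blur", sigma_ref=4.0)
        if domain == "acuity"
        else DegradationSpec("grayscale")
    )
    arch = arch or desk_arch()
    train_set, test_set = generate_dataset(desk_spec(seed=dataset_seed))

    cells = [(r, "const1") for r in REGIMENS] + [("D2F", "dec1")]
    runs: Dict[Tuple[str, str, int], RunRecord] = {}
    records: List[ev.EvalRecord] = []
    for regimen_name, schedule_name in cells:
        for seed in seeds:
            regimen = make_regimen(regimen_name, epochs, degraded_kind=degraded_kind)
            schedule = make_lr_schedule(schedule_name, epochs)
            cadence = 1 if regimen_name == "D2F" else epochs
            cfg = TrainConfig(
                epochs=epochs, seed=seed, eval_each_epoch=False,
                checkpoint_every=cadence,
            )
            run = train(arch, train_set, test_set, regimen, schedule, cfg)
            runs[(regimen_name, schedule_name, seed)] = run
            final = run.final_checkpoint()
            for cond in (DegradationSpec("none"), degraded_condition):
                records.append(
                    ev.evaluate(
                        final, test_set, cond,
                        regimen_name=regimen_name,
                        lr_schedule_name=schedule_name,
                        seed=seed,
                    )
                )
    return GridResult(
        domain=domain, epochs=epochs, seeds=tuple(seeds), runs=runs,
        eval_records=records, test_set=test_set,
        degraded_condition=degraded_condition,
    )


# ---------------------------------------------------------------------------
# summary quantities

def regimen_ordering_contrasts(grid: GridResult) -> Dict[str, float]:
    """Seed-averaged contrasts behind the regimen-ordering panels
    (constant LR 1): the F2F full-vs-degraded gap, the D2D
    degraded-vs-full gap, and the D2F-minus-F2D difference of
    mean(full, degraded)."""
    f2f = grid.accuracy("F2F", "const1", "full") - grid.accuracy("F2F", "const1", "degraded")
    d2d = grid.accuracy("D2D", "const1", "degraded") - grid.accuracy("D2D", "const1", "full")
    d2f = 0.5 * (
        grid.accuracy("D2F", "const1", "full") + grid.accuracy("D2F", "const1", "degraded")
    )
    f2d = 0.5 * (
        grid.accuracy("F2D", "const1", "full") + grid.accuracy("F2D", "const1", "degraded")
    )
    return {
        "f2f_full_minus_degraded": f2f,
        "d2d_degraded_minus_full": d2d,
        "d2f_minus_f2d_mean": d2f - f2d,
    }


def lr_decay_delta(grid: GridResult) -> Dict[str, float]:
    """Decreasing-minus-constant (dec1 - const1) accuracy delta for the
    developmental D2F regimen, per test condition, seed-averaged."""
    return {
        cond: grid.accuracy("D2F", "dec1", cond) - grid.accuracy("D2F", "const1", cond)
        for cond in ("degraded", "full")
    }


def color_scatter_pairs(grid: GridResult) -> List[Tuple[float, float]]:
    """Per-filter (decreasing, constant) color-tuning-score pairs for D2F
    runs sharing an initialization seed, pooled across seeds."""
    pairs: List[Tuple[float, float]] = []
    for seed in grid.seeds:
        dec = grid.runs[("D2F", "dec1", seed)].final_checkpoint()
        const = grid.runs[("D2F", "const1", seed)].final_checkpoint()
        for fd, fc in zip(extract_first_layer(dec), extract_first_layer(const)):
            pairs.append((color_tuning_score(fd), color_tuning_score(fc)))
    return pairs


def below_diagonal_fraction(grid: GridResult) -> Tuple[int, int]:
    return below_diagonal_count(color_scatter_pairs(grid))


def lr_drop_correlation_contrast(grid: GridResult) -> Dict[str, float]:
    """Mean adjacent-epoch weight correlation (all layers) before versus
    after the dec1 LR drop, over the grid's D2F dec1 runs."""
    switch = scale_epoch(50, grid.epochs)
    pre, post = [], []
    for seed in grid.seeds:
        run = grid.runs[("D2F", "dec1", seed)]
        records, _ = dynamics_profile(run)
        for rec in records:
            if np.isnan(rec.correlation):
                continue
            if rec.epoch_pair[1] <= switch:
                pre.append(rec.correlation)
            elif rec.epoch_pair[0] >= switch:
                post.append(rec.correlation)
    return {
        "pre_drop_mean_correlation": float(np.mean(pre)),
        "post_drop_mean_correlation": float(np.mean(post)),
    }


def stabilization_epochs(grid: GridResult, threshold: float = 0.99) -> Dict[str, float]:
    """Seed-averaged first epoch at which each layer's adjacent-epoch
    correlation reaches ``threshold`` in the D2F dec1 runs; layers that
    never stabilize count as epochs + 1."""
    sums: Dict[str, List[float]] = {}
    for seed in grid.seeds:
        run = grid.runs[("D2F", "dec1", seed)]
        _, stab = dynamics_profile(run, stabilization_threshold=threshold)
        for layer, epoch in stab.items():
            sums.setdefault(layer, []).append(
                float(epoch) if epoch is not None else float(grid.epochs + 1)
            )
    return {layer: float(np.mean(v)) for layer, v in sums.items()}


def zero_lr_sanity(
    arch: Optional[ArchConfig] = None, epochs: int = 2, seed: int = 0
) -> Dict[str, float]:
    """Train with an all-zero learning rate and summarize that nothing
    moved: max absolute weight change, min adjacent-epoch correlation,
    max change magnitude."""
    from .imagesets import SyntheticSetSpec
    from .network import ConvLayerSpec
    from .schedules import LRSchedule

    arch = arch or ArchConfig(
        conv_layers=(ConvLayerSpec(4, 3, 1, True), ConvLayerSpec(8, 3, 1, True)),
        fc_layers=(16,), n_classes=4, input_size=24,
    )
    spec = SyntheticSetSpec(
        n_classes=arch.n_classes, train_per_class=8, test_per_class=2,
        image_size=32, seed=seed,
    )
    train_set, test_set = generate_dataset(spec)
    zero = LRSchedule(name="zero", kind="constant", initial_lr=0.0)
    cfg = TrainConfig(epochs=epochs, seed=seed, batch_size=16, crop_size=arch.input_size,
                      eval_each_epoch=False, checkpoint_every=1)
    run = train(arch, train_set, test_set, make_regimen("F2F", epochs), zero, cfg)
    first, last = run.checkpoints[0], run.checkpoints[-1]
    max_change = max(
        float(np.max(np.abs(last.layers[n][k] - first.layers[n][k])))
        for n in first.layers
        for k in ("W", "b")
    )
    records, _ = dynamics_profile(run)
    return {
        "max_weight_change": max_change,
        "min_correlation": float(np.min([r.correlation for r in records])),
        "max_change_magnitude": float(np.max([r.change_magnitude for r in records])),
    }
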