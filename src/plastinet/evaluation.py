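"""Test batteries and matched schedule comparisons.

Evaluation is always deterministic: test images are degraded per the
requested condition, center-cropped, rescaled, and classified; accuracy is
top-1 over the whole split.  Sweeps vary test blur or test hue rotation to
probe how robustly a trained model generalizes away from its training
distribution.  Matched comparisons contrast each decreasing-LR run with
the constant-LR run sharing its initial (or final) value, per seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import degradations as deg
from .degradations import DegradationSpec, preprocess_batch
from .imagesets import LabeledImageSet
from .network import ModelCheckpoint, Network
from .schedules import (
    LRSchedule,
    RegimenSchedule,
    make_lr_schedule,
    make_regimen,
    matched_pairs,
)
from .training import RunRecord, TrainConfig, train

DEFAULT_BLUR_GRID = (0.0, 1.0, 2.0, 3.0, 4.0)
DEFAULT_HUE_GRID = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0)


@dataclass(frozen=True)
class EvalRecord:
    regimen_name: str
    lr_schedule_name: str
    seed: int
    test_condition: DegradationSpec
    top1_accuracy: float

    def __post_init__(self):
        if not 0 <= self.top1_accuracy <= 1:
            raise ValueError("accuracy must lie in [0, 1]")


@dataclass(frozen=True)
class ComparisonCell:
    regimen_name: str
    pair: Tuple[str, str]
    test_condition: str
    delta_accuracy: float
    se: float

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("standard error must be >= 0")


def evaluate(
    checkpoint: ModelCheckpoint,
    test_set: LabeledImageSet,
    condition: DegradationSpec = DegradationSpec(kind="none"),
    regimen_name: str = "",
    lr_schedule_name: str = "",
    seed: int = 0,
    crop_size: Optional[int] = None,
) -> EvalRecord:
    """Top-1 accuracy of a checkpoint on a (possibly degraded) test split."""
    if len(test_set) == 0:
        raise ValueError("test set is empty")
    if test_set.n_classes != checkpoint.arch.n_classes:
        raise ValueError("test set and model disagree on the number of classes")
    crop = crop_size if crop_size is not None else checkpoint.arch.input_size
    images = deg.apply_to_set(condition, test_set.images)
    x = preprocess_batch(images, train_mode=False, crop_size=crop)
    net = Network.from_checkpoint(checkpoint)
    preds = net.predict(x)
    acc = float(np.mean(preds == np.asarray(test_set.labels)))
    return EvalRecord(
        regimen_name=regimen_name,
        lr_schedule_name=lr_schedule_name,
        seed=seed,
        test_condition=condition,
        top1_accuracy=acc,
    )


def blur_sweep(
    checkpoint: ModelCheckpoint,
    test_set: LabeledImageSet,
    sigmas: Sequence[float] = DEFAULT_BLUR_GRID,
    **kwargs,
) -> List[EvalRecord]:
    """Accuracy as a function of test blur (sigma quoted at the reference
    resolution; 0 means no degradation)."""
    records = []
    for sigma in sigmas:
        if sigma < 0:
            raise ValueError("blur sigmas must be >= 0")
        cond = (
            DegradationSpec(kind="none")
            if sigma == 0
            else DegradationSpec(kind="blur", sigma_ref=float(sigma))
        )
        records.append(evaluate(checkpoint, test_set, cond, **kwargs))
    return records


def hue_sweep(
    checkpoint: ModelCheckpoint,
    test_set: LabeledImageSet,
    angles: Sequence[float] = DEFAULT_HUE_GRID,
    **kwargs,
) -> List[EvalRecord]:
    """Accuracy as test-image hues are rotated by each angle."""
    records = []
    for angle in angles:
        if not 0 <= angle % 360 < 360:
            raise ValueError("angles must be finite degrees")
        cond = (
            DegradationSpec(kind="none")
            if angle % 360 == 0
            else DegradationSpec(kind="hue_rotation", angle=float(angle % 360))
        )
        records.append(evaluate(checkpoint, test_set, cond, **kwargs))
    return records


def records_frame(records: Iterable[EvalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "regimen": r.regimen_name,
                "lr_schedule": r.lr_schedule_name,
                "seed": r.seed,
                "condition": r.test_condition.label(),
                "accuracy": r.top1_accuracy,
            }
            for r in records
        ]
    )


def aggregate_seeds(records: Iterable[EvalRecord]) -> pd.DataFrame:
    """Mean and standard error (sample SD / sqrt(n)) per
    (regimen, schedule, condition) cell across seeds.  Single-seed cells
    get ``se = NaN`` and ``se_defined = False``."""
    df = records_frame(records)
    out = []
    for key, grp in df.groupby(["regimen", "lr_schedule", "condition"]):
        vals = grp["accuracy"].to_numpy()
        n = len(vals)
        se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
        out.append(
            {
                "regimen": key[0],
                "lr_schedule": key[1],
                "condition": key[2],
                "n_seeds": n,
                "mean_accuracy": float(vals.mean()),
                "se": se,
                "se_defined": n >= 2,
            }
        )
    return pd.DataFrame(out)


def compare_matched(
    records: Iterable[EvalRecord], matching_basis: str = "initial"
) -> List[ComparisonCell]:
    """Per-seed decreasing-minus-constant accuracy deltas, averaged across
    seeds, for every matched schedule pair present in ``records``.

    Raises if a pair member is missing for any (regimen, condition, seed)
    covered by the other member.
    """
    df = records_frame(records)
    cells: List[ComparisonCell] = []
    for dec_name, const_name, basis in matched_pairs(matching_basis):
        dec = df[df["lr_schedule"] == dec_name]
        const = df[df["lr_schedule"] == const_name]
        if dec.empty or const.empty:
            continue
        for (regimen, condition), dgrp in dec.groupby(["regimen", "condition"]):
            cgrp = const[(const["regimen"] == regimen) & (const["condition"] == condition)]
            missing = set(dgrp["seed"]) - set(cgrp["seed"])
            if missing:
                raise ValueError(
                    f"missing {const_name} runs for regimen={regimen} "
                    f"condition={condition} seeds={sorted(missing)}"
                )
            deltas = []
            for _, row in dgrp.iterrows():
                cacc = cgrp[cgrp["seed"] == row["seed"]]["accuracy"].iloc[0]
                deltas.append(row["accuracy"] - cacc)
            deltas = np.asarray(deltas)
            se = (
                float(np.std(deltas, ddof=1) / np.sqrt(len(deltas)))
                if len(deltas) >= 2
                else 0.0
            )
            cells.append(
                ComparisonCell(
                    regimen_name=regimen,
                    pair=(dec_name, const_name),
                    test_condition=condition,
                    delta_accuracy=float(deltas.mean()),
                    se=se,
                )
            )
    return cells


def comparison_frame(cells: Iterable[ComparisonCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "regimen": c.regimen_name,
                "decreasing": c.pair[0],
                "constant": c.pair[1],
                "condition": c.test_condition,
                "delta_accuracy": c.delta_accuracy,
                "se": c.se,
            }
            for c in cells
        ]
    )


def timing_sweep(
    arch,
    train_set: LabeledImageSet,
    test_set: LabeledImageSet,
    config: TrainConfig,
    switch_epochs: Sequence[int],
    degraded_kind: str = "blur",
    mode: str = "lr_switch",
    lr_pair: Tuple[float, float] = (0.01, 0.001),
) -> pd.DataFrame:
    """Train/evaluate once per switch point and tabulate accuracies.

    ``mode='lr_switch'`` holds the regimen's degraded/full split at the
    midpoint and moves only the epoch after which the LR drops.
    ``mode='degraded_length'`` co-times the LR drop with the end of the
    degraded phase and varies that phase's length instead.
    """
    if mode not in ("lr_switch", "degraded_length"):
        raise ValueError("mode must be 'lr_switch' or 'degraded_length'")
    rows = []
    none = DegradationSpec(kind="none")
    for k in switch_epochs:
        if not 0 < k < config.epochs:
            raise ValueError(f"switch epoch {k} out of range (1..{config.epochs - 1})")
        regimen_switch = None if mode == "lr_switch" else k
        regimen = make_regimen(
            "D2F", config.epochs, degraded_kind=degraded_kind, switch_after=regimen_switch
        )
        schedule = LRSchedule(
            name=f"dec@{k}", kind="step", initial_lr=lr_pair[0], steps=((k, lr_pair[1]),)
        )
        run = train(arch, train_set, test_set, regimen, schedule, config)
        final = run.final_checkpoint()
        degraded_spec = regimen.phases[0][0]
        for cond_name, cond in (("full", none), ("degraded", degraded_spec)):
            rec = evaluate(final, test_set, cond, regimen_name=regimen.name,
                           lr_schedule_name=schedule.name, seed=config.seed)
            rows.append(
                {
                    "mode": mode,
                    "switch_epoch": k,
                    "seed": config.seed,
                    "condition": cond_name,
                    "accuracy": rec.top1_accuracy,
                }
            )
    return pd.DataFrame(rows)
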