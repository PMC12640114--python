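"""Training loop crossing stimulus regimens with learning-rate schedules.

Each run trains one network for ``config.epochs`` epochs.  At every epoch
the full training split is degraded according to the regimen's phase for
that epoch (degraded variants are cached per unique degradation), randomly
cropped/flipped, shuffled into minibatches, and passed once through SGD
with Nesterov momentum at the schedule's learning rate.  Weights are
checkpointed every ``checkpoint_every`` epochs (and always at the final
epoch) so that representational dynamics can be analysed afterwards.

All randomness flows from ``config.seed`` through three named child
streams (init / shuffle / augmentation), making whole runs bitwise
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import degradations as deg
from .degradations import DegradationSpec, preprocess_batch
from .imagesets import LabeledImageSet
from .network import ArchConfig, ModelCheckpoint, NesterovSGD, Network, build_model
from .schedules import (
    LRSchedule,
    PlateauState,
    RegimenSchedule,
    degradation_at_epoch,
    initial_plateau_state,
    lr_at_epoch,
    plateau_update,
)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    momentum: float = 0.9
    epochs: int = 10
    seed: int = 0
    crop_size: int = 56
    checkpoint_every: int = 1
    eval_each_epoch: bool = True
    plateau_monitor: str = "test_acc_full"  # or test_acc_degraded / train_loss

    def __post_init__(self):
        if self.batch_size <= 0 or self.epochs <= 0 or self.checkpoint_every <= 0:
            raise ValueError("batch_size, epochs and checkpoint_every must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")


@dataclass
class RunRecord:
    """Everything produced by one (regimen x LR schedule x seed) run."""

    regimen: RegimenSchedule
    lr_schedule: LRSchedule
    seed: int
    checkpoints: List[ModelCheckpoint]
    per_epoch: List[dict]
    arch: ArchConfig

    def final_checkpoint(self) -> ModelCheckpoint:
        return self.checkpoints[-1]

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.per_epoch:
            spec: DegradationSpec = rec["degradation"]
            rows.append(
                {
                    "epoch": rec["epoch"],
                    "lr": rec["lr"],
                    "degradation_kind": spec.kind,
                    "sigma": spec.sigma_ref if spec.kind == "blur" else np.nan,
                    "train_loss": rec["train_loss"],
                    "test_acc_full": rec.get("test_acc_full", np.nan),
                    "test_acc_degraded": rec.get("test_acc_degraded", np.nan),
                }
            )
        return pd.DataFrame(rows)


def regimen_degraded_spec(regimen: RegimenSchedule) -> DegradationSpec:
    """The regimen's characteristic degradation: the most severe non-identity
    phase spec (first phase order breaks ties), or identity for F2F."""
    candidates = [spec for spec, _ in regimen.phases if spec.kind != "none"]
    if not candidates:
        return DegradationSpec(kind="none")
    blurs = [s for s in candidates if s.kind == "blur"]
    if blurs:
        return max(blurs, key=lambda s: s.sigma_ref)
    return candidates[0]


class _DegradedCache:
    """Degraded copies of a split, computed once per unique degradation."""

    def __init__(self, image_set: LabeledImageSet):
        self.image_set = image_set
        self._store: Dict[str, list] = {}

    def get(self, spec: DegradationSpec) -> list:
        key = spec.label()
        if key not in self._store:
            self._store[key] = deg.apply_to_set(spec, self.image_set.images)
        return self._store[key]


def _accuracy(net: Network, images: list, labels: np.ndarray, crop_size: int) -> float:
    x = preprocess_batch(images, train_mode=False, crop_size=crop_size)
    preds = net.predict(x)
    return float(np.mean(preds == labels))


def train(
    arch: ArchConfig,
    train_set: LabeledImageSet,
    test_set: LabeledImageSet,
    regimen: RegimenSchedule,
    lr_schedule: LRSchedule,
    config: TrainConfig,
) -> RunRecord:
    """Run one full training simulation and return its :class:`RunRecord`."""
    if regimen.total_epochs != config.epochs:
        raise ValueError(
            f"regimen covers {regimen.total_epochs} epochs but config asks for {config.epochs}"
        )
    if train_set.n_classes != arch.n_classes or test_set.n_classes != arch.n_classes:
        raise ValueError("dataset and architecture disagree on the number of classes")

    init_ss, shuffle_ss, aug_ss = np.random.SeedSequence(config.seed).spawn(3)
    init_seed = int(init_ss.generate_state(1)[0] % (2**31))
    shuffle_rng = np.random.default_rng(shuffle_ss)
    aug_rng = np.random.default_rng(aug_ss)

    ckpt0 = build_model(arch, init_seed)
    net = Network.from_checkpoint(ckpt0)
    optimizer = NesterovSGD(momentum=config.momentum)

    train_cache = _DegradedCache(train_set)
    test_cache = _DegradedCache(test_set)
    labels = np.asarray(train_set.labels)
    test_labels = np.asarray(test_set.labels)
    degraded_eval_spec = regimen_degraded_spec(regimen)

    plateau_state: Optional[PlateauState] = None
    if lr_schedule.kind == "reduce_on_plateau":
        higher = config.plateau_monitor != "train_loss"
        plateau_state = initial_plateau_state(lr_schedule, higher_is_better=higher)

    checkpoints = [ckpt0]
    per_epoch: List[dict] = []
    n = len(train_set)

    for epoch in range(1, config.epochs + 1):
        lr = lr_at_epoch(lr_schedule, epoch, plateau_state)
        spec = degradation_at_epoch(regimen, epoch)
        images = train_cache.get(spec)
        x = preprocess_batch(images, train_mode=True, crop_size=config.crop_size, rng=aug_rng)
        perm = shuffle_rng.permutation(n)

        total_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            loss, grads = net.loss_and_gradients(x[idx], labels[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} (lr={lr})"
                )
            optimizer.step(net.layers, grads, lr)
            total_loss += loss * len(idx)
        train_loss = total_loss / n

        rec = {"epoch": epoch, "lr": lr, "degradation": spec, "train_loss": train_loss}
        if config.eval_each_epoch or lr_schedule.kind == "reduce_on_plateau":
            rec["test_acc_full"] = _accuracy(net, test_set.images, test_labels, config.crop_size)
            rec["test_acc_degraded"] = _accuracy(
                net, test_cache.get(degraded_eval_spec), test_labels, config.crop_size
            )
        per_epoch.append(rec)

        if plateau_state is not None:
            monitored = rec[config.plateau_monitor] if config.plateau_monitor != "train_loss" else train_loss
            plateau_state = plateau_update(
                plateau_state,
                lr_schedule.plateau_params,
                monitored,
                higher_is_better=config.plateau_monitor != "train_loss",
            )

        if epoch % config.checkpoint_every == 0 or epoch == config.epochs:
            checkpoints.append(net.checkpoint(epoch))

    return RunRecord(
        regimen=regimen,
        lr_schedule=lr_schedule,
        seed=config.seed,
        checkpoints=checkpoints,
        per_epoch=per_epoch,
        arch=arch,
    )
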