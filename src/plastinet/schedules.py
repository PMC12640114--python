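"""Stimulus regimens and learning-rate schedules.

A *regimen* is the temporal ordering of degraded versus full-fidelity
training inputs across epochs.  The four canonical presets are

    F2F  full-fidelity throughout (control)
    D2D  degraded throughout (control)
    D2F  degraded first half, full second half (the developmental order)
    F2D  the inverse of D2F

plus partial-degradation variants (a shorter initial degraded phase) and a
gradual-blur staircase.  A *learning-rate schedule* is the epoch-indexed
rule for the SGD step size, used as a computational stand-in for neuronal
plasticity level: constant presets model sustained plasticity, decreasing
presets model a time-limited critical period.

Epochs are 1-based throughout; "the LR drops after epoch k" means epochs
<= k keep the old value and epoch k+1 onward use the new one.  When
``total_epochs`` differs from the 100-epoch reference, all switch points
scale proportionally (rounded to nearest integer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

from .degradations import DegradationSpec

REFERENCE_EPOCHS = 100

#: Blur sigma (at the 256-px reference resolution) used for all "degraded"
#: acuity phases.
DEFAULT_BLUR_SIGMA = 4.0

REGIMEN_PRESETS = ("F2F", "D2D", "D2F", "F2D", "D2F_partial", "gradual_blur")

#: Constant learning-rate presets: name -> LR.
CONSTANT_LRS = {"const1": 0.01, "const2": 0.001, "const3": 0.0001}
#: Decreasing presets: name -> (initial LR, final LR); the drop happens
#: after the (scaled) midpoint epoch.
DECREASING_LRS = {
    "dec1": (0.01, 0.001),
    "dec2": (0.01, 0.0001),
    "dec3": (0.001, 0.0001),
}
#: Gradual decay staircase: one value per fifth of training.
GRADUAL_LR_VALUES = (0.01, 0.0075, 0.005, 0.0025, 0.001)
GRADUAL_BLUR_LEVELS = (4.0, 3.0, 2.0, 1.0, 0.0)


def scale_epoch(epoch_at_reference: int, total_epochs: int) -> int:
    """Map a switch epoch quoted at the 100-epoch reference onto a run of
    ``total_epochs``, preserving the fraction of training elapsed."""
    if total_epochs == REFERENCE_EPOCHS:
        return epoch_at_reference
    scaled = round(epoch_at_reference * total_epochs / REFERENCE_EPOCHS)
    return int(min(max(scaled, 0), total_epochs))


@dataclass(frozen=True)
class RegimenSchedule:
    """Epoch-indexed sequence of degradations: ordered (spec, n_epochs)
    phases summing to ``total_epochs``."""

    name: str
    phases: Tuple[Tuple[DegradationSpec, int], ...]
    total_epochs: int

    def __post_init__(self):
        if any(n <= 0 for _, n in self.phases):
            raise ValueError("phase epoch counts must be positive")
        if sum(n for _, n in self.phases) != self.total_epochs:
            raise ValueError("phase epochs must sum to total_epochs")

    def to_json_dict(self) -> dict:
        return {
            "name": self.name,
            "total_epochs": self.total_epochs,
            "phases": [
                {"degradation": spec.to_json_dict(), "n_epochs": n}
                for spec, n in self.phases
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "RegimenSchedule":
        phases = tuple(
            (DegradationSpec.from_json_dict(p["degradation"]), int(p["n_epochs"]))
            for p in d["phases"]
        )
        return cls(name=d["name"], phases=phases, total_epochs=int(d["total_epochs"]))


def _degraded_spec(degraded_kind: str, sigma_ref: float) -> DegradationSpec:
    if degraded_kind == "blur":
        return DegradationSpec(kind="blur", sigma_ref=sigma_ref)
    if degraded_kind == "grayscale":
        return DegradationSpec(kind="grayscale")
    raise ValueError(f"degraded kind must be 'blur' or 'grayscale', got {degraded_kind!r}")


def make_regimen(
    name: str,
    total_epochs: int = REFERENCE_EPOCHS,
    degraded_kind: str = "blur",
    sigma_ref: float = DEFAULT_BLUR_SIGMA,
    partial_epochs: Optional[int] = None,
    switch_after: Optional[int] = None,
) -> RegimenSchedule:
    """Build a named regimen preset.

    ``partial_epochs`` (for ``D2F_partial``) is quoted at the 100-epoch
    reference (10, 20, 30 or 40) and scaled proportionally.  ``switch_after``
    overrides the D2F/F2D midpoint switch (given in *actual* epochs), used
    by timing sweeps.
    """
    none = DegradationSpec(kind="none")
    degraded = _degraded_spec(degraded_kind, sigma_ref)
    if total_epochs <= 0:
        raise ValueError("total_epochs must be positive")

    if name in ("F2F", "D2D"):
        spec = none if name == "F2F" else degraded
        half = total_epochs // 2
        if half == 0:
            phases = ((spec, total_epochs),)
        else:
            # two identical-spec phases, mirroring the 50 + 50 bookkeeping
            phases = ((spec, half), (spec, total_epochs - half))
        return RegimenSchedule(name=name, phases=phases, total_epochs=total_epochs)

    if name in ("D2F", "F2D"):
        k = switch_after if switch_after is not None else scale_epoch(50, total_epochs)
        if not 0 < k < total_epochs:
            raise ValueError(f"switch epoch {k} out of range for {total_epochs} epochs")
        first, second = (degraded, none) if name == "D2F" else (none, degraded)
        return RegimenSchedule(
            name=name,
            phases=((first, k), (second, total_epochs - k)),
            total_epochs=total_epochs,
        )

    if name == "D2F_partial":
        if partial_epochs not in (10, 20, 30, 40):
            raise ValueError("D2F_partial requires partial_epochs in {10, 20, 30, 40}")
        k = scale_epoch(partial_epochs, total_epochs)
        if not 0 < k < total_epochs:
            raise ValueError("scaled partial phase collapses; increase total_epochs")
        return RegimenSchedule(
            name=f"D2F_partial{partial_epochs}",
            phases=((degraded, k), (none, total_epochs - k)),
            total_epochs=total_epochs,
        )

    if name == "gradual_blur":
        if degraded_kind != "blur":
            raise ValueError("gradual_blur is defined for the acuity (blur) domain")
        n_levels = len(GRADUAL_BLUR_LEVELS)
        if total_epochs < n_levels:
            raise ValueError(f"gradual_blur needs >= {n_levels} epochs")
        bounds = [scale_epoch(20 * i, total_epochs) for i in range(n_levels + 1)]
        phases = []
        for i, sigma in enumerate(GRADUAL_BLUR_LEVELS):
            n = bounds[i + 1] - bounds[i]
            if n <= 0:
                raise ValueError("gradual_blur phases collapse at this total_epochs")
            spec = DegradationSpec(kind="blur", sigma_ref=sigma) if sigma > 0 else none
            phases.append((spec, n))
        return RegimenSchedule(
            name="gradual_blur", phases=tuple(phases), total_epochs=total_epochs
        )

    raise ValueError(f"unknown regimen preset: {name!r}")


def degradation_at_epoch(regimen: RegimenSchedule, epoch: int) -> DegradationSpec:
    """Degradation in force at a 1-based epoch; phase boundaries are
    inclusive of their last epoch."""
    if not 1 <= epoch <= regimen.total_epochs:
        raise ValueError(
            f"epoch {epoch} out of range [1, {regimen.total_epochs}]"
        )
    upto = 0
    for spec, n in regimen.phases:
        upto += n
        if epoch <= upto:
            return spec
    raise AssertionError("unreachable: phases sum to total_epochs")


@dataclass(frozen=True)
class PlateauParams:
    factor: float = 0.5
    patience: int = 5
    min_delta: float = 0.0
    cooldown: int = 0
    min_lr: float = 0.0

    def __post_init__(self):
        if not 0 < self.factor < 1:
            raise ValueError("plateau factor must lie in (0, 1)")
        if self.patience < 0 or self.cooldown < 0 or self.min_delta < 0 or self.min_lr < 0:
            raise ValueError("plateau parameters must be non-negative")


@dataclass(frozen=True)
class LRSchedule:
    """Learning-rate rule.  ``steps`` lists (epoch_after_which, new_lr)
    pairs for step/multi_step kinds; plateau kinds carry
    :class:`PlateauParams` and are advanced externally through
    :func:`plateau_update`."""

    name: str
    kind: str
    initial_lr: float
    steps: Tuple[Tuple[int, float], ...] = ()
    plateau_params: Optional[PlateauParams] = None

    def __post_init__(self):
        if self.kind not in ("constant", "step", "multi_step", "reduce_on_plateau"):
            raise ValueError(f"unknown LR schedule kind: {self.kind!r}")
        if self.initial_lr < 0 or (self.initial_lr == 0 and self.kind != "constant"):
            # an all-zero constant schedule is allowed as a no-update diagnostic
            raise ValueError("initial_lr must be positive")
        if self.kind in ("step", "multi_step"):
            epochs = [e for e, _ in self.steps]
            lrs = [self.initial_lr] + [lr for _, lr in self.steps]
            if any(b <= a for a, b in zip(epochs, epochs[1:])):
                raise ValueError("step epochs must be strictly increasing")
            if any(b >= a for a, b in zip(lrs, lrs[1:])):
                raise ValueError("step LR values must be strictly decreasing")
        if self.kind == "reduce_on_plateau" and self.plateau_params is None:
            raise ValueError("reduce_on_plateau requires plateau_params")

    def final_lr(self) -> float:
        if self.kind in ("step", "multi_step") and self.steps:
            return self.steps[-1][1]
        return self.initial_lr

    def to_json_dict(self) -> dict:
        d = {"name": self.name, "kind": self.kind, "initial_lr": self.initial_lr}
        if self.steps:
            d["steps"] = [[int(e), float(lr)] for e, lr in self.steps]
        if self.plateau_params is not None:
            p = self.plateau_params
            d["plateau_params"] = {
                "factor": p.factor,
                "patience": p.patience,
                "min_delta": p.min_delta,
                "cooldown": p.cooldown,
                "min_lr": p.min_lr,
            }
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "LRSchedule":
        pp = d.get("plateau_params")
        return cls(
            name=d["name"],
            kind=d["kind"],
            initial_lr=float(d["initial_lr"]),
            steps=tuple((int(e), float(lr)) for e, lr in d.get("steps", ())),
            plateau_params=PlateauParams(**pp) if pp else None,
        )


@dataclass(frozen=True)
class PlateauState:
    """State machine for the reduce-on-plateau rule."""

    current_lr: float
    best_metric: float = -math.inf
    epochs_since_improvement: int = 0
    cooldown_remaining: int = 0

    def __post_init__(self):
        if self.epochs_since_improvement < 0 or self.cooldown_remaining < 0:
            raise ValueError("plateau counters must be non-negative")


LR_PRESETS = tuple(CONSTANT_LRS) + tuple(DECREASING_LRS) + ("gradual", "plateau")


def make_lr_schedule(
    name: str,
    total_epochs: int = REFERENCE_EPOCHS,
    switch_after: Optional[int] = None,
) -> LRSchedule:
    """Build a named LR schedule preset.

    Decreasing presets drop after the scaled midpoint unless
    ``switch_after`` (actual epochs) overrides it; the gradual preset steps
    down every fifth of training.
    """
    if name in CONSTANT_LRS:
        return LRSchedule(name=name, kind="constant", initial_lr=CONSTANT_LRS[name])
    if name in DECREASING_LRS:
        lo_hi = DECREASING_LRS[name]
        k = switch_after if switch_after is not None else scale_epoch(50, total_epochs)
        if not 0 < k <= total_epochs:
            raise ValueError(f"LR switch epoch {k} out of range")
        return LRSchedule(
            name=name, kind="step", initial_lr=lo_hi[0], steps=((k, lo_hi[1]),)
        )
    if name == "gradual":
        bounds = [scale_epoch(20 * i, total_epochs) for i in range(1, 5)]
        steps = tuple(
            (b, lr) for b, lr in zip(bounds, GRADUAL_LR_VALUES[1:]) if b < total_epochs
        )
        return LRSchedule(
            name="gradual", kind="multi_step",
            initial_lr=GRADUAL_LR_VALUES[0], steps=steps,
        )
    if name == "plateau":
        return LRSchedule(
            name="plateau", kind="reduce_on_plateau",
            initial_lr=0.01, plateau_params=PlateauParams(),
        )
    raise ValueError(f"unknown LR schedule preset: {name!r}")


def lr_at_epoch(
    schedule: LRSchedule, epoch: int, state: Optional[PlateauState] = None
) -> float:
    """Learning rate in force at a 1-based epoch.

    Step schedules change value at epoch k+1 when the step is quoted
    "after epoch k".  Plateau schedules simply report ``state.current_lr``
    (the caller advances the state with :func:`plateau_update`).
    """
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    if schedule.kind == "constant":
        return schedule.initial_lr
    if schedule.kind in ("step", "multi_step"):
        lr = schedule.initial_lr
        for after, new_lr in schedule.steps:
            if epoch > after:
                lr = new_lr
        return lr
    if schedule.kind == "reduce_on_plateau":
        if state is None:
            raise ValueError("plateau schedule queried without a PlateauState")
        return state.current_lr
    raise AssertionError("unreachable")


def initial_plateau_state(schedule: LRSchedule, higher_is_better: bool = True) -> PlateauState:
    best = -math.inf if higher_is_better else math.inf
    return PlateauState(current_lr=schedule.initial_lr, best_metric=best)


def plateau_update(
    state: PlateauState,
    params: PlateauParams,
    monitored: float,
    higher_is_better: bool = True,
) -> PlateauState:
    """Advance the reduce-on-plateau state after one epoch's monitored
    metric.

    An improvement larger than ``min_delta`` resets the stagnation counter;
    once the counter exceeds ``patience`` (and any cooldown has elapsed)
    the LR is multiplied by ``factor``, floored at ``min_lr``.
    """
    improved = (
        monitored > state.best_metric + params.min_delta
        if higher_is_better
        else monitored < state.best_metric - params.min_delta
    )
    best = monitored if improved else state.best_metric
    cooldown = max(state.cooldown_remaining - 1, 0)
    if state.cooldown_remaining > 0:
        # during cooldown stagnation is not accumulated
        return replace(
            state, best_metric=best, epochs_since_improvement=0,
            cooldown_remaining=cooldown,
        )
    stagnant = 0 if improved else state.epochs_since_improvement + 1
    if stagnant > params.patience:
        new_lr = max(state.current_lr * params.factor, params.min_lr)
        return PlateauState(
            current_lr=new_lr, best_metric=best,
            epochs_since_improvement=0, cooldown_remaining=params.cooldown,
        )
    return replace(state, best_metric=best, epochs_since_improvement=stagnant)


def matched_pairs(matching_basis: str = "initial") -> List[Tuple[str, str, str]]:
    """Decreasing-vs-constant schedule pairings.

    Matching by initial value pairs each decreasing preset with the
    constant preset sharing its starting LR; matching by final value pairs
    it with the constant preset equal to its ending LR.
    """
    if matching_basis == "initial":
        pairs = [("dec1", "const1"), ("dec2", "const1"), ("dec3", "const2")]
    elif matching_basis == "final":
        pairs = [("dec1", "const2"), ("dec2", "const3"), ("dec3", "const3")]
    else:
        raise ValueError("matching_basis must be 'initial' or 'final'")
    return [(d, c, matching_basis) for d, c in pairs]
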