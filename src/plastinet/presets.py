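"""Desk-scale study conditions.

One canonical configuration, defined once, under which the full regimen x
schedule grids are run on a single CPU in minutes: a 10-class synthetic
set (100 train + 30 test images per class, 64 x 64 px) with paired hue
centers (``hue_sharing=2``) so that hue and texture band are each
individually partial and jointly complete class cues, a 3-conv / 2-fc
classifier on 56 x 56 crops, and 10 training epochs with all regimen and
schedule switch points scaled proportionally from the 100-epoch reference.
"""

from __future__ import annotations

from .imagesets import SyntheticSetSpec
from .network import ArchConfig
from .training import TrainConfig

#: Seeds used for stochastic replication suites (three training runs).
DESK_SEEDS = (1, 2, 3)

DESK_EPOCHS = 10


def desk_spec(seed: int = 1) -> SyntheticSetSpec:
    return SyntheticSetSpec(
        n_classes=10,
        train_per_class=100,
        test_per_class=30,
        image_size=64,
        hue_sharing=2,
        seed=seed,
    )


def desk_arch() -> ArchConfig:
    return ArchConfig()


def desk_train_config(seed: int, epochs: int = DESK_EPOCHS) -> TrainConfig:
    return TrainConfig(epochs=epochs, seed=seed)
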