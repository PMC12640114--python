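"""First-layer receptive-field tuning and layer-wise weight dynamics.

Two per-filter tuning metrics summarize what a first-layer receptive field
responds to:

* ``color_tuning_score`` — the fraction of the filter's energy orthogonal
  to the achromatic (equal-channel) axis.  0 for grayscale-equivalent
  filters, 1 for purely chromatic ones; invariant to global scaling.
* ``sf_centroid`` — the power-weighted mean radial frequency of the
  filter's achromatic Fourier spectrum (cycles/pixel); low for coarse,
  smooth filters, high for fine-structured ones.

Weight-trajectory metrics quantify training dynamics per layer: the mean
absolute change of a layer's kernel weights between adjacent epochs, and
the Pearson correlation of the flattened kernel weights between adjacent
epochs (scale-invariant, so it disregards uniform filter growth or decay).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .network import ModelCheckpoint

STABILIZATION_THRESHOLD = 0.99

_ACHROMATIC_AXIS = np.ones(3) / np.sqrt(3.0)


@dataclass(frozen=True)
class FilterRaster:
    filter_index: int
    weights: np.ndarray  # k x k x 3

    def __post_init__(self):
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("filter weights must be finite")


@dataclass(frozen=True)
class TuningScore:
    filter_index: int
    color_score: float
    sf_centroid: float

    def __post_init__(self):
        if not 0 <= self.color_score <= 1:
            raise ValueError("color_score must lie in [0, 1]")
        if not 0 <= self.sf_centroid <= 0.5 * math.sqrt(2) + 1e-12:
            raise ValueError("sf_centroid out of the representable range")


@dataclass(frozen=True)
class WeightDynamicsRecord:
    layer_name: str
    epoch_pair: Tuple[int, int]
    change_magnitude: float
    correlation: float

    def __post_init__(self):
        if self.change_magnitude < 0:
            raise ValueError("change_magnitude must be >= 0")
        if not (np.isnan(self.correlation) or -1 - 1e-9 <= self.correlation <= 1 + 1e-9):
            raise ValueError("correlation must lie in [-1, 1]")


def extract_first_layer(checkpoint: ModelCheckpoint) -> List[FilterRaster]:
    """All first-conv-layer filters, in index order, as k x k x 3 rasters."""
    if "conv1" not in checkpoint.layers:
        raise ValueError("checkpoint has no convolutional layer")
    W = checkpoint.layers["conv1"]["W"]  # (k, k, 3, F)
    return [FilterRaster(i, np.array(W[:, :, :, i], dtype=np.float64)) for i in range(W.shape[3])]


def filter_mosaic(filters: Sequence[FilterRaster], n_cols: int = 8, pad: int = 1) -> np.ndarray:
    """Tile filters into one RGB image, each min-max normalized
    independently (for visualization only)."""
    k = filters[0].weights.shape[0]
    n = len(filters)
    n_rows = math.ceil(n / n_cols)
    tile_h = n_rows * (k + pad) + pad
    tile_w = n_cols * (k + pad) + pad
    canvas = np.full((tile_h, tile_w, 3), 0.5)
    for idx, f in enumerate(filters):
        w = f.weights
        lo, hi = w.min(), w.max()
        norm = (w - lo) / (hi - lo) if hi > lo else np.full_like(w, 0.5)
        r, c = divmod(idx, n_cols)
        y = pad + r * (k + pad)
        x = pad + c * (k + pad)
        canvas[y : y + k, x : x + k] = norm
    return canvas


def color_tuning_score(f: FilterRaster) -> float:
    """Chromatic energy fraction of a filter.

    Each pixel's RGB triplet is split into its projection onto the
    achromatic axis (1,1,1)/sqrt(3) and the chromatic residual; the score
    is the residual sum of squares over the total sum of squares (0 for an
    all-zero filter)."""
    w = np.asarray(f.weights, dtype=np.float64)
    total = float(np.sum(w**2))
    if total == 0:
        return 0.0
    achro = (w @ _ACHROMATIC_AXIS)[..., None] * _ACHROMATIC_AXIS
    resid = float(np.sum((w - achro) ** 2))
    return min(max(resid / total, 0.0), 1.0)


def sf_centroid(f: FilterRaster) -> float:
    """Power-weighted mean radial frequency (cycles/pixel) of the filter's
    mean-removed achromatic component; 0 for a constant filter.

    Invariant to amplitude scaling and to adding a constant."""
    w = np.asarray(f.weights, dtype=np.float64)
    achro = w @ _ACHROMATIC_AXIS
    achro = achro - achro.mean()
    power = np.abs(np.fft.fft2(achro)) ** 2
    k0, k1 = achro.shape
    fy = np.fft.fftfreq(k0)[:, None]
    fx = np.fft.fftfreq(k1)[None, :]
    radius = np.sqrt(fy**2 + fx**2)
    nondc = radius > 0
    total = power[nondc].sum()
    if total <= 0:
        return 0.0
    return float((power[nondc] * radius[nondc]).sum() / total)


def tuning_scores(filters: Sequence[FilterRaster]) -> List[TuningScore]:
    return [
        TuningScore(f.filter_index, color_tuning_score(f), sf_centroid(f)) for f in filters
    ]


def below_diagonal_count(pairs: Sequence[Tuple[float, float]]) -> Tuple[int, int]:
    """Count pairs with the first score strictly below the second.

    Convention: the first element is the decreasing-LR model's score
    (vertical axis), the second the constant-LR model's (horizontal axis);
    "below the diagonal" means score_A < score_B.  Ties do not count.
    """
    if len(pairs) == 0:
        raise ValueError("below_diagonal_count needs at least one pair")
    below = sum(1 for a, b in pairs if not (np.isnan(a) or np.isnan(b)) and a < b)
    return below, len(pairs)


def _layer_weights(ckpt: ModelCheckpoint, layer_name: str) -> np.ndarray:
    if layer_name not in ckpt.layers:
        raise ValueError(f"layer {layer_name!r} not in checkpoint")
    return np.asarray(ckpt.layers[layer_name]["W"], dtype=np.float64).ravel()


def weight_change_magnitude(
    ckpt_t: ModelCheckpoint, ckpt_t1: ModelCheckpoint, layer_name: str
) -> float:
    """Mean absolute elementwise difference of a layer's kernel weights
    between two checkpoints (biases excluded)."""
    a = _layer_weights(ckpt_t, layer_name)
    b = _layer_weights(ckpt_t1, layer_name)
    if a.shape != b.shape:
        raise ValueError(f"layer {layer_name!r} changed shape between checkpoints")
    return float(np.mean(np.abs(b - a)))


def adjacent_epoch_correlation(
    ckpt_t: ModelCheckpoint, ckpt_t1: ModelCheckpoint, layer_name: str
) -> float:
    """Pearson correlation of a layer's flattened kernel weights between
    two checkpoints (biases excluded); NaN for zero-variance layers."""
    a = _layer_weights(ckpt_t, layer_name)
    b = _layer_weights(ckpt_t1, layer_name)
    if a.shape != b.shape:
        raise ValueError(f"layer {layer_name!r} changed shape between checkpoints")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def dynamics_profile(
    run,
    layer_names: Optional[Sequence[str]] = None,
    stabilization_threshold: float = STABILIZATION_THRESHOLD,
) -> Tuple[List[WeightDynamicsRecord], Dict[str, Optional[int]]]:
    """Both dynamics metrics for every (layer, adjacent checkpoint pair).

    Returns the record list plus a per-layer summary: the first epoch t+1
    whose (t, t+1) correlation reaches the stabilization threshold, or
    ``None`` if it is never reached.  Zero-variance (NaN) correlations are
    excluded from the summary.
    """
    ckpts = run.checkpoints
    if len(ckpts) < 2:
        raise ValueError("dynamics_profile needs at least two checkpoints")
    if layer_names is None:
        layer_names = run.arch.layer_names()
    records: List[WeightDynamicsRecord] = []
    stabilization: Dict[str, Optional[int]] = {}
    for layer in layer_names:
        first_stable = None
        for c0, c1 in zip(ckpts, ckpts[1:]):
            mag = weight_change_magnitude(c0, c1, layer)
            corr = adjacent_epoch_correlation(c0, c1, layer)
            records.append(
                WeightDynamicsRecord(
                    layer_name=layer,
                    epoch_pair=(c0.epoch, c1.epoch),
                    change_magnitude=mag,
                    correlation=corr,
                )
            )
            if first_stable is None and not np.isnan(corr) and corr >= stabilization_threshold:
                first_stable = c1.epoch
        stabilization[layer] = first_stable
    return records, stabilization


def dynamics_frame(records: Sequence[WeightDynamicsRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "layer": r.layer_name,
                "epoch_from": r.epoch_pair[0],
                "epoch_to": r.epoch_pair[1],
                "change_magnitude": r.change_magnitude,
                "correlation": r.correlation,
            }
            for r in records
        ]
    )


def scatter_frame(
    scores_decreasing: Sequence[TuningScore],
    scores_constant: Sequence[TuningScore],
    metric: str = "color_score",
) -> pd.DataFrame:
    """Per-filter scatter data pairing two runs' tuning scores by filter
    index (runs must share the initialization seed for indices to
    correspond)."""
    if len(scores_decreasing) != len(scores_constant):
        raise ValueError("score lists must pair filters one-to-one")
    rows = []
    for sd, sc in zip(scores_decreasing, scores_constant):
        rows.append(
            {
                "filter_index": sd.filter_index,
                "score_decreasing": getattr(sd, metric),
                "score_constant": getattr(sc, metric),
            }
        )
    return pd.DataFrame(rows)
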