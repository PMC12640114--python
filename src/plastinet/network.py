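"""A compact trainable convolutional classifier in NumPy.

The network mirrors, at desk scale, the classic conv-then-fully-connected
object classifier design: a stack of convolutional layers (ReLU, optional
2x2 max-pooling) feeding fully-connected layers and a softmax output.
Convolutions are computed as im2col + BLAS matmul; gradients flow back
through an index-based col2im scatter.  Everything is float32 and strictly
deterministic for a given seed.

Weight layout: conv kernels are ``(k, k, in_ch, out_ch)`` so the first
layer's receptive fields are directly viewable as ``k x k x 3`` rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class ConvLayerSpec:
    n_filters: int
    kernel_size: int
    stride: int = 1
    pool: bool = False


@dataclass(frozen=True)
class ArchConfig:
    """Scaled-down conv-net architecture.

    At least two conv layers and one hidden fully-connected layer are
    required so that layer-wise dynamics (early vs. late layers) remain
    meaningful.  The output layer width always equals ``n_classes``.
    """

    conv_layers: Tuple[ConvLayerSpec, ...] = (
        ConvLayerSpec(32, 5, 2, True),
        ConvLayerSpec(64, 3, 1, True),
        ConvLayerSpec(64, 3, 1, False),
    )
    fc_layers: Tuple[int, ...] = (128,)
    n_classes: int = 10
    input_size: int = 56

    def __post_init__(self):
        if len(self.conv_layers) < 2:
            raise ValueError("at least 2 conv layers required")
        if len(self.fc_layers) < 1:
            raise ValueError("at least 1 hidden fc layer required")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @property
    def first_layer_filters(self) -> int:
        return self.conv_layers[0].n_filters

    def layer_names(self) -> List[str]:
        names = [f"conv{i + 1}" for i in range(len(self.conv_layers))]
        names += [f"fc{i + 1}" for i in range(len(self.fc_layers) + 1)]
        return names


@dataclass
class ModelCheckpoint:
    """Weight snapshot: ``layers`` maps layer name -> {"W": ..., "b": ...};
    epoch 0 denotes the initialization."""

    epoch: int
    layers: Dict[str, Dict[str, np.ndarray]]
    arch: ArchConfig


def _conv_out_size(size: int, k: int, stride: int, pool: bool) -> int:
    out = (size - k) // stride + 1
    if pool:
        out //= 2
    return out


def feature_size(arch: ArchConfig) -> int:
    """Flattened feature count entering the first fc layer."""
    size = arch.input_size
    ch = 3
    for spec in arch.conv_layers:
        size = _conv_out_size(size, spec.kernel_size, spec.stride, spec.pool)
        if size < 1:
            raise ValueError("architecture shrinks the input below 1 pixel")
        ch = spec.n_filters
    return size * size * ch


def build_model(arch: ArchConfig, seed: int) -> ModelCheckpoint:
    """He fan-in initialization of all layers, deterministic per seed."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    layers: Dict[str, Dict[str, np.ndarray]] = {}
    ch = 3
    for i, spec in enumerate(arch.conv_layers):
        k = spec.kernel_size
        fan_in = k * k * ch
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, ch, spec.n_filters))
        layers[f"conv{i + 1}"] = {
            "W": W.astype(np.float32),
            "b": np.zeros(spec.n_filters, dtype=np.float32),
        }
        ch = spec.n_filters
    width_in = feature_size(arch)
    widths = list(arch.fc_layers) + [arch.n_classes]
    for i, width in enumerate(widths):
        W = rng.normal(0.0, np.sqrt(2.0 / width_in), size=(width_in, width))
        layers[f"fc{i + 1}"] = {
            "W": W.astype(np.float32),
            "b": np.zeros(width, dtype=np.float32),
        }
        width_in = width
    return ModelCheckpoint(epoch=0, layers=layers, arch=arch)


def clone_weights(layers: Dict[str, Dict[str, np.ndarray]]) -> Dict[str, Dict[str, np.ndarray]]:
    return {name: {k: v.copy() for k, v in p.items()} for name, p in layers.items()}


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, H, W, C) -> (N, Ho, Wo, k*k*C) patch matrix."""
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # N, H-k+1, W-k+1, C, k, k
    win = win[:, ::stride, ::stride]
    n, ho, wo, c, _, _ = win.shape
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n, ho, wo, k * k * c)


class _Col2Im:
    """Precomputed scatter indices mapping patch gradients back to the
    input tensor (the adjoint of im2col)."""

    def __init__(self, h: int, w: int, c: int, k: int, stride: int):
        ho = (h - k) // stride + 1
        wo = (w - k) // stride + 1
        ys = (np.arange(ho) * stride)[:, None, None, None, None]
        xs = (np.arange(wo) * stride)[None, :, None, None, None]
        ki = np.arange(k)[None, None, :, None, None]
        kj = np.arange(k)[None, None, None, :, None]
        cc = np.arange(c)[None, None, None, None, :]
        idx = ((ys + ki) * w + (xs + kj)) * c + cc  # (ho, wo, k, k, c)
        self.idx = idx.ravel()
        self.per_image = h * w * c
        self.shape = (h, w, c)

    def scatter(self, dcols: np.ndarray, n: int) -> np.ndarray:
        offsets = (np.arange(n) * self.per_image)[:, None]
        flat_idx = (self.idx[None, :] + offsets).ravel()
        out = np.bincount(
            flat_idx, weights=dcols.reshape(n, -1).ravel().astype(np.float64),
            minlength=n * self.per_image,
        )
        return out.reshape((n,) + self.shape).astype(np.float32)


class Network:
    """Stateful forward/backward wrapper around a weight dictionary."""

    def __init__(self, arch: ArchConfig, layers: Dict[str, Dict[str, np.ndarray]]):
        self.arch = arch
        self.layers = layers
        self._col2im_cache: Dict[tuple, _Col2Im] = {}

    @classmethod
    def from_checkpoint(cls, ckpt: ModelCheckpoint) -> "Network":
        return cls(ckpt.arch, clone_weights(ckpt.layers))

    def checkpoint(self, epoch: int) -> ModelCheckpoint:
        return ModelCheckpoint(epoch=epoch, layers=clone_weights(self.layers), arch=self.arch)

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, cache: Optional[list] = None) -> np.ndarray:
        """Logits for a (N, H, W, 3) float32 batch; fills ``cache`` with the
        intermediates needed by :meth:`backward` when given."""
        record = cache is not None
        for i, spec in enumerate(self.arch.conv_layers):
            p = self.layers[f"conv{i + 1}"]
            k = spec.kernel_size
            cols = _im2col(x, k, spec.stride)
            wf = p["W"].reshape(-1, spec.n_filters)
            pre = cols @ wf + p["b"]
            act = np.maximum(pre, 0.0)
            pool_cache = None
            if spec.pool:
                act, pool_cache = _maxpool_forward(act)
            if record:
                cache.append(("conv", i, x.shape, cols, pre > 0, pool_cache))
            x = act
        n = x.shape[0]
        x = x.reshape(n, -1)
        n_fc = len(self.arch.fc_layers) + 1
        for i in range(n_fc):
            p = self.layers[f"fc{i + 1}"]
            pre = x @ p["W"] + p["b"]
            last = i == n_fc - 1
            act = pre if last else np.maximum(pre, 0.0)
            if record:
                cache.append(("fc", i, x, None if last else pre > 0))
            x = act
        return x

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        preds = []
        for start in range(0, x.shape[0], batch_size):
            logits = self.forward(x[start : start + batch_size])
            preds.append(np.argmax(logits, axis=1))
        return np.concatenate(preds)

    # -- backward ----------------------------------------------------------

    def loss_and_gradients(self, x: np.ndarray, y: np.ndarray):
        """Mean categorical cross-entropy and gradients w.r.t. all
        parameters for one minibatch."""
        cache: list = []
        logits = self.forward(x, cache=cache)
        n = x.shape[0]
        shifted = logits - logits.max(axis=1, keepdims=True)
        logsumexp = np.log(np.exp(shifted).sum(axis=1))
        loss = float(np.mean(logsumexp - shifted[np.arange(n), y]))
        probs = np.exp(shifted) / np.exp(shifted).sum(axis=1, keepdims=True)
        dlogits = probs
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n

        grads: Dict[str, Dict[str, np.ndarray]] = {}
        grad = dlogits.astype(np.float32)
        for entry in reversed(cache):
            if entry[0] == "fc":
                _, i, inp, relu_mask = entry
                if relu_mask is not None:
                    grad = grad * relu_mask
                p = self.layers[f"fc{i + 1}"]
                grads[f"fc{i + 1}"] = {"W": inp.T @ grad, "b": grad.sum(axis=0)}
                grad = grad @ p["W"].T
            else:
                _, i, in_shape, cols, relu_mask, pool_cache = entry
                spec = self.arch.conv_layers[i]
                if i == len(self.arch.conv_layers) - 1:
                    out_shape = relu_mask.shape if pool_cache is None else pool_cache[1].shape
                    grad = grad.reshape(out_shape)
                if pool_cache is not None:
                    grad = _maxpool_backward(grad, pool_cache)
                grad = grad * relu_mask
                wf = self.layers[f"conv{i + 1}"]["W"].reshape(-1, spec.n_filters)
                nb, ho, wo, kkc = cols.shape
                g2 = grad.reshape(-1, spec.n_filters)
                dW = cols.reshape(-1, kkc).T @ g2
                grads[f"conv{i + 1}"] = {
                    "W": dW.reshape(self.layers[f"conv{i + 1}"]["W"].shape),
                    "b": g2.sum(axis=0),
                }
                if i > 0:  # no need for the input-image gradient
                    dcols = g2 @ wf.T
                    key = (in_shape[1], in_shape[2], in_shape[3], spec.kernel_size, spec.stride)
                    if key not in self._col2im_cache:
                        self._col2im_cache[key] = _Col2Im(*key)
                    grad = self._col2im_cache[key].scatter(
                        dcols.reshape(nb, ho, wo, kkc), nb
                    )
        return loss, grads


def _maxpool_forward(x: np.ndarray):
    """2x2 stride-2 max pooling (odd trailing row/col dropped)."""
    n, h, w, c = x.shape
    ho, wo = h // 2, w // 2
    xr = x[:, : 2 * ho, : 2 * wo, :].reshape(n, ho, 2, wo, 2, c)
    xr = np.ascontiguousarray(xr.transpose(0, 1, 3, 5, 2, 4)).reshape(n, ho, wo, c, 4)
    am = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, am[..., None], axis=-1)[..., 0]
    return out, (x.shape, am)


def _maxpool_backward(grad: np.ndarray, pool_cache) -> np.ndarray:
    in_shape, am = pool_cache
    n, h, w, c = in_shape
    ho, wo = am.shape[1], am.shape[2]
    d4 = np.zeros((n, ho, wo, c, 4), dtype=grad.dtype)
    np.put_along_axis(d4, am[..., None], grad[..., None], axis=-1)
    d = d4.reshape(n, ho, wo, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, 2 * ho, 2 * wo, c)
    if 2 * ho != h or 2 * wo != w:
        full = np.zeros(in_shape, dtype=grad.dtype)
        full[:, : 2 * ho, : 2 * wo, :] = d
        return full
    return d


class NesterovSGD:
    """SGD with Nesterov momentum, matching the common DL-framework update:
    ``v <- m v - lr g``; ``w <- w + m v - lr g``.  A zero learning rate
    leaves weights bitwise unchanged."""

    def __init__(self, momentum: float = 0.9):
        if not 0 <= momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        self.momentum = momentum
        self.velocity: Dict[str, Dict[str, np.ndarray]] = {}

    def step(self, layers, grads, lr: float):
        m = self.momentum
        for name, params in layers.items():
            g = grads[name]
            vdict = self.velocity.setdefault(
                name, {k: np.zeros_like(v) for k, v in params.items()}
            )
            for key, w in params.items():
                gk = g[key].astype(np.float32)
                v = m * vdict[key] - lr * gk
                vdict[key] = v
                w += m * v - lr * gk
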