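"""Stimulus degradations and test-time perturbations.

Training-time manipulations emulate degraded developmental visual input:
Gaussian blur stands in for low visual acuity, grayscale conversion for
immature color vision.  Test-time perturbations (blur sweeps, hue rotation)
probe how much a trained model relies on fine spatial structure or on
specific chromatic values.

All operators take H x W x 3 float rasters with values in [0, 1] and return
arrays of the same shape.  Math is done in floating point; clipping to
[0, 1] happens only at operator exit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import color as _skcolor

#: Reference image width (pixels) at which blur sigmas are quoted.  A blur
#: of ``sigma_ref`` pixels at this resolution is scaled to the same fraction
#: of image extent at any other resolution.
REFERENCE_SIZE = 256

#: ITU-R BT.601 luminance coefficients.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class DegradationSpec:
    """One stimulus manipulation.

    Parameters
    ----------
    kind:
        One of ``"none"``, ``"blur"``, ``"grayscale"``, ``"hue_rotation"``.
    sigma_ref:
        Gaussian blur sigma in pixels at the :data:`REFERENCE_SIZE`
        resolution.  Required (and only allowed) for ``kind="blur"``.
    angle:
        Hue shift in degrees.  Required (and only allowed) for
        ``kind="hue_rotation"``.
    """

    kind: str = "none"
    sigma_ref: Optional[float] = None
    angle: Optional[float] = None

    def __post_init__(self):
        if self.kind not in ("none", "blur", "grayscale", "hue_rotation"):
            raise ValueError(f"unknown degradation kind: {self.kind!r}")
        if (self.kind == "blur") != (self.sigma_ref is not None):
            raise ValueError("sigma_ref must be given iff kind='blur'")
        if (self.kind == "hue_rotation") != (self.angle is not None):
            raise ValueError("angle must be given iff kind='hue_rotation'")
        if self.sigma_ref is not None and self.sigma_ref < 0:
            raise ValueError("sigma_ref must be >= 0")

    def to_json_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.sigma_ref is not None:
            d["sigma_ref"] = float(self.sigma_ref)
        if self.angle is not None:
            d["angle"] = float(self.angle)
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "DegradationSpec":
        return cls(
            kind=d.get("kind", "none"),
            sigma_ref=d.get("sigma_ref"),
            angle=d.get("angle"),
        )

    def label(self) -> str:
        if self.kind == "blur":
            return f"blur{self.sigma_ref:g}"
        if self.kind == "hue_rotation":
            return f"hue{self.angle:g}"
        return self.kind


def _check_raster(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 raster, got shape {image.shape}")
    return image


def gaussian_blur(
    image: np.ndarray,
    sigma_ref: float,
    ref_size: int = REFERENCE_SIZE,
    clip: bool = True,
) -> np.ndarray:
    """Isotropic Gaussian blur with resolution-scaled sigma.

    The effective sigma is ``sigma_ref * image_width / ref_size`` so that a
    given ``sigma_ref`` removes the same fraction of image extent at every
    resolution.  Channels are filtered independently with reflective
    boundary handling and the kernel truncated at 4 sigma.

    ``sigma_ref == 0`` returns the input values unchanged.  Set
    ``clip=False`` to obtain the raw filtered values (useful for spectral
    analysis, where clipping would re-introduce high frequencies).
    """
    image = _check_raster(image)
    if sigma_ref < 0:
        raise ValueError("sigma_ref must be >= 0")
    if sigma_ref == 0:
        return image.copy()
    sigma_eff = sigma_ref * image.shape[1] / ref_size
    out = ndimage.gaussian_filter(
        image, sigma=(sigma_eff, sigma_eff, 0), mode="reflect", truncate=4.0
    )
    return np.clip(out, 0.0, 1.0) if clip else out


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """BT.601 luminance, replicated into all three channels.

    Replication keeps the tensor shape constant so one network can be
    trained across chromatic and achromatic phases.  Idempotent.
    """
    image = _check_raster(image)
    luma = image @ LUMA_WEIGHTS
    return np.repeat(luma[:, :, None], 3, axis=2)


def hue_rotate(image: np.ndarray, angle: float) -> np.ndarray:
    """Shift every pixel's hue by ``angle`` degrees (modulo 360).

    Works in an HSV decomposition; saturation and value are preserved up to
    floating-point round trip.  ``angle`` multiples of 360 are identities.
    """
    image = _check_raster(image)
    shift = (angle / 360.0) % 1.0
    if shift == 0.0:
        return image.copy()
    hsv = _skcolor.rgb2hsv(image)
    hsv[:, :, 0] = (hsv[:, :, 0] + shift) % 1.0
    return np.clip(_skcolor.hsv2rgb(hsv), 0.0, 1.0)


def apply(spec: DegradationSpec, image: np.ndarray) -> np.ndarray:
    """Dispatch ``spec`` to the matching operator; ``kind='none'`` is the
    exact identity."""
    if spec.kind == "none":
        return image
    if spec.kind == "blur":
        return gaussian_blur(image, spec.sigma_ref)
    if spec.kind == "grayscale":
        return to_grayscale(image)
    if spec.kind == "hue_rotation":
        return hue_rotate(image, spec.angle)
    raise ValueError(f"unknown degradation kind: {spec.kind!r}")


def apply_to_set(spec: DegradationSpec, images) -> list:
    """Apply one degradation to every raster of a sequence."""
    if spec.kind == "none":
        return list(images)
    return [apply(spec, im) for im in images]


def preprocess_batch(
    images,
    train_mode: bool,
    crop_size: int,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Crop, optionally flip, and rescale a batch to model input range.

    Training mode takes a uniformly random crop position and an independent
    0.5-probability horizontal flip per image, drawn from ``rng`` (the run's
    seeded stream).  Eval mode takes a deterministic center crop with no
    flip.  Pixels are affinely rescaled from [0, 1] to [-1, 1].

    Returns an ``N x crop x crop x 3`` float32 tensor.
    """
    images = [np.asarray(im) for im in images]
    h, w = images[0].shape[:2]
    if crop_size >= h or crop_size >= w:
        raise ValueError(f"crop_size {crop_size} must be < image size {h}x{w}")
    if train_mode and rng is None:
        raise ValueError("train_mode preprocessing requires a seeded rng")
    n = len(images)
    out = np.empty((n, crop_size, crop_size, 3), dtype=np.float32)
    if train_mode:
        ys = rng.integers(0, h - crop_size + 1, size=n)
        xs = rng.integers(0, w - crop_size + 1, size=n)
        flips = rng.random(n) < 0.5
    else:
        ys = np.full(n, (h - crop_size) // 2)
        xs = np.full(n, (w - crop_size) // 2)
        flips = np.zeros(n, dtype=bool)
    for i, im in enumerate(images):
        crop = im[ys[i] : ys[i] + crop_size, xs[i] : xs[i] + crop_size, :]
        if flips[i]:
            crop = crop[:, ::-1, :]
        out[i] = crop
    out *= 2.0
    out -= 1.0
    return out


def spectral_power_above(image: np.ndarray, cutoff: float) -> float:
    """Total 2-D spectral power at radial frequencies above ``cutoff``
    (cycles/pixel), summed over channels.  Used to verify that blur
    monotonically removes fine structure."""
    image = _check_raster(image)
    h, w = image.shape[:2]
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.sqrt(fy**2 + fx**2)
    mask = radius > cutoff
    total = 0.0
    for c in range(3):
        spec = np.fft.fft2(image[:, :, c])
        total += float(np.sum(np.abs(spec[mask]) ** 2))
    return total
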