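"""Procedural multi-class image sets.

These datasets stand in for a large natural-image corpus at desk scale.
Each class is defined by three redundant cues:

* a class-specific **hue** (class hue centers equally spaced on the hue
  circle), so grayscale conversion removes chromatic class information;
* a class-specific **band-pass texture** (filtered white noise masked to
  the shape), so Gaussian blur removes fine spatial-frequency class
  information;
* a class-specific **procedural shape** (regular polygons and smooth
  blobs), which survives both degradations and keeps degraded training
  phases learnable.

Because both removable cue families genuinely carry class information,
training-phase degradations are consequential rather than cosmetic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import color as _skcolor
from skimage.draw import polygon as _draw_polygon

from .degradations import LUMA_WEIGHTS

#: Fractional amplitude of the multiplicative value-channel texture.
TEXTURE_AMPLITUDE = 0.35
#: Per-image jitters keep classes from being trivially memorizable.
HUE_JITTER_DEG = 8.0
SV_JITTER = 0.1


def _default_texture_bands(
    n_classes: int, hue_sharing: int = 1
) -> Tuple[Tuple[float, float], ...]:
    """Evenly spaced band centers over 0.28-0.46 cycles/pixel, width 0.06.

    The bands sit high enough that Gaussian blur at the canonical severity
    effectively erases them (rather than merely attenuating them), so a
    blurred training phase must fall back on the coarse cue families.
    When several consecutive classes share a hue center
    (``hue_sharing > 1``), band indices are interleaved so that same-hue
    classes receive well-separated texture bands and remain
    distinguishable by texture alone.
    """
    if n_classes == 1:
        centers = np.array([0.37])
    else:
        centers = np.linspace(0.28, 0.46, n_classes)
    n_groups = max(n_classes // hue_sharing, 1)
    order = [(k % hue_sharing) * n_groups + (k // hue_sharing) for k in range(n_classes)]
    order = [min(o, n_classes - 1) for o in order]
    centers = centers[order]
    return tuple((float(c - 0.03), float(c + 0.03)) for c in centers)


def _default_shape_families(n_classes: int, hue_sharing: int = 1) -> Tuple[str, ...]:
    """Distinct polygon outlines (vertex counts 3, 4, ...).

    The outline is the coarse, blur-robust cue family: unlike the fine
    texture it survives blurring, so a degraded training phase can instill
    shape-based strategies that remain valid on full-fidelity input.  With
    ``hue_sharing > 1`` vertex counts are interleaved so same-hue classes
    receive maximally different outlines.
    """
    counts = np.arange(3, 3 + n_classes)
    n_groups = max(n_classes // hue_sharing, 1)
    order = [(k % hue_sharing) * n_groups + (k // hue_sharing) for k in range(n_classes)]
    order = [min(o, n_classes - 1) for o in order]
    return tuple(f"polygon{int(counts[o])}" for o in order)


@dataclass(frozen=True)
class SyntheticSetSpec:
    """Full generative recipe for one synthetic labeled image set."""

    n_classes: int = 10
    train_per_class: int = 200
    test_per_class: int = 50
    image_size: int = 64
    hue_separation: Optional[float] = None  # degrees; None -> 360 / n_hue_centers
    texture_freq_band_per_class: Optional[Tuple[Tuple[float, float], ...]] = None
    shape_family_per_class: Optional[Tuple[str, ...]] = None
    noise_sd: float = 0.02
    seed: int = 0
    #: Number of consecutive classes sharing one hue center.  With the
    #: default 1 every class has its own hue; with 2 the hue identifies a
    #: class only up to a pair resolved by texture band, so removing either
    #: cue family discards genuine class information.
    hue_sharing: int = 1

    def __post_init__(self):
        for name in ("n_classes", "train_per_class", "test_per_class", "image_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.hue_sharing < 1 or self.n_classes % self.hue_sharing != 0:
            raise ValueError("hue_sharing must be >= 1 and divide n_classes")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        bands = self.texture_bands()
        if len(bands) != self.n_classes:
            raise ValueError("texture_freq_band_per_class must have length n_classes")
        for lo, hi in bands:
            if not (0 < lo < hi <= 0.5):
                raise ValueError(
                    f"texture_freq_band_per_class band ({lo}, {hi}) must lie in (0, 0.5]"
                )
        if len(self.shape_families()) != self.n_classes:
            raise ValueError("shape_family_per_class must have length n_classes")

    def texture_bands(self) -> Tuple[Tuple[float, float], ...]:
        if self.texture_freq_band_per_class is not None:
            return tuple(tuple(b) for b in self.texture_freq_band_per_class)
        return _default_texture_bands(self.n_classes, self.hue_sharing)

    def shape_families(self) -> Tuple[str, ...]:
        if self.shape_family_per_class is not None:
            return tuple(self.shape_family_per_class)
        return _default_shape_families(self.n_classes, self.hue_sharing)

    def hue_centers_deg(self) -> np.ndarray:
        n_centers = self.n_classes // self.hue_sharing
        sep = self.hue_separation if self.hue_separation is not None else 360.0 / n_centers
        return ((np.arange(self.n_classes) // self.hue_sharing) * sep) % 360.0

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # resolved defaults recorded for documentation; ignored on load
        d["derived"] = {
            "texture_freq_band_per_class": [list(b) for b in self.texture_bands()],
            "shape_family_per_class": list(self.shape_families()),
            "hue_centers_deg": self.hue_centers_deg().tolist(),
        }
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticSetSpec":
        d = dict(d)
        d.pop("derived", None)
        if d.get("texture_freq_band_per_class") is not None:
            d["texture_freq_band_per_class"] = tuple(
                tuple(b) for b in d["texture_freq_band_per_class"]
            )
        if d.get("shape_family_per_class") is not None:
            d["shape_family_per_class"] = tuple(d["shape_family_per_class"])
        return cls(**d)


@dataclass
class LabeledImageSet:
    """A class-labeled raster collection for one train/test split."""

    images: List[np.ndarray]
    labels: List[int]
    split: str
    n_classes: int
    provenance: object = None

    def __post_init__(self):
        self.validate()

    def validate(self):
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have the same length")
        if self.split not in ("train", "test"):
            raise ValueError("split must be 'train' or 'test'")
        if self.images:
            shape = self.images[0].shape
            for im in self.images:
                if im.shape != shape:
                    raise ValueError("all rasters must share one shape")
                if im.min() < -1e-9 or im.max() > 1 + 1e-9:
                    raise ValueError("pixel values must lie in [0, 1]")
            present = set(self.labels)
            if present != set(range(self.n_classes)):
                missing = sorted(set(range(self.n_classes)) - present)
                raise ValueError(f"classes missing from split {self.split!r}: {missing}")

    def __len__(self):
        return len(self.images)

    def image_size(self) -> int:
        return self.images[0].shape[0]

    def with_images(self, images: Sequence[np.ndarray]) -> "LabeledImageSet":
        """Same labels/metadata with substituted rasters (e.g. degraded)."""
        return LabeledImageSet(
            images=list(images), labels=list(self.labels),
            split=self.split, n_classes=self.n_classes, provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# rendering

def _band_pass_noise(size: int, band: Tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Unit-variance white noise filtered to a radial frequency annulus."""
    noise = rng.standard_normal((size, size))
    f = np.fft.fftfreq(size)
    radius = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
    mask = (radius >= band[0]) & (radius <= band[1])
    spec = np.fft.fft2(noise) * mask
    tex = np.real(np.fft.ifft2(spec))
    sd = tex.std()
    return tex / sd if sd > 0 else tex


def _shape_mask(size: int, family: str, rng: np.random.Generator) -> np.ndarray:
    """Soft [0, 1] mask of a randomly placed/rotated/scaled shape."""
    cx = size * (0.5 + rng.uniform(-0.08, 0.08))
    cy = size * (0.5 + rng.uniform(-0.08, 0.08))
    r0 = size * rng.uniform(0.26, 0.36)
    rot = rng.uniform(0, 2 * np.pi)
    if family.startswith("polygon"):
        k = int(family[len("polygon"):])
        theta = rot + 2 * np.pi * np.arange(k) / k
        radii = np.full(k, r0)
    elif family == "blob":
        k = 64
        theta = rot + 2 * np.pi * np.arange(k) / k
        # low-order harmonic radial perturbation -> smooth irregular outline
        amps = rng.uniform(-0.15, 0.15, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        pert = sum(a * np.cos((j + 2) * theta + p) for j, (a, p) in enumerate(zip(amps, phases)))
        radii = r0 * (1 + pert)
    else:
        raise ValueError(f"unknown shape family: {family!r}")
    rows = cy + radii * np.sin(theta)
    cols = cx + radii * np.cos(theta)
    mask = np.zeros((size, size), dtype=np.float64)
    rr, cc = _draw_polygon(rows, cols, shape=(size, size))
    mask[rr, cc] = 1.0
    return ndimage.gaussian_filter(mask, 0.8)


def _render_image(
    spec: SyntheticSetSpec, class_idx: int, rng: np.random.Generator
) -> np.ndarray:
    size = spec.image_size
    hue = (spec.hue_centers_deg()[class_idx] + rng.uniform(-HUE_JITTER_DEG, HUE_JITTER_DEG)) % 360
    sat = np.clip(0.78 + rng.uniform(-SV_JITTER, SV_JITTER), 0, 1)
    val = np.clip(0.78 + rng.uniform(-SV_JITTER, SV_JITTER), 0, 1)
    base_rgb = _skcolor.hsv2rgb(np.array([[[hue / 360.0, sat, val]]]))[0, 0]

    mask = _shape_mask(size, spec.shape_families()[class_idx], rng)
    tex = _band_pass_noise(size, spec.texture_bands()[class_idx], rng)
    shading = np.clip(1.0 + TEXTURE_AMPLITUDE * tex, 0.0, 2.0)
    shape_rgb = base_rgb[None, None, :] * shading[:, :, None]

    img = 0.5 * (1.0 - mask[:, :, None]) + shape_rgb * mask[:, :, None]
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(spec: SyntheticSetSpec) -> Tuple[LabeledImageSet, LabeledImageSet]:
    """Render deterministic train and test splits for a spec.

    Both splits come from the same generative process with disjoint random
    draws; equal specs (including seed) yield bitwise-equal datasets.
    """
    train_ss, test_ss = np.random.SeedSequence(spec.seed).spawn(2)
    sets = []
    for split, per_class, ss in (
        ("train", spec.train_per_class, train_ss),
        ("test", spec.test_per_class, test_ss),
    ):
        rng = np.random.default_rng(ss)
        images, labels = [], []
        for c in range(spec.n_classes):
            for _ in range(per_class):
                images.append(_render_image(spec, c, rng))
                labels.append(c)
        sets.append(
            LabeledImageSet(
                images=images, labels=labels, split=split,
                n_classes=spec.n_classes, provenance=spec,
            )
        )
    return sets[0], sets[1]


# ---------------------------------------------------------------------------
# cue diagnostics

def _chroma_vector(image: np.ndarray) -> np.ndarray:
    """Mean saturation-weighted hue direction (2-vector); ~0 for
    achromatic images."""
    hsv = _skcolor.rgb2hsv(image)
    h = hsv[:, :, 0] * 2 * np.pi
    s = hsv[:, :, 1]
    return np.array([np.mean(s * np.cos(h)), np.mean(s * np.sin(h))])


def _texture_centroid(image: np.ndarray) -> float:
    """Power-weighted mean radial frequency of the mean-removed luminance
    spectrum (cycles/pixel)."""
    luma = image @ LUMA_WEIGHTS
    luma = luma - luma.mean()
    spec = np.abs(np.fft.fft2(luma)) ** 2
    size = luma.shape[0]
    f = np.fft.fftfreq(size)
    radius = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
    nondc = radius > 0
    total = spec[nondc].sum()
    if total == 0:
        return 0.0
    return float((spec[nondc] * radius[nondc]).sum() / total)


def cue_diagnostics(image_set: LabeledImageSet) -> dict:
    """Quantify how class-separated the two removable cue families are.

    Returns per-class mean hue (degrees, saturation-weighted circular
    mean), per-class texture-band energy centroids (cycles/pixel), and two
    scalar separations: ``chromatic_separation`` (mean pairwise distance
    between class chroma vectors; 0 for achromatic sets) and
    ``texture_separation`` (mean pairwise distance between class spectral
    centroids).  Single-class sets get ``separation_defined=False``.
    """
    if len(image_set) == 0:
        raise ValueError("cue_diagnostics requires a non-empty set")
    n = image_set.n_classes
    chroma = np.zeros((n, 2))
    centroid = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for img, lab in zip(image_set.images, image_set.labels):
        chroma[lab] += _chroma_vector(img)
        centroid[lab] += _texture_centroid(img)
        counts[lab] += 1
    chroma /= counts[:, None]
    centroid /= counts
    hue_deg = (np.degrees(np.arctan2(chroma[:, 1], chroma[:, 0]))) % 360.0

    report = {
        "n_classes": n,
        "class_mean_hue_deg": hue_deg.tolist(),
        "class_chroma_vectors": chroma.tolist(),
        "class_texture_centroid": centroid.tolist(),
        "separation_defined": n >= 2,
    }
    if n >= 2:
        iu = np.triu_indices(n, k=1)
        dch = np.linalg.norm(chroma[:, None, :] - chroma[None, :, :], axis=2)
        dtx = np.abs(centroid[:, None] - centroid[None, :])
        report["chromatic_separation"] = float(dch[iu].mean())
        report["texture_separation"] = float(dtx[iu].mean())
    else:
        report["chromatic_separation"] = None
        report["texture_separation"] = None
    return report


# ---------------------------------------------------------------------------
# persistence

def save_imageset(sets: Sequence[LabeledImageSet], out_dir) -> Path:
    """Persist splits as one PNG per image plus ``manifest.csv``
    (columns filename, label, split) and a ``spec.json`` sidecar when the
    provenance is a :class:`SyntheticSetSpec`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sets:
        for i, (img, lab) in enumerate(zip(s.images, s.labels)):
            fname = f"{s.split}_{i:05d}.png"
            arr = np.clip(np.round(np.asarray(img) * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(out_dir / fname)
            rows.append({"filename": fname, "label": lab, "split": s.split})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    spec = sets[0].provenance if sets else None
    if isinstance(spec, SyntheticSetSpec):
        (out_dir / "spec.json").write_text(json.dumps(spec.to_json_dict(), indent=2))
    return out_dir


def load_imageset(directory, split: str) -> LabeledImageSet:
    """Load one split from any directory obeying the manifest schema
    (synthetic or user-supplied PNG/JPEG images)."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    sub = manifest[manifest["split"] == split]
    if sub.empty:
        raise ValueError(f"manifest contains no rows for split {split!r}")
    images, labels = [], []
    for _, row in sub.iterrows():
        with Image.open(directory / row["filename"]) as im:
            arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
        images.append(arr)
        labels.append(int(row["label"]))
    n_classes = int(manifest["label"].max()) + 1
    spec_path = directory / "spec.json"
    provenance = str(directory)
    if spec_path.exists():
        provenance = SyntheticSetSpec.from_json_dict(json.loads(spec_path.read_text()))
    return LabeledImageSet(
        images=images, labels=labels, split=split,
        n_classes=n_classes, provenance=provenance,
    )
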