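"""Synthetic tongue-scene generator.

Real tongue photographs (a clinic-collected set and the public BioHit set)
cannot ship with the package, so every downstream stage is exercised on
rendered scenes that mimic their structure: a tongue-like silhouette whose
width separates the three shape classes (thin / normal / bulgy), a crescent
"lip" band of similar hue hugging the upper tongue boundary (the distractor
that makes lip-touching tongues easy to misclassify as bulgy), a pixel-exact
binary mask of the tongue only, and multiplicative texture plus additive
Gaussian noise on the image (never the mask).

The silhouette is a rotated ellipse whose lower half is stretched by a
``droop`` factor, giving the hanging-tongue outline. Default class width
ratios are 0.35 / 0.55 / 0.80 of the image width with +/-5% jitter, so mask
area and aspect ratio separate the classes linearly — the property the
classification benchmark relies on.

Everything is deterministic: a scene's seed fully determines its pixels, and
dataset sample seeds derive from the master seed as ``seed * 10**6 + index``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .errors import ParameterError

__all__ = [
    "ShapeParams", "SceneParams", "LabelledSample",
    "make_sample", "make_dataset", "write_dataset",
    "CLASS_NAMES", "DEFAULT_WIDTH_RATIOS", "CLINIC_PROPORTIONS",
]

CLASS_NAMES = ("thin", "normal", "bulgy")
DEFAULT_WIDTH_RATIOS = (0.35, 0.55, 0.80)
# clinic-like class proportions (thin : bulgy : normal = 253 : 331 : 226)
CLINIC_PROPORTIONS = {"thin": 253, "bulgy": 331, "normal": 226}

# base colours (RGB in [0,1])
_TONGUE_RGB = np.array([0.78, 0.35, 0.38])
_LIP_RGB = np.array([0.72, 0.45, 0.42])
_SKIN_RGB = np.array([0.85, 0.68, 0.58])


@dataclass
class ShapeParams:
    class_id: int                      # 0=thin, 1=normal, 2=bulgy
    center: tuple                      # (row, col) pixels
    half_width: float                  # pixels
    half_height: float                 # pixels
    droop: float = 0.35                # lower-boundary stretch, dimensionless
    rotation: float = 0.0              # degrees


@dataclass
class SceneParams:
    image_size: int = 224
    lip_thickness: float = 10.0        # pixels
    lip_contact: bool = True
    lip_similarity: float = 0.5        # 0 = distinct hue, 1 = tongue hue
    texture_scale: float = 0.15        # multiplicative texture amplitude
    noise_sd: float = 4.0              # additive noise, 8-bit intensity units
    seed: int = 0


@dataclass
class LabelledSample:
    id: str
    image: np.ndarray                  # (H, W, 3) uint8
    mask: np.ndarray | None            # (H, W) in {0,1}, uint8
    label: int | None                  # class id


def _signed_radius(shape: ShapeParams, size: int) -> np.ndarray:
    """Normalized radial coordinate r: the silhouette is r <= 1."""
    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)
    dy = rows - shape.center[0]
    dx = cols - shape.center[1]
    theta = np.deg2rad(shape.rotation)
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    # stretch the lower half by the droop factor
    v = np.where(v > 0, v / (1.0 + shape.droop), v)
    return np.sqrt((u / shape.half_width) ** 2 + (v / shape.half_height) ** 2)


def _check_in_frame(shape: ShapeParams, size: int) -> None:
    reach = max(shape.half_width, shape.half_height * (1.0 + shape.droop)) + 1.0
    r0, c0 = shape.center
    if (r0 - reach < 0 or c0 - reach < 0
            or r0 + reach >= size or c0 + reach >= size):
        raise ParameterError(
            f"shape (center={shape.center}, half_width={shape.half_width:.1f}, "
            f"half_height={shape.half_height:.1f}) exceeds the {size}x{size} frame")


def _smooth_noise(rng: np.random.Generator, size: int, cells: int = 8) -> np.ndarray:
    """Smooth zero-mean field in [-1,1]: bilinear upsampling of coarse noise."""
    coarse = rng.uniform(-1.0, 1.0, (cells + 1, cells + 1))
    idx = np.linspace(0, cells, size)
    i0 = np.clip(idx.astype(int), 0, cells - 1)
    f = idx - i0
    rows = coarse[i0][:, i0] * np.outer(1 - f, 1 - f) \
        + coarse[i0 + 1][:, i0] * np.outer(f, 1 - f) \
        + coarse[i0][:, i0 + 1] * np.outer(1 - f, f) \
        + coarse[i0 + 1][:, i0 + 1] * np.outer(f, f)
    return rows


def make_sample(shape: ShapeParams, scene: SceneParams,
                sample_id: str = "sample") -> LabelledSample:
    """Render one scene: RGB image, exact binary tongue mask, class label."""
    size = scene.image_size
    if size < 32:
        raise ParameterError(f"image_size must be >= 32, got {size}")
    _check_in_frame(shape, size)
    rng = np.random.default_rng(scene.seed)

    r = _signed_radius(shape, size)
    mask = (r <= 1.0)

    # lip: a crescent band around/above the tongue, outside the mask
    gap = 0.0 if scene.lip_contact else 0.08
    lip_rel = scene.lip_thickness / max(shape.half_height, 1.0)
    rows = np.mgrid[0:size, 0:size][0]
    above = rows <= shape.center[0] + 0.35 * shape.half_height
    lip = (r > 1.0 + gap) & (r <= 1.0 + gap + lip_rel) & above & ~mask

    lip_rgb = (1 - scene.lip_similarity) * _LIP_RGB + scene.lip_similarity * _TONGUE_RGB
    img = np.empty((size, size, 3), dtype=np.float64)
    img[:] = _SKIN_RGB
    img[mask] = _TONGUE_RGB
    img[lip] = lip_rgb

    if scene.texture_scale:
        texture = 1.0 + scene.texture_scale * _smooth_noise(rng, size)
        img *= texture[..., None]
    img = img * 255.0
    if scene.noise_sd:
        img += rng.normal(0.0, scene.noise_sd, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return LabelledSample(id=sample_id, image=img,
                          mask=mask.astype(np.uint8), label=shape.class_id)


def _shape_for_class(class_id: int, size: int, rng: np.random.Generator,
                     width_ratios=DEFAULT_WIDTH_RATIOS) -> ShapeParams:
    ratio = width_ratios[class_id] * rng.uniform(0.95, 1.05)   # +/-5% jitter
    half_width = ratio * size / 2.0
    half_height = size * rng.uniform(0.26, 0.30)
    droop = rng.uniform(0.25, 0.45)
    rotation = rng.uniform(-8.0, 8.0)
    margin = max(half_width, half_height * (1.0 + droop)) + 2.0
    lo, hi = margin, size - 1 - margin
    if lo >= hi:
        raise ParameterError(
            f"class {class_id} shape does not fit a {size}x{size} frame")
    center = (rng.uniform(lo, min(hi, size * 0.55)), rng.uniform(lo, hi))
    return ShapeParams(class_id=class_id, center=center, half_width=half_width,
                       half_height=half_height, droop=droop, rotation=rotation)


def make_dataset(n_per_class: int, scene: SceneParams,
                 class_margins=DEFAULT_WIDTH_RATIOS,
                 imbalance: dict | None = None) -> list[LabelledSample]:
    """Render a balanced (or clinic-proportioned) labelled dataset.

    Per-sample seeds are ``scene.seed * 10**6 + index`` so manifests are
    reproducible without storing seeds.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    if imbalance:
        total = 3 * n_per_class
        weight_sum = sum(imbalance.values())
        counts = {CLASS_NAMES.index(k): max(1, round(total * v / weight_sum))
                  for k, v in imbalance.items()}
    else:
        counts = {c: n_per_class for c in range(3)}
    samples: list[LabelledSample] = []
    index = 0
    for class_id in range(3):
        for _ in range(counts[class_id]):
            sample_seed = scene.seed * 10 ** 6 + index
            srng = np.random.default_rng(sample_seed)
            shape = _shape_for_class(class_id, scene.image_size, srng, class_margins)
            s = make_sample(shape, replace(scene, seed=sample_seed),
                            sample_id=f"s{index:04d}_{CLASS_NAMES[class_id]}")
            samples.append(s)
            index += 1
    return samples


def write_dataset(samples: list[LabelledSample], out_dir, scene: SceneParams,
                  extra_manifest: dict | None = None) -> None:
    """Write images/<id>.png, masks/<id>.png, labels.csv and manifest.yaml."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        Image.fromarray(s.image).save(out / "images" / f"{s.id}.png")
        if s.mask is not None:
            Image.fromarray((s.mask * 255).astype(np.uint8)).save(
                out / "masks" / f"{s.id}.png")
        if s.label is not None:
            rows.append({"id": s.id, "class_name": CLASS_NAMES[s.label],
                         "class_id": s.label})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)
    manifest = {"generator": asdict(scene), "n_samples": len(samples)}
    manifest.update(extra_manifest or {})
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
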