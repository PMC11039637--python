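"""Seeded generator of dermoscopy-like images with ground-truth masks.

Emulates the visual regime of dermoscopic lesion photographs at desk scale:
a roughly elliptical, darker, irregular-border lesion occupying a
controllable fraction of a lighter textured skin background, optionally
overlaid with dark curvilinear hair strokes, impulse ("salt and pepper")
noise and multiplicative speckle noise.

The generator is a pure function of ``(spec, seed)``.  Independent random
streams are spawned for the background/lesion composite, the hair strokes
and the noise, so two specs that differ only in ``hair_count`` produce
pixel rasters that are identical everywhere except under the hairs — the
paired-twin oracle the hair-removal tests rely on.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .exceptions import ValidationError
from .image import LabeledImage

__all__ = ["LesionSpec", "generate_lesion", "generate_dataset", "write_dataset", "read_manifest"]

_SKIN_TONE = np.array([205.0, 160.0, 140.0])
_LESION_TONE = np.array([95.0, 60.0, 55.0])


@dataclass(frozen=True)
class LesionSpec:
    """Parameters of one synthetic dermoscopy image."""

    height: int = 64
    width: int = 64
    foreground_fraction: float = 0.20
    hair_count: int = 0
    impulse_noise_prob: float = 0.0
    speckle_variance: float = 0.0
    class_id: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.height < 16:
            raise ValidationError(f"height must be >= 16, got {self.height}")
        if self.width < 16:
            raise ValidationError(f"width must be >= 16, got {self.width}")
        if not 0.0 < self.foreground_fraction < 1.0:
            raise ValidationError(
                f"foreground_fraction must be in (0,1), got {self.foreground_fraction}"
            )
        if self.hair_count < 0:
            raise ValidationError(f"hair_count must be >= 0, got {self.hair_count}")
        if not 0.0 <= self.impulse_noise_prob < 1.0:
            raise ValidationError(
                f"impulse_noise_prob must be in [0,1), got {self.impulse_noise_prob}"
            )
        if self.speckle_variance < 0.0:
            raise ValidationError(
                f"speckle_variance must be >= 0, got {self.speckle_variance}"
            )


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean low-frequency field, unit-ish amplitude."""
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    scale = np.abs(field).max()
    return field / scale if scale > 0 else field


def _lesion_mask(rng: np.random.Generator, h: int, w: int, fraction: float) -> np.ndarray:
    """Ellipse with low-frequency radial perturbation, area-corrected to the target."""
    target = fraction * h * w
    cy = h / 2.0 + rng.uniform(-0.08, 0.08) * h
    cx = w / 2.0 + rng.uniform(-0.08, 0.08) * w
    q = rng.uniform(0.6, 1.0)                       # axis ratio b/a
    theta0 = rng.uniform(0, np.pi)
    # radial wobble: a few random Fourier modes
    n_modes = 4
    amps = rng.uniform(0.03, 0.08, n_modes)
    phases = rng.uniform(0, 2 * np.pi, n_modes)

    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta0), np.sin(theta0)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    ang = np.arctan2(v, u)
    wobble = np.zeros_like(ang)
    for m, (a, p) in enumerate(zip(amps, phases), start=2):
        wobble += a * np.cos(m * ang + p)

    a_axis = np.sqrt(target / (np.pi * q))
    for _ in range(6):
        b_axis = q * a_axis
        r = np.sqrt((u / a_axis) ** 2 + (v / b_axis) ** 2)
        mask = r <= 1.0 + wobble
        area = mask.sum()
        if area == 0:
            a_axis *= 1.5
            continue
        ratio = area / target
        if abs(ratio - 1.0) <= 0.05:
            break
        a_axis /= np.sqrt(ratio)
    return mask.astype(np.uint8)


def _draw_hairs(rng: np.random.Generator, pixels: np.ndarray, count: int) -> None:
    """Overlay dark cubic-Bezier strokes 1-3 px wide, intensity <= 60."""
    h, w = pixels.shape[:2]
    for _ in range(count):
        pts = rng.uniform([-0.2 * h, -0.2 * w], [1.2 * h, 1.2 * w], size=(4, 2))
        t = np.linspace(0.0, 1.0, 4 * (h + w))[:, None]
        curve = ((1 - t) ** 3 * pts[0] + 3 * (1 - t) ** 2 * t * pts[1]
                 + 3 * (1 - t) * t ** 2 * pts[2] + t ** 3 * pts[3])
        ij = np.round(curve).astype(int)
        keep = (ij[:, 0] >= 0) & (ij[:, 0] < h) & (ij[:, 1] >= 0) & (ij[:, 1] < w)
        ij = ij[keep]
        if ij.size == 0:
            continue
        stroke = np.zeros((h, w), dtype=bool)
        stroke[ij[:, 0], ij[:, 1]] = True
        width = int(rng.integers(1, 4))
        if width > 1:
            stroke = ndimage.binary_dilation(stroke, iterations=width - 1)
        shade = rng.uniform(15.0, 60.0)
        pixels[stroke] = shade + rng.normal(0.0, 3.0, size=(int(stroke.sum()), 1))


def generate_lesion(spec: LesionSpec) -> LabeledImage:
    """Render one image/mask pair from ``spec`` (bit-reproducible per seed)."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_scene, rng_hair, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    h, w = spec.height, spec.width
    # textured skin background with a gentle illumination gradient
    base = _SKIN_TONE + rng_scene.uniform(-15, 15, 3)
    grad = np.linspace(-1, 1, w)[None, :] * rng_scene.uniform(-8, 8)
    texture = _smooth_noise(rng_scene, (h, w), sigma=3.0) * 12.0
    pixels = base[None, None, :] + (grad + texture)[:, :, None]
    pixels += rng_scene.normal(0.0, 2.0, (h, w, 3))

    mask = _lesion_mask(rng_scene, h, w, spec.foreground_fraction)
    lesion = _LESION_TONE + rng_scene.uniform(-15, 15, 3)
    lesion_tex = _smooth_noise(rng_scene, (h, w), sigma=2.0) * 10.0
    # soft interior blend keeps borders irregular but the mask stays crisp
    soft = ndimage.gaussian_filter(mask.astype(float), 1.0)
    blend = np.where(mask, np.clip(0.7 + 0.3 * soft, 0, 1), 0.0)
    lesion_img = lesion[None, None, :] + lesion_tex[:, :, None]
    pixels = pixels * (1 - blend[:, :, None]) + lesion_img * blend[:, :, None]

    if spec.hair_count:
        _draw_hairs(rng_hair, pixels, spec.hair_count)

    if spec.speckle_variance > 0:
        pixels = pixels * (1.0 + rng_noise.normal(0.0, np.sqrt(spec.speckle_variance), (h, w, 1)))
    if spec.impulse_noise_prob > 0:
        u = rng_noise.random((h, w))
        salt = u < spec.impulse_noise_prob / 2
        pepper = (u >= spec.impulse_noise_prob / 2) & (u < spec.impulse_noise_prob)
        pixels[salt] = 255.0
        pixels[pepper] = 0.0

    pixels = np.clip(pixels, 0, 255).astype(np.uint8)
    return LabeledImage(pixels=pixels, mask=mask, label=spec.class_id,
                        meta={"seed": spec.seed})


def generate_dataset(n: int, specs: Sequence[LesionSpec], seed: int) -> List[LabeledImage]:
    """``n`` images cycling through ``specs``; per-image seeds spawn from ``seed``."""
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if not specs:
        raise ValidationError("specs must be a non-empty list")
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    images = []
    for i in range(n):
        spec = replace(specs[i % len(specs)], seed=int(child_seeds[i]))
        images.append(generate_lesion(spec))
    return images


def write_dataset(images: Sequence[LabeledImage], out_dir: str | Path,
                  stem_prefix: str = "lesion") -> Path:
    """Write ``<stem>.png`` / ``<stem>_mask.png`` pairs plus a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "mask_path", "label", "seed"])
        for i, img in enumerate(images):
            stem = f"{stem_prefix}_{i:04d}"
            iio.imwrite(out / f"{stem}.png", np.asarray(img.pixels, dtype=np.uint8))
            mask_path = ""
            if img.mask is not None:
                mask_path = f"{stem}_mask.png"
                iio.imwrite(out / mask_path, (img.mask * 255).astype(np.uint8))
            writer.writerow([f"{stem}.png", mask_path,
                             "" if img.label is None else img.label,
                             img.meta.get("seed", "")])
    return manifest


def read_manifest(manifest: str | Path) -> List[LabeledImage]:
    """Load a dataset previously written by :func:`write_dataset`."""
    manifest = Path(manifest)
    root = manifest.parent
    images = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            pixels = iio.imread(root / row["path"])
            mask: Optional[np.ndarray] = None
            if row["mask_path"]:
                mask = (iio.imread(root / row["mask_path"]) > 127).astype(np.uint8)
            label = int(row["label"]) if row["label"] else None
            meta = {"seed": int(row["seed"])} if row["seed"] else {}
            images.append(LabeledImage(pixels=pixels, mask=mask, label=label, meta=meta))
    return images
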