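"""The preprocessing stack: resize, color conversion, contrast enhancement,
denoising and thick-hair removal.

The default pipeline order is
``resize -> color convert -> hair removal -> adaptive median -> adaptive
local -> equalize``.  Every operation preserves the ``[0, 255]`` intensity
range and never alters mask values (resize resamples the mask with
nearest-neighbour and re-thresholds it to ``{0, 1}``).

Standard image primitives are delegated to scikit-image/scipy; the adaptive
median filter is implemented here because no installed library provides the
classical variable-window (stage A / stage B) algorithm.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import exposure, filters, morphology
from skimage import transform as sktransform
from skimage.restoration import inpaint_biharmonic

from .exceptions import ValidationError
from .image import LabeledImage

__all__ = [
    "PreprocessConfig", "resize_bilinear", "convert_color_space", "to_rgb",
    "equalize_adaptive", "filter_adaptive_median", "filter_adaptive_local",
    "remove_hairs", "hair_mask", "run_pipeline", "DEFAULT_ORDER",
]

SUPPORTED_SPACES = ("RGB", "HSV", "GRAY", "LAB")
DEFAULT_ORDER = ("resize", "color", "hairs", "median", "local", "equalize")


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable knobs of the preprocessing stack.

    ``local_noise_variance=None`` means "auto": the noise power is estimated
    as the median of the local variances, a robust proxy for stationary
    sensor noise on mostly-smooth skin.
    """

    target_height: int = 128
    target_width: int = 128
    color_space: str = "RGB"
    clahe_clip_limit: float = 2.0
    median_max_window: int = 7
    local_noise_variance: Optional[float] = None
    hair_kernel_length: int = 9
    hair_threshold: float = 40.0
    local_window: int = 7
    median_impulse_tolerance: float = 16.0

    def validate(self) -> None:
        if self.target_height < 16 or self.target_width < 16:
            raise ValidationError(
                f"target dimensions must be >= 16, got "
                f"{self.target_height}x{self.target_width}"
            )
        if self.median_max_window < 3 or self.median_max_window % 2 == 0:
            raise ValidationError(
                f"median_max_window must be an odd integer >= 3, got {self.median_max_window}"
            )
        if self.color_space not in SUPPORTED_SPACES:
            raise ValidationError(
                f"color_space must be one of {SUPPORTED_SPACES}, got {self.color_space!r}"
            )
        if self.clahe_clip_limit < 0:
            raise ValidationError("clahe_clip_limit must be >= 0")
        if self.local_noise_variance is not None and self.local_noise_variance < 0:
            raise ValidationError("local_noise_variance must be >= 0 or None (auto)")
        if self.hair_kernel_length < 3:
            raise ValidationError(
                f"hair_kernel_length must be >= 3, got {self.hair_kernel_length}"
            )


def resize_bilinear(image: LabeledImage, cfg: PreprocessConfig) -> LabeledImage:
    """Bilinear pixel resampling; nearest-neighbour for the mask."""
    cfg.validate()
    shape = (cfg.target_height, cfg.target_width)
    if (image.height, image.width) == shape:
        return image.copy()
    out = sktransform.resize(image.pixels.astype(np.float64), shape, order=1,
                             preserve_range=True, anti_aliasing=False)
    mask = None
    if image.mask is not None:
        m = sktransform.resize(image.mask.astype(np.float64), shape, order=0,
                               preserve_range=True, anti_aliasing=False)
        mask = (m > 0.5).astype(np.uint8)
    return LabeledImage(pixels=np.clip(out, 0, 255).astype(image.pixels.dtype),
                        mask=mask, label=image.label,
                        color_space=image.color_space, meta=dict(image.meta))


def convert_color_space(image: LabeledImage, space: str) -> LabeledImage:
    """Standard color transform from RGB.

    Output ranges follow the conventions of the named transform: RGB and
    GRAY stay in ``[0, 255]``; HSV channels are proportions in ``[0, 1]``;
    LAB uses the CIE ranges (L in ``[0, 100]``).
    """
    if space not in SUPPORTED_SPACES:
        raise ValidationError(
            f"unknown color space {space!r}; supported: {SUPPORTED_SPACES}"
        )
    if image.color_space != "RGB":
        raise ValidationError(f"input must be RGB, got {image.color_space}")
    if space == "RGB":
        return image.copy()
    rgb = image.pixels.astype(np.float64) / 255.0
    if space == "HSV":
        out = skcolor.rgb2hsv(rgb)
    elif space == "LAB":
        out = skcolor.rgb2lab(rgb)
    else:  # GRAY
        out = skcolor.rgb2gray(rgb) * 255.0
    return image.with_pixels(out.astype(np.float32), color_space=space)


def to_rgb(image: LabeledImage) -> LabeledImage:
    """Inverse transform back to uint8 RGB (GRAY is replicated to 3 channels)."""
    if image.color_space == "RGB":
        return image.copy()
    px = image.pixels.astype(np.float64)
    if image.color_space == "HSV":
        rgb = skcolor.hsv2rgb(px) * 255.0
    elif image.color_space == "LAB":
        rgb = skcolor.lab2rgb(px) * 255.0
    else:  # GRAY
        rgb = np.repeat(px[:, :, None], 3, axis=2)
    return image.with_pixels(np.clip(np.round(rgb), 0, 255).astype(np.uint8),
                             color_space="RGB")


def _luminance_apply(image: LabeledImage, fn) -> LabeledImage:
    """Apply ``fn`` (on a [0,1] luminance plane) to the V channel of HSV for
    color images, or directly for single-channel images."""
    px = image.pixels.astype(np.float64)
    if image.channels == 1:
        plane = px / 255.0
        out = np.clip(fn(np.clip(plane, 0, 1)), 0, 1) * 255.0
        return image.with_pixels(out.astype(image.pixels.dtype)
                                 if np.issubdtype(image.pixels.dtype, np.integer)
                                 else out.astype(np.float32))
    hsv = skcolor.rgb2hsv(px / 255.0)
    hsv[:, :, 2] = np.clip(fn(hsv[:, :, 2]), 0, 1)
    rgb = np.clip(skcolor.hsv2rgb(hsv) * 255.0, 0, 255)
    return image.with_pixels(np.round(rgb).astype(np.uint8))


def equalize_adaptive(image: LabeledImage, cfg: PreprocessConfig) -> LabeledImage:
    """Contrast-limited adaptive histogram equalisation on the luminance only.

    ``clahe_clip_limit`` follows the familiar OpenCV-style scale (default
    2.0) and is mapped onto scikit-image's fractional clip limit
    (``clip_limit / 100``).
    """
    cfg.validate()
    clip = max(cfg.clahe_clip_limit / 100.0, 1e-4)

    def _clahe(plane: np.ndarray) -> np.ndarray:
        if plane.max() - plane.min() < 1e-6:
            return plane  # constant image: nothing to equalise
        return exposure.equalize_adapthist(plane, clip_limit=clip)

    return _luminance_apply(image, _clahe)


def _channels(px: np.ndarray) -> list[np.ndarray]:
    if px.ndim == 2:
        return [px]
    return [px[:, :, c] for c in range(px.shape[2])]


def _stack_like(planes: list[np.ndarray], px: np.ndarray) -> np.ndarray:
    out = planes[0] if px.ndim == 2 else np.stack(planes, axis=2)
    if np.issubdtype(px.dtype, np.integer):
        out = np.clip(np.round(out), 0, 255)
    return out.astype(px.dtype)


def _adaptive_median_plane(plane: np.ndarray, max_window: int,
                           tolerance: float) -> np.ndarray:
    """Classical adaptive median (stage A grows the window, stage B replaces
    only impulsive pixels).

    A pixel is impulsive when it sits at a strict extreme of its window *and*
    deviates from the window median by more than ``tolerance`` intensity
    levels; the deviation guard keeps ordinary texture extremes (which every
    natural image has) untouched, so an impulse-free image passes through
    unchanged.
    """
    out = plane.astype(np.float64).copy()
    undecided = np.ones(plane.shape, dtype=bool)
    x = plane.astype(np.float64)
    med = None
    for win in range(3, max_window + 1, 2):
        med = ndimage.median_filter(x, size=win, mode="reflect")
        mn = ndimage.minimum_filter(x, size=win, mode="reflect")
        mx = ndimage.maximum_filter(x, size=win, mode="reflect")
        stage_a = (med > mn) & (med < mx)            # window holds a valid median
        decide = undecided & stage_a
        extreme = ~((x > mn) & (x < mx))             # stage B: pixel is an extreme
        impulsive = decide & extreme & (np.abs(x - med) > tolerance)
        out[impulsive] = med[impulsive]
        undecided &= ~decide
        if not undecided.any():
            break
    if undecided.any() and med is not None:
        med = ndimage.median_filter(x, size=max_window, mode="reflect")
        replace_ = undecided & (np.abs(x - med) > tolerance)
        out[replace_] = med[replace_]
    return out


def filter_adaptive_median(image: LabeledImage, cfg: PreprocessConfig) -> LabeledImage:
    """Adaptive median filter: replaces only pixels judged impulsive."""
    cfg.validate()
    px = image.pixels
    planes = [_adaptive_median_plane(p, cfg.median_max_window,
                                     cfg.median_impulse_tolerance)
              for p in _channels(px)]
    return image.with_pixels(_stack_like(planes, px))


def _adaptive_local_plane(plane: np.ndarray, window: int,
                          noise_var: Optional[float]) -> np.ndarray:
    x = plane.astype(np.float64)
    mean = ndimage.uniform_filter(x, size=window, mode="reflect")
    sq = ndimage.uniform_filter(x * x, size=window, mode="reflect")
    var = np.maximum(sq - mean * mean, 0.0)
    nv = float(np.median(var)) if noise_var is None else float(noise_var)
    if nv == 0.0:
        return x
    ratio = np.clip(nv / np.maximum(var, 1e-12), 0.0, 1.0)
    return x - ratio * (x - mean)


def filter_adaptive_local(image: LabeledImage, cfg: PreprocessConfig) -> LabeledImage:
    """Adaptive local noise-reduction filter.

    ``out = x - (noise_var / local_var) * (x - local_mean)`` with the ratio
    clipped to ``[0, 1]``; reduces to the identity when the noise power is
    zero and to the local mean wherever ``local_var == noise_var``.
    """
    cfg.validate()
    px = image.pixels
    planes = [_adaptive_local_plane(p, cfg.local_window, cfg.local_noise_variance)
              for p in _channels(px)]
    return image.with_pixels(_stack_like(planes, px))


def _line_selem(length: int, angle_deg: float) -> np.ndarray:
    """Linear structuring element of the given length and orientation."""
    theta = np.deg2rad(angle_deg)
    half = (length - 1) / 2.0
    t = np.linspace(-half, half, 2 * length)
    ys = np.round(t * np.sin(theta)).astype(int)
    xs = np.round(t * np.cos(theta)).astype(int)
    size = length if length % 2 else length + 1
    sel = np.zeros((size, size), dtype=bool)
    c = size // 2
    keep = (np.abs(ys) <= c) & (np.abs(xs) <= c)
    sel[ys[keep] + c, xs[keep] + c] = True
    return sel


def hair_mask(image: LabeledImage, cfg: PreprocessConfig,
              threshold: Optional[float] = None) -> np.ndarray:
    """Dark curvilinear structure detector.

    Maximum morphological black-hat over a bank of oriented linear
    structuring elements flags thin dark structures; the lesion body itself
    (the large dark blob found by Otsu thresholding, opened to drop thin
    structures and dilated to cover its border fringe) is excluded so border
    concavities are never mistaken for hairs.
    """
    cfg.validate()
    if threshold is None:
        threshold = cfg.hair_threshold
    px = image.pixels.astype(np.float64)
    gray = skcolor.rgb2gray(px / 255.0) * 255.0 if image.channels == 3 else px
    response = np.zeros_like(gray)
    for angle in (0, 30, 60, 90, 120, 150):
        sel = _line_selem(cfg.hair_kernel_length, angle)
        closed = morphology.closing(gray, sel)
        response = np.maximum(response, closed - gray)
    dark = gray < filters.threshold_otsu(gray)
    blob = morphology.opening(dark, morphology.disk(3))
    blob = morphology.dilation(blob, morphology.disk(2))
    mask = (response > threshold) & ~blob
    if mask.any():
        mask = ndimage.binary_dilation(mask, iterations=1)
    return mask


def remove_hairs(image: LabeledImage, cfg: PreprocessConfig) -> LabeledImage:
    """Black-hat hair detection followed by biharmonic inpainting (the
    DullRazor-style approach); mask and label are untouched."""
    mask = hair_mask(image, cfg)
    if not mask.any():
        return image.copy()
    px = image.pixels.astype(np.float64) / 255.0
    kwargs = {"channel_axis": 2} if image.channels == 3 else {}
    filled = inpaint_biharmonic(px, mask, **kwargs)
    out = np.clip(filled * 255.0, 0, 255)
    if np.issubdtype(image.pixels.dtype, np.integer):
        out = np.round(out)
    return image.with_pixels(out.astype(image.pixels.dtype))


_STAGES = {
    "resize": resize_bilinear,
    "hairs": remove_hairs,
    "median": filter_adaptive_median,
    "local": filter_adaptive_local,
    "equalize": equalize_adaptive,
}


def run_pipeline(image: LabeledImage, cfg: PreprocessConfig,
                 order: Sequence[str] = DEFAULT_ORDER) -> LabeledImage:
    """Apply the configured stages in order (see module docstring)."""
    cfg.validate()
    out = image
    for stage in order:
        if stage == "color":
            out = convert_color_space(out, cfg.color_space)
        elif stage in _STAGES:
            out = _STAGES[stage](out, cfg)
        else:
            raise ValidationError(f"unknown pipeline stage {stage!r}")
    return out
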