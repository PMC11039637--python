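"""The in-memory raster container shared by every stage of the pipeline.

A :class:`LabeledImage` couples an ``H x W x 3`` (or ``H x W``) pixel raster
with an optional binary lesion mask and an optional integer class label.  RGB
rasters are kept in the conventional ``[0, 255]`` range; non-RGB color spaces
carry whatever range the standard transform defines (see
:func:`lesionforge.preprocess.convert_color_space`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import ValidationError

__all__ = ["LabeledImage"]


@dataclass
class LabeledImage:
    pixels: np.ndarray
    mask: Optional[np.ndarray] = None
    label: Optional[int] = None
    color_space: str = "RGB"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValidationError(
                f"pixels must be H x W or H x W x C, got shape {self.pixels.shape}"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.pixels.shape[:2]:
                raise ValidationError(
                    f"mask shape {self.mask.shape} does not match pixel grid "
                    f"{self.pixels.shape[:2]}"
                )
            vals = np.unique(self.mask)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValidationError(f"mask values must be in {{0,1}}, got {vals[:8]}")
            self.mask = self.mask.astype(np.uint8)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else int(self.pixels.shape[2])

    def with_pixels(self, pixels: np.ndarray, color_space: Optional[str] = None) -> "LabeledImage":
        """Copy of this image with new pixels (mask and label carried over)."""
        return replace(
            self,
            pixels=pixels,
            mask=None if self.mask is None else self.mask.copy(),
            color_space=self.color_space if color_space is None else color_space,
            meta=dict(self.meta),
        )

    def copy(self) -> "LabeledImage":
        return replace(
            self,
            pixels=self.pixels.copy(),
            mask=None if self.mask is None else self.mask.copy(),
            meta=dict(self.meta),
        )

    def foreground_fraction(self) -> float:
        if self.mask is None:
            raise ValidationError("image has no mask")
        return float(self.mask.mean())
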