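"""Grayscale image container shared by all stages.

A mammogram here is a plain 2-D intensity raster plus a declared bit depth;
all detector logic is range-relative, so the bit depth only fixes the legal
intensity interval [0, 2**bit_depth - 1] for validation and file output.
Coordinates everywhere in this package are 0-based with x = column and
y = row; boxes are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GrayImage", "as_gray"]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale image with a declared bit depth (8 or 16)."""

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"expected a 2-D image, got shape {px.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if px.size and (px.min() < 0 or px.max() > self.max_value):
            raise ValueError(
                f"intensities outside [0, {self.max_value}] for bit depth {self.bit_depth}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)

    def astype_float(self) -> np.ndarray:
        return np.asarray(self.pixels, dtype=np.float64)


def as_gray(image: "GrayImage | np.ndarray") -> GrayImage:
    """Coerce an array (or pass through a GrayImage) into a GrayImage.

    Bit depth is inferred from the dtype: uint16 maps to 16 bits, anything
    else to 8 bits (float arrays must already lie in [0, 255]).
    """
    if isinstance(image, GrayImage):
        return image
    arr = np.asarray(image)
    depth = 16 if arr.dtype == np.uint16 else 8
    return GrayImage(arr, bit_depth=depth)
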