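"""Three-step image enhancement used to condition images for a CNN detector.

The chain is: (1) truncation normalization — clip intensities to robust
"effective" bounds taken from the histogram of the breast (non-zero) pixels,
then stretch to the full output range; (2) contrast-limited adaptive
histogram equalization (CLAHE) at two different clip limits; (3) stacking of
the three results into a 3-channel image.  The nested-contours detector
itself runs on the raw image; this module is optional conditioning.

CLAHE is implemented here in the classical tile form: the image is divided
into a grid of tiles, each tile's histogram is clipped at
``clip_limit * tile_pixels / n_bins`` counts with the excess redistributed
uniformly, each clipped histogram yields an equalization lookup table, and
every pixel is mapped through a bilinear blend of the four surrounding tile
tables.  ``clip_limit`` is therefore a multiple of the uniform-histogram bin
height (1.0 allows no contrast amplification beyond uniform; larger values
allow more), which is the convention the clip values 1.0 and 2.0 refer to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import GrayImage, as_gray

__all__ = [
    "PreprocessParams",
    "ThreeChannelImage",
    "truncation_normalize",
    "clahe",
    "synthesize_three_channel",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the enhancement chain.

    low_fraction / high_fraction: fraction of the non-zero-pixel histogram
    cut away at the bottom / top when selecting the effective intensity
    bounds; 0 means the global extreme is used (no truncation on that side).
    clip_limit_1 / clip_limit_2: CLAHE clip limits for channels 2 and 3.
    tile_grid: (rows, cols) of the CLAHE tile grid.
    """

    low_fraction: float = 0.01
    high_fraction: float = 0.01
    clip_limit_1: float = 1.0
    clip_limit_2: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)

    def __post_init__(self) -> None:
        if not (0 <= self.low_fraction < 1 and 0 <= self.high_fraction < 1):
            raise ValueError("fractions must lie in [0, 1)")
        if self.low_fraction >= 1 - self.high_fraction:
            raise ValueError("low_fraction must be below 1 - high_fraction")
        if self.clip_limit_1 <= 0 or self.clip_limit_2 <= 0:
            raise ValueError("clip limits must be positive")
        if self.clip_limit_1 == self.clip_limit_2:
            raise ValueError("clip_limit_1 and clip_limit_2 must differ")
        r, c = self.tile_grid
        if r < 1 or c < 1:
            raise ValueError("tile_grid entries must be positive")


@dataclass(frozen=True)
class ThreeChannelImage:
    """Truncated/normalized channel plus two CLAHE channels, same shape."""

    ch_trunc: GrayImage
    ch_clahe1: GrayImage
    ch_clahe2: GrayImage

    def __post_init__(self) -> None:
        if not (self.ch_trunc.shape == self.ch_clahe1.shape == self.ch_clahe2.shape):
            raise ValueError("all three channels must share height/width")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ch_trunc.shape

    def stack(self) -> np.ndarray:
        """(H, W, 3) array, channel order trunc / clahe1 / clahe2."""
        return np.dstack(
            [self.ch_trunc.pixels, self.ch_clahe1.pixels, self.ch_clahe2.pixels]
        )


def truncation_normalize(
    image: GrayImage | np.ndarray, params: PreprocessParams | None = None
) -> GrayImage:
    """Clip intensities to effective bounds and stretch to the full range.

    The effective minimum / maximum are intensity percentiles of the
    non-zero (breast) pixels at ``low_fraction`` and ``1 - high_fraction``;
    a fraction of 0 falls back to the global extreme so that the operation
    is the identity (up to rescale) on images already spanning their range.

    Raises ValueError when the image carries no dynamic range (all pixels
    equal, or the selected bounds coincide).
    """
    img = as_gray(image)
    params = params or PreprocessParams()
    arr = img.astype_float()
    if arr.max() == arr.min():
        raise ValueError("degenerate image: no dynamic range (all pixels equal)")

    nonzero = arr[arr > 0]
    if nonzero.size == 0:
        raise ValueError("degenerate image: no non-zero (breast) pixels")
    lo = (
        float(np.percentile(nonzero, 100.0 * params.low_fraction))
        if params.low_fraction > 0
        else float(arr.min())
    )
    hi = (
        float(np.percentile(nonzero, 100.0 * (1 - params.high_fraction)))
        if params.high_fraction > 0
        else float(arr.max())
    )
    if hi <= lo:
        raise ValueError(
            f"degenerate effective bounds (lo={lo}, hi={hi}): no dynamic range"
        )
    clipped = np.clip(arr, lo, hi)
    out = (clipped - lo) / (hi - lo) * img.max_value
    return GrayImage(np.rint(out).astype(img.dtype), bit_depth=img.bit_depth)


def _tile_lut(tile: np.ndarray, clip_limit: float, n_bins: int, max_value: int) -> np.ndarray:
    """Equalization lookup table of one tile with histogram clipping."""
    hist = np.bincount(tile.ravel(), minlength=n_bins).astype(np.float64)
    n = hist.sum()
    if np.count_nonzero(hist) <= 1:
        # flat tile: equalization would invent contrast from nothing;
        # keep the identity mapping
        return np.linspace(0, max_value, n_bins)
    clip = max(clip_limit * n / n_bins, 1.0)
    excess = np.maximum(hist - clip, 0.0).sum()
    hist = np.minimum(hist, clip) + excess / n_bins
    cdf = np.cumsum(hist)
    # map the lowest occupied bin to 0 and the top of the cdf to max_value
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    denom = cdf[-1] - cdf_min
    if denom <= 0:
        return np.linspace(0, max_value, n_bins)
    return (cdf - cdf_min) / denom * max_value


def clahe(
    image: GrayImage | np.ndarray,
    clip_limit: float,
    tile_grid: tuple[int, int] = (8, 8),
) -> GrayImage:
    """Contrast-limited adaptive histogram equalization.

    Tiles of ``tile_grid`` share the image (the image is edge-padded to a
    multiple of the tile size); per-tile histograms are clipped at
    ``clip_limit`` times the uniform bin height, excess redistributed, and
    pixel values are mapped through a bilinear blend of the four nearest
    tile lookup tables.  Output preserves shape and the bit-depth range.
    """
    if clip_limit <= 0:
        raise ValueError(f"clip_limit must be positive, got {clip_limit}")
    img = as_gray(image)
    rows, cols = tile_grid
    if rows < 1 or cols < 1:
        raise ValueError("tile_grid entries must be positive")
    h, w = img.shape
    n_bins = img.max_value + 1
    arr = np.asarray(img.pixels, dtype=np.int64)

    th = -(-h // rows)  # tile height (ceil), image padded to rows*th
    tw = -(-w // cols)
    pad_h, pad_w = rows * th - h, cols * tw - w
    padded = np.pad(arr, ((0, pad_h), (0, pad_w)), mode="edge")

    luts = np.empty((rows, cols, n_bins), dtype=np.float64)
    for i in range(rows):
        for j in range(cols):
            tile = padded[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            luts[i, j] = _tile_lut(tile, clip_limit, n_bins, img.max_value)

    # bilinear blend between tile centers; clamp outside the center lattice
    yy = (np.arange(h) + 0.5) / th - 0.5
    xx = (np.arange(w) + 0.5) / tw - 0.5
    y0 = np.clip(np.floor(yy).astype(int), 0, rows - 1)
    x0 = np.clip(np.floor(xx).astype(int), 0, cols - 1)
    y1 = np.minimum(y0 + 1, rows - 1)
    x1 = np.minimum(x0 + 1, cols - 1)
    wy = np.clip(yy - y0, 0.0, 1.0)[:, None]
    wx = np.clip(xx - x0, 0.0, 1.0)[None, :]

    v = arr[:h, :w]
    g00 = luts[y0[:, None], x0[None, :], v]
    g01 = luts[y0[:, None], x1[None, :], v]
    g10 = luts[y1[:, None], x0[None, :], v]
    g11 = luts[y1[:, None], x1[None, :], v]
    out = (1 - wy) * ((1 - wx) * g00 + wx * g01) + wy * ((1 - wx) * g10 + wx * g11)
    out = np.clip(np.rint(out), 0, img.max_value).astype(img.dtype)
    return GrayImage(out, bit_depth=img.bit_depth)


def synthesize_three_channel(
    image: GrayImage | np.ndarray, params: PreprocessParams | None = None
) -> ThreeChannelImage:
    """Run the full enhancement chain and stack its three results.

    Channel 1 is the truncated/normalized image; channels 2 and 3 are its
    CLAHE enhancements at ``clip_limit_1`` and ``clip_limit_2``.
    """
    params = params or PreprocessParams()
    base = truncation_normalize(image, params)
    return ThreeChannelImage(
        ch_trunc=base,
        ch_clahe1=clahe(base, params.clip_limit_1, params.tile_grid),
        ch_clahe2=clahe(base, params.clip_limit_2, params.tile_grid),
    )
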