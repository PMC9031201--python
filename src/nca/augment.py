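"""Annotation-consistent training-set augmentation.

Two operators: an eightfold expansion of every sample by independently
drawn rotation / mirror / shift, and the four-image Mosaic mix.  Both move
the ground-truth boxes through exactly the same geometry as the pixels
(boxes are re-axis-aligned as the bounding box of their transformed corners
and clipped), and both are bit-reproducible given a seed.  Exposed corners
after rotation are filled with 0, the black background of mammograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, resize, warp

from .image import GrayImage
from .metrics import Annotation, BoundingBox

__all__ = ["AugmentedSample", "eightfold_augment", "mosaic", "apply_affine_sample"]

MOSAIC_DROP_FRACTION = 0.8  # drop a box losing more than this area share


@dataclass(frozen=True)
class AugmentedSample:
    """An image with its annotations plus provenance of how it was made."""

    image: GrayImage
    annotations: tuple[Annotation, ...] = ()
    provenance: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "annotations", tuple(self.annotations))
        h, w = self.image.shape
        for ann in self.annotations:
            b = ann.box
            if not (0 <= b.x_min < b.x_max <= w and 0 <= b.y_min < b.y_max <= h):
                raise ValueError(f"annotation box {b} outside image bounds {(h, w)}")


def _transform_box(
    box: BoundingBox, matrix: np.ndarray, shape: tuple[int, int]
) -> BoundingBox | None:
    """Map a half-open box through a 3x3 affine, re-axis-align and clip."""
    corners = np.array(
        [
            [box.x_min, box.y_min, 1.0],
            [box.x_max, box.y_min, 1.0],
            [box.x_min, box.y_max, 1.0],
            [box.x_max, box.y_max, 1.0],
        ]
    )
    mapped = corners @ matrix.T
    xs, ys = mapped[:, 0], mapped[:, 1]
    h, w = shape
    x0, x1 = max(xs.min(), 0.0), min(xs.max(), float(w))
    y0, y1 = max(ys.min(), 0.0), min(ys.max(), float(h))
    if x1 - x0 <= 0 or y1 - y0 <= 0:
        return None
    return BoundingBox(x0, y0, x1, y1)


def apply_affine_sample(
    sample: AugmentedSample,
    angle_deg: float = 0.0,
    mirror_h: bool = False,
    mirror_v: bool = False,
    shift: tuple[float, float] = (0.0, 0.0),
    provenance: str = "",
    seed: int = 0,
) -> AugmentedSample:
    """Rotate about the image center, mirror, then translate; remap boxes.

    Rotation is counterclockwise in the usual display sense (y axis down);
    ``shift`` is (dx, dy) in pixels.  Pixels exposed by the transform are
    filled with intensity 0.
    """
    img = sample.image
    h, w = img.shape
    cx, cy = w / 2.0, h / 2.0
    t = np.deg2rad(angle_deg)
    # CCW on screen with y pointing down
    rot = np.array(
        [[np.cos(t), np.sin(t), 0.0], [-np.sin(t), np.cos(t), 0.0], [0.0, 0.0, 1.0]]
    )
    mir = np.diag([-1.0 if mirror_h else 1.0, -1.0 if mirror_v else 1.0, 1.0])
    to_center = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=float)
    from_center = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1]], dtype=float)
    trans = np.array([[1, 0, shift[0]], [0, 1, shift[1]], [0, 0, 1]], dtype=float)
    matrix = trans @ from_center @ mir @ rot @ to_center

    tform = AffineTransform(matrix=matrix)
    out = warp(
        img.astype_float(), tform.inverse, output_shape=img.shape, order=1, cval=0.0
    )
    out_img = GrayImage(
        np.clip(np.rint(out), 0, img.max_value).astype(img.dtype), bit_depth=img.bit_depth
    )
    anns = []
    for ann in sample.annotations:
        nb = _transform_box(ann.box, matrix, img.shape)
        if nb is not None:
            anns.append(Annotation(box=nb, lesion_type=ann.lesion_type, density_class=ann.density_class))
    return AugmentedSample(
        image=out_img, annotations=tuple(anns), provenance=provenance, seed=seed
    )


def eightfold_augment(sample: AugmentedSample, seed: int = 0) -> list[AugmentedSample]:
    """Expand one sample into exactly 8 randomly transformed variants.

    Each variant draws an independent uniform rotation angle, two Bernoulli
    mirrors and a uniform translation within ±10% of each dimension.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    h, w = sample.image.shape
    out = []
    for i in range(8):
        angle = float(rng.uniform(0.0, 360.0))
        mirror_h = bool(rng.random() < 0.5)
        mirror_v = bool(rng.random() < 0.5)
        dx = float(rng.uniform(-0.1, 0.1) * w)
        dy = float(rng.uniform(-0.1, 0.1) * h)
        prov = (
            f"{sample.provenance or 'src'}|rot={angle:.2f}deg"
            f",mh={mirror_h},mv={mirror_v},shift=({dx:.1f},{dy:.1f})"
        )
        out.append(
            apply_affine_sample(
                sample, angle, mirror_h, mirror_v, (dx, dy), provenance=prov, seed=seed
            )
        )
    return out


def mosaic(
    samples: list[AugmentedSample],
    seed: int = 0,
    out_shape: tuple[int, int] = (512, 512),
) -> AugmentedSample:
    """Mix exactly four samples into one mosaic image.

    A mosaic center is drawn uniformly within the central half of
    ``out_shape``; each input is rescaled to fill its quadrant (top-left,
    top-right, bottom-left, bottom-right in input order) and its boxes are
    remapped through the same scaling.  Boxes that lose more than 80% of
    their area are dropped.  Every output pixel comes from exactly one
    input.  Deterministic given the seed.
    """
    if len(samples) != 4:
        raise ValueError(f"mosaic requires exactly 4 samples, got {len(samples)}")
    rng = np.random.default_rng(seed)
    H, W = out_shape
    cy = int(rng.integers(H // 4, 3 * H // 4 + 1))
    cx = int(rng.integers(W // 4, 3 * W // 4 + 1))
    quadrants = [
        (0, cy, 0, cx),
        (0, cy, cx, W),
        (cy, H, 0, cx),
        (cy, H, cx, W),
    ]
    canvas = np.zeros(out_shape, dtype=np.float64)
    anns: list[Annotation] = []
    bit_depth = samples[0].image.bit_depth
    for sample, (y0, y1, x0, x1) in zip(samples, quadrants):
        qh, qw = y1 - y0, x1 - x0
        if qh <= 0 or qw <= 0:
            continue
        src = sample.image.astype_float()
        sh, sw = src.shape
        scaled = resize(src, (qh, qw), order=1, preserve_range=True, anti_aliasing=False)
        canvas[y0:y1, x0:x1] = scaled
        sx, sy = qw / sw, qh / sh
        for ann in sample.annotations:
            b = ann.box
            nb_x0 = x0 + b.x_min * sx
            nb_x1 = x0 + b.x_max * sx
            nb_y0 = y0 + b.y_min * sy
            nb_y1 = y0 + b.y_max * sy
            cx0, cx1 = max(nb_x0, x0), min(nb_x1, float(x1))
            cy0, cy1 = max(nb_y0, y0), min(nb_y1, float(y1))
            full = (nb_x1 - nb_x0) * (nb_y1 - nb_y0)
            kept = max(cx1 - cx0, 0.0) * max(cy1 - cy0, 0.0)
            if full <= 0 or kept / full < 1.0 - MOSAIC_DROP_FRACTION:
                continue
            anns.append(
                Annotation(
                    box=BoundingBox(cx0, cy0, cx1, cy1),
                    lesion_type=ann.lesion_type,
                    density_class=ann.density_class,
                )
            )
    max_value = (1 << bit_depth) - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    img = GrayImage(np.clip(np.rint(canvas), 0, max_value).astype(dtype), bit_depth=bit_depth)
    provenance = "mosaic[" + ",".join(s.provenance or "src" for s in samples) + f"]@({cx},{cy})"
    return AugmentedSample(image=img, annotations=tuple(anns), provenance=provenance, seed=seed)
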