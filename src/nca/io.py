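"""Readers and writers: images, annotation/detection JSON, overlays.

JSON schemas are versioned and shared across the pipeline.  Coordinates
are 0-based with x = column, y = row; boxes half-open [x_min, y_min,
x_max, y_max].

Annotations file::

    {"version": 1,
     "annotations": [{"box": [x0, y0, x1, y1],
                      "lesion_type": "star_like",
                      "density_class": "B"}, ...]}

Detections file::

    {"version": 1,
     "detections": [{"box": [...], "score": 4.2, "depth": 7,
                     "contour": [[x, y], ...]}, ...]}
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image, ImageDraw

from .core import LesionCandidate
from .image import GrayImage
from .metrics import Annotation, BoundingBox

__all__ = [
    "load_image",
    "save_image",
    "read_annotations",
    "write_annotations",
    "read_detections",
    "write_detections",
    "write_overlay",
]

SCHEMA_VERSION = 1

_LUMA = np.array([0.2125, 0.7154, 0.0721])  # Rec. 709 weights


def load_image(path: str | Path) -> GrayImage:
    """Read a grayscale PNG/TIFF (or DICOM when pydicom is installed).

    Multi-channel inputs are converted by luminance; uint16 data keeps its
    16-bit depth, everything else is treated as 8-bit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise RuntimeError("DICOM support requires the 'pydicom' extra") from exc
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array
        if str(getattr(ds, "PhotometricInterpretation", "")) == "MONOCHROME1":
            arr = arr.max() - arr  # inverted grayscale convention
    elif suffix in (".png", ".tif", ".tiff"):
        try:
            import imageio.v3 as iio

            arr = iio.imread(path)
        except Exception as exc:
            raise ValueError(f"unreadable image file {path}: {exc}") from exc
    else:
        raise ValueError(f"unsupported image format {suffix!r} for {path}")
    arr = np.asarray(arr)
    if arr.ndim == 3:
        weights = _LUMA if arr.shape[2] >= 3 else np.ones(arr.shape[2]) / arr.shape[2]
        arr = (arr[..., : len(weights)].astype(np.float64) @ weights)
        arr = np.rint(arr)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image in {path}, got shape {arr.shape}")
    if arr.dtype == np.uint16 or (arr.dtype.kind in "iu" and arr.max() > 255):
        return GrayImage(arr.astype(np.uint16), bit_depth=16)
    return GrayImage(np.clip(arr, 0, 255).astype(np.uint8), bit_depth=8)


def save_image(path: str | Path, image: GrayImage | np.ndarray) -> None:
    """Write a grayscale image as PNG or TIFF (by extension)."""
    import imageio.v3 as iio

    path = Path(path)
    if isinstance(image, GrayImage):
        arr = np.asarray(image.pixels, dtype=image.dtype)
    else:
        arr = np.asarray(image)
    iio.imwrite(path, arr)


def _box_from_list(raw, where: str) -> BoundingBox:
    if not (isinstance(raw, (list, tuple)) and len(raw) == 4):
        raise ValueError(f"{where}: box must be [x_min, y_min, x_max, y_max], got {raw!r}")
    try:
        return BoundingBox(*map(float, raw))
    except ValueError as exc:
        raise ValueError(f"{where}: {exc}") from exc


def read_annotations(path: str | Path) -> list[Annotation]:
    """Load ground-truth annotations, validating every record."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict) or "annotations" not in data:
        raise ValueError(f"{path}: not an annotations file")
    out = []
    for i, rec in enumerate(data["annotations"]):
        where = f"{path} annotation #{i}"
        box = _box_from_list(rec.get("box"), where)
        try:
            out.append(
                Annotation(
                    box=box,
                    lesion_type=rec.get("lesion_type"),
                    density_class=rec.get("density_class"),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from exc
    return out


def write_annotations(path: str | Path, annotations: Sequence[Annotation]) -> None:
    payload = {
        "version": SCHEMA_VERSION,
        "annotations": [
            {
                "box": ann.box.as_list(),
                "lesion_type": ann.lesion_type,
                **({"density_class": ann.density_class} if ann.density_class else {}),
            }
            for ann in annotations
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_detections(path: str | Path, candidates: Sequence[LesionCandidate]) -> None:
    payload = {
        "version": SCHEMA_VERSION,
        "detections": [
            {
                "box": cand.box.as_list(),
                "score": cand.score,
                "depth": cand.depth,
                "contour": cand.contour.vertices.tolist(),
            }
            for cand in candidates
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_detections(path: str | Path) -> list[dict]:
    """Load detections as dicts with 'box' (BoundingBox) and 'score'."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict) or "detections" not in data:
        raise ValueError(f"{path}: not a detections file")
    out = []
    for i, rec in enumerate(data["detections"]):
        where = f"{path} detection #{i}"
        out.append(
            {
                "box": _box_from_list(rec.get("box"), where),
                "score": float(rec.get("score", 0.0)),
                "depth": int(rec.get("depth", 0)),
                "contour": rec.get("contour"),
            }
        )
    return out


def write_overlay(
    path: str | Path,
    image: GrayImage,
    candidates: Sequence[LesionCandidate],
    annotations: Sequence[Annotation] = (),
) -> None:
    """Draw detected contours (and optional truth boxes) on the image.

    Detections are traced by their approximate lesion contour — the
    mark style a reader can compare against the source image — with the
    bounding box dashed around it; ground truth is drawn as plain boxes.
    """
    arr = image.astype_float()
    arr = (arr - arr.min()) / max(arr.max() - arr.min(), 1.0) * 255.0
    canvas = Image.fromarray(arr.astype(np.uint8)).convert("RGB")
    draw = ImageDraw.Draw(canvas)
    for ann in annotations:
        b = ann.box
        draw.rectangle([b.x_min, b.y_min, b.x_max - 1, b.y_max - 1], outline=(80, 200, 80))
    for cand in candidates:
        pts = [(float(x), float(y)) for x, y in cand.contour.vertices]
        draw.polygon(pts, outline=(255, 60, 60))
        b = cand.box
        draw.rectangle([b.x_min, b.y_min, b.x_max - 1, b.y_max - 1], outline=(255, 160, 60))
    canvas.save(Path(path))
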