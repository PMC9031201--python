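"""Detection-evaluation metrics for lesion marking.

Detection is scored as a pure localisation task: a predicted box is correct
when its intersection-over-union with an unmatched ground-truth box reaches
the threshold (0.5 by default); there is no true-negative cell.  Reported
scores are Precision = TP/(TP+FP), Recall = TP/(TP+FN), their harmonic mean
F1, and the recall-weighted

    F_beta = (1 + beta^2) * P * R / (beta * P + R)

with the linear-in-beta denominator: that is the form whose published
reference values this module reproduces, and it is kept deliberately (it is
not the textbook beta^2 weighting).  Average precision uses the 11-point
interpolation AP = (1/11) * sum over r in {0, 0.1, ..., 1} of
max{p at recall >= r}.

Clinical-style tables tally outcomes per image and per mammographic lesion
type: on a single-lesion image TP/FN record whether the lesion was marked
and FP records whether any spurious marking appeared.  Report values can be
rounded or truncated to two decimals; truncation is the default because the
reference tables follow it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LESION_TYPES",
    "DENSITY_CLASSES",
    "BoundingBox",
    "Annotation",
    "ConfusionCounts",
    "PRCurve",
    "MetricReport",
    "iou",
    "match_detections",
    "precision_recall",
    "f1",
    "f_beta",
    "average_precision_11pt",
    "mean_ap",
    "aggregate_by_type",
    "compare_marking_rates",
]

#: the closed set of mammographic appearance types
LESION_TYPES = (
    "star_like",
    "mass_unclear_border",
    "round_oval_clear_border",
    "asymmetric_density",
    "invisible_dense_background",
    "partly_visualized",
)

#: ACR parenchymal density categories
DENSITY_CLASSES = ("A", "B", "C", "D")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based, half-open: pixels with x in [x_min, x_max)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"empty box: {self}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def contains_box(self, other: "BoundingBox") -> bool:
        return (
            self.x_min <= other.x_min
            and self.y_min <= other.y_min
            and self.x_max >= other.x_max
            and self.y_max >= other.y_max
        )

    def as_list(self) -> list[float]:
        return [self.x_min, self.y_min, self.x_max, self.y_max]


@dataclass(frozen=True)
class Annotation:
    """A ground-truth lesion: box plus mammographic type, optional density."""

    box: BoundingBox
    lesion_type: str
    density_class: str | None = None

    def __post_init__(self) -> None:
        if self.lesion_type not in LESION_TYPES:
            raise ValueError(
                f"unknown lesion_type {self.lesion_type!r}; expected one of {LESION_TYPES}"
            )
        if self.density_class is not None and self.density_class not in DENSITY_CLASSES:
            raise ValueError(
                f"unknown density_class {self.density_class!r}; expected one of {DENSITY_CLASSES}"
            )


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN tallies; detection has no true-negative cell."""

    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class PRCurve:
    """Operating points (recall, precision), each coordinate in [0, 1]."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(r), float(p)) for r, p in self.points)
        for r, p in pts:
            if not (0 <= r <= 1 and 0 <= p <= 1):
                raise ValueError(f"PR point outside the unit square: ({r}, {p})")
        object.__setattr__(self, "points", pts)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union S(A∩B)/S(A∪B) of two boxes; in [0, 1]."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def _box_center(b: BoundingBox) -> tuple[float, float]:
    return ((b.x_min + b.x_max) / 2.0, (b.y_min + b.y_max) / 2.0)


def _center_inside(pt: tuple[float, float], b: BoundingBox) -> bool:
    return b.x_min <= pt[0] < b.x_max and b.y_min <= pt[1] < b.y_max


def match_detections(
    detections: Sequence[tuple[BoundingBox, float]],
    ground_truths: Sequence[Annotation | BoundingBox],
    iou_threshold: float = 0.5,
    mode: str = "iou",
) -> tuple[ConfusionCounts, list[tuple[int, int]]]:
    """Greedy one-to-one matching of detections to ground truths.

    Detections are visited in descending score; each is assigned to the
    still-unmatched ground truth of highest IoU among those it qualifies
    for.  Two qualification modes:

    - ``"iou"`` (default, the detection-benchmark rule): the pair must
      reach IoU >= ``iou_threshold``;
    - ``"marking"`` (the clinical reading rule — the mark points at the
      lesion): IoU >= threshold, or the boxes mutually contain each
      other's centers.

    Returns the confusion counts and the (detection_index,
    ground_truth_index) match list.  tp + fn always equals
    len(ground_truths).
    """
    if not (0 < iou_threshold <= 1):
        raise ValueError("iou_threshold must lie in (0, 1]")
    if mode not in ("iou", "marking"):
        raise ValueError(f"unknown matching mode {mode!r}")
    gt_boxes = [g.box if isinstance(g, Annotation) else g for g in ground_truths]
    order = sorted(range(len(detections)), key=lambda i: (-detections[i][1], i))
    taken = [False] * len(gt_boxes)
    matches: list[tuple[int, int]] = []
    for di in order:
        box = detections[di][0]
        best_j, best_iou = -1, -1.0
        for j, gt in enumerate(gt_boxes):
            if taken[j]:
                continue
            v = iou(box, gt)
            ok = v >= iou_threshold
            if not ok and mode == "marking":
                ok = _center_inside(_box_center(gt), box) and _center_inside(
                    _box_center(box), gt
                )
            if ok and v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            taken[best_j] = True
            matches.append((di, best_j))
    tp = len(matches)
    counts = ConfusionCounts(tp=tp, fp=len(detections) - tp, fn=len(gt_boxes) - tp)
    return counts, sorted(matches)


def precision_recall(c: ConfusionCounts) -> tuple[float | None, float | None]:
    """Exact precision and recall; ``None`` marks an undefined ratio."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    return precision, recall


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if p == 0 and r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def f_beta(p: float, r: float, beta: float) -> float:
    """(1 + beta^2) * p * r / (beta * p + r) — linear-in-beta denominator.

    Reduces to f1 at beta = 1.  The denominator is intentionally beta*p + r
    (not beta^2*p + r); see the module docstring.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    denom = beta * p + r
    if denom == 0:
        return 0.0
    return (1 + beta**2) * p * r / denom


def average_precision_11pt(curve: PRCurve) -> float:
    """11-point interpolated average precision of a PR curve."""
    if not curve.points:
        raise ValueError("empty PR curve")
    recalls = np.array([r for r, _ in curve.points])
    precisions = np.array([p for _, p in curve.points])
    total = 0.0
    for r in np.linspace(0.0, 1.0, 11):
        mask = recalls >= r - 1e-12
        total += float(precisions[mask].max()) if mask.any() else 0.0
    return total / 11.0


def mean_ap(per_class: Mapping[str, float]) -> float:
    """Arithmetic mean of per-class average precisions."""
    if not per_class:
        raise ValueError("empty per-class AP map")
    return float(np.mean(list(per_class.values())))


def _round_value(x: float | None, mode: str) -> float | None:
    if x is None:
        return None
    if mode == "truncate_2dp":
        return math.floor(x * 100 + 1e-9) / 100
    if mode == "round_2dp":
        return round(x, 2)
    if mode == "none":
        return x
    raise ValueError(f"unknown rounding mode {mode!r}")


@dataclass(frozen=True)
class MetricReport:
    """Per-type confusion counts with derived overall scores.

    Derived precision/recall are exact ratios of the total counts; the
    two-decimal view (``precision``, ``recall``, ``f1`` properties and
    ``f_beta_values``) applies ``rounding_mode`` first, and F-scores are
    computed from the already-rounded precision/recall — the convention the
    published reference tables follow.
    """

    per_type: Mapping[str, ConfusionCounts]
    rounding_mode: str = "truncate_2dp"
    betas: tuple[float, ...] = (1.0,)
    negative_images_fp: int = 0

    @property
    def totals(self) -> ConfusionCounts:
        total = ConfusionCounts()
        for c in self.per_type.values():
            total = total + c
        return total

    @property
    def precision_exact(self) -> float | None:
        return precision_recall(self.totals)[0]

    @property
    def recall_exact(self) -> float | None:
        return precision_recall(self.totals)[1]

    @property
    def precision(self) -> float | None:
        return _round_value(self.precision_exact, self.rounding_mode)

    @property
    def recall(self) -> float | None:
        return _round_value(self.recall_exact, self.rounding_mode)

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None:
            return None
        return _round_value(f1(p, r), self.rounding_mode)

    @property
    def f_beta_values(self) -> dict[float, float | None]:
        p, r = self.precision, self.recall
        out: dict[float, float | None] = {}
        for b in self.betas:
            if p is None or r is None:
                out[b] = None
            else:
                out[b] = _round_value(f_beta(p, r, b), self.rounding_mode)
        return out

    def to_dict(self) -> dict:
        t = self.totals
        return {
            "per_type": {k: {"tp": c.tp, "fp": c.fp, "fn": c.fn} for k, c in self.per_type.items()},
            "totals": {"tp": t.tp, "fp": t.fp, "fn": t.fn},
            "negative_images_fp": self.negative_images_fp,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "f_beta": {str(b): v for b, v in self.f_beta_values.items()},
            "rounding_mode": self.rounding_mode,
        }


def aggregate_by_type(
    per_type_counts: Mapping[str, ConfusionCounts] | Iterable[Mapping[str, ConfusionCounts]],
    rounding_mode: str = "truncate_2dp",
    betas: Sequence[float] = (1.0,),
    negative_images_fp: int = 0,
) -> MetricReport:
    """Build a MetricReport from per-type counts.

    Accepts either one mapping lesion_type -> ConfusionCounts or an iterable
    of such mappings (per image), which are summed.  Unknown lesion-type
    labels are rejected; totals equal the per-type sums by construction.
    """
    if isinstance(per_type_counts, Mapping):
        items: Iterable[Mapping[str, ConfusionCounts]] = [per_type_counts]
    else:
        items = per_type_counts
    summed: dict[str, ConfusionCounts] = {t: ConfusionCounts() for t in LESION_TYPES}
    for mapping in items:
        for t, c in mapping.items():
            if t not in summed:
                raise ValueError(f"unknown lesion_type {t!r}")
            summed[t] = summed[t] + c
    return MetricReport(
        per_type=summed,
        rounding_mode=rounding_mode,
        betas=tuple(betas),
        negative_images_fp=negative_images_fp,
    )


def compare_marking_rates(
    a: tuple[int, int], b: tuple[int, int]
) -> float:
    """Two-sided chi-square test (no continuity correction) on two rates.

    ``a`` and ``b`` are (successes, trials).  Returns the p-value of the
    chi-square test on the 2x2 table; degenerate tables with a zero margin
    are rejected.  Identical proportions give p = 1.
    """
    (sa, na), (sb, nb) = a, b
    if not (0 <= sa <= na and 0 <= sb <= nb and na > 0 and nb > 0):
        raise ValueError("invalid successes/trials")
    table = np.array([[sa, na - sa], [sb, nb - sb]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in the 2x2 table")
    if sa * nb == sb * na:
        return 1.0
    res = stats.chi2_contingency(table, correction=False)
    return float(res.pvalue)
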