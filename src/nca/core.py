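"""The nested-contours algorithm (NCA) for suspicious-mass detection.

A mammographic mass is the 2-D projection of a roughly convex 3-D lesion,
so its intensity rises smoothly toward a maximum: iso-intensity contours
taken at successive brightness levels around a mass form a chain of nested,
mutually similar closed curves.  The detector exploits exactly this:

1. iso-contours are extracted over the entire brightness range of the raw
   image at a constant gradation step ``k`` (marching squares with
   sub-pixel interpolation; contours cut by the image border are closed
   along it so partly visualized masses stay detectable);
2. contours at successive levels are linked into nested chains, lowest
   level upward;
3. a chain is cut wherever the next contour stops resembling the previous
   one — the area ratio deviates by more than ``tau_area`` or the centroid
   moves by more than ``tau_shift`` equivalent radii — each maximal
   well-nested segment standing on its own; segments that are too shallow,
   too small or too large are discarded.  Surviving segments are the mass
   candidates.

The detector is range-relative: by default ``k`` is 1/32 of the image's
intensity range, so an affine remap of intensities leaves the detected
geometry unchanged.  No pre-processing is required; the source image is the
input.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from shapely.geometry import Polygon
from shapely.strtree import STRtree
from skimage.measure import find_contours

from .image import GrayImage, as_gray
from .metrics import BoundingBox

__all__ = [
    "IsoContour",
    "ContourNest",
    "NCAParams",
    "LesionCandidate",
    "build_level_contours",
    "contains",
    "link_nested_chains",
    "step_dissimilarity",
    "prune_chains",
    "detect_lesions",
]


@dataclass(frozen=True, eq=False)
class IsoContour:
    """A closed iso-intensity polygon at one brightness level.

    ``vertices`` is an (N, 2) array of sub-pixel (x, y) points; the polygon
    is implicitly closed (last vertex joins the first).
    """

    level: float
    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("vertices must be an (N>=3, 2) array of (x, y)")
        if v.shape[0] > 3 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        object.__setattr__(self, "vertices", v)

    @cached_property
    def polygon(self) -> Polygon:
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            poly = poly.buffer(0)
            if poly.geom_type == "MultiPolygon":
                poly = max(poly.geoms, key=lambda g: g.area)
        return poly

    @cached_property
    def area(self) -> float:
        return float(self.polygon.area)

    @cached_property
    def perimeter(self) -> float:
        return float(self.polygon.length)

    @cached_property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (float(c.x), float(c.y))

    @cached_property
    def bounding_box(self) -> BoundingBox:
        x0, y0, x1, y1 = self.polygon.bounds
        return BoundingBox(x0, y0, max(x1, x0 + 1e-6), max(y1, y0 + 1e-6))


@dataclass(frozen=True)
class ContourNest:
    """An ordered chain of mutually nested contours, level strictly rising."""

    contours: tuple[IsoContour, ...]
    dissimilarity_trace: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "contours", tuple(self.contours))
        trace = tuple(self.dissimilarity_trace)
        if not trace and len(self.contours) > 1:
            trace = tuple(
                step_dissimilarity(a, b)
                for a, b in zip(self.contours[:-1], self.contours[1:])
            )
        object.__setattr__(self, "dissimilarity_trace", trace)
        if len(trace) != max(len(self.contours) - 1, 0):
            raise ValueError("dissimilarity_trace length must be depth - 1")

    @property
    def depth(self) -> int:
        return len(self.contours)

    @property
    def outermost(self) -> IsoContour:
        return self.contours[0]


@dataclass(frozen=True)
class NCAParams:
    """Tuning knobs of the detector.

    k: gradation step in intensity units; ``None`` resolves to
        (image max - image min) / k_divisions at detection time, keeping the
        level placement relative to the brightness range.
    min_depth: minimum surviving chain length for a mass.
    tau_area: max allowed |1 - area(next)/area(prev)| per step.
    tau_shift: max allowed centroid shift per step, in units of the previous
        contour's equivalent radius sqrt(area/pi).
    min_area / max_area: candidate outer-contour area bounds in px^2;
        ``max_area_fraction`` is used when max_area is None.
    """

    k: float | None = None
    k_divisions: int = 32
    min_depth: int = 3
    tau_area: float = 0.5
    tau_shift: float = 0.5
    polarity: str = "bright_on_dark"
    min_area: float = 25.0
    max_area: float | None = None
    max_area_fraction: float = 0.25
    min_contour_area: float = 4.0

    def __post_init__(self) -> None:
        if self.k is not None and self.k <= 0:
            raise ValueError("k must be positive")
        if self.k_divisions < 2:
            raise ValueError("k_divisions must be at least 2")
        if self.min_depth < 2:
            raise ValueError("min_depth must be at least 2")
        if self.tau_area <= 0 or self.tau_shift <= 0:
            raise ValueError("tau_area and tau_shift must be positive")
        if self.polarity != "bright_on_dark":
            raise ValueError("only bright_on_dark polarity is supported")
        max_area = self.max_area
        if max_area is not None and not (self.min_area < max_area):
            raise ValueError("min_area must be below max_area")
        if self.min_contour_area < 0:
            raise ValueError("min_contour_area must be >= 0")

    def resolve_k(self, intensity_range: float) -> float:
        return self.k if self.k is not None else intensity_range / self.k_divisions

    def resolve_max_area(self, image_area: float) -> float:
        return self.max_area if self.max_area is not None else self.max_area_fraction * image_area


@dataclass(frozen=True)
class LesionCandidate:
    """A detected mass: representative contour, box, nest depth, score."""

    contour: IsoContour
    box: BoundingBox
    depth: int
    score: float


def _signed_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def build_level_contours(
    image: GrayImage | np.ndarray, k: float, min_contour_area: float = 0.0
) -> list[IsoContour]:
    """Extract closed iso-contours at levels min+k, min+2k, ... < max.

    Marching-squares contours with sub-pixel linear interpolation; the image
    is padded with its minimum so every contour closes, including those cut
    by the border (their border run is collapsed onto the image edge).  Only
    contours that enclose brighter-than-level regions are kept, matching the
    bright-on-dark polarity of masses.  ``min_contour_area`` (px^2) floors
    out sub-resolution noise specks before any geometry is built; 0 keeps
    everything.  A degenerate (constant) image yields an empty list.
    """
    if k <= 0:
        raise ValueError("gradation step k must be positive")
    img = as_gray(image)
    arr = img.astype_float()
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        return []
    h, w = arr.shape
    padded = np.pad(arr, 1, constant_values=lo)
    out: list[IsoContour] = []
    level = lo + k
    eps = 1e-9 * max(abs(hi), 1.0)
    while level < hi - eps:
        raw = [
            rc
            for rc in find_contours(padded, level, positive_orientation="high")
            if rc.shape[0] >= 4 and rc[0, 0] == rc[-1, 0] and rc[0, 1] == rc[-1, 1]
        ]
        if raw:
            # batched shoelace over all contours of this level: signed area
            # in the (x=col, y=row) frame is negative for bright-enclosing
            # contours under the 'high' orientation convention
            concat = np.concatenate(raw)
            lengths = np.fromiter((rc.shape[0] for rc in raw), dtype=np.intp)
            ends = np.cumsum(lengths)
            starts = ends - lengths
            x, y = concat[:, 1], concat[:, 0]
            cross = x[:-1] * y[1:] - x[1:] * y[:-1]
            sums = np.add.reduceat(cross, starts)
            # reduceat segments run to the next start: strip the spurious
            # boundary-crossing term between consecutive contours
            if len(raw) > 1:
                sums[:-1] -= cross[ends[:-1] - 1]
            signed = 0.5 * sums
            for idx in np.nonzero((signed < 0) & (-signed >= min_contour_area))[0]:
                xy = raw[idx][:-1, ::-1] - 1.0
                np.clip(xy[:, 0], 0.0, w - 1.0, out=xy[:, 0])
                np.clip(xy[:, 1], 0.0, h - 1.0, out=xy[:, 1])
                if xy.shape[0] < 3:
                    continue
                contour = IsoContour(level=level, vertices=xy)
                if contour.area > max(min_contour_area, 0.0):
                    out.append(contour)
        level += k
    return out


def contains(outer: IsoContour, inner: IsoContour) -> bool:
    """True iff ``inner`` lies entirely inside or on ``outer``.

    A bounding-box rejection precedes the exact polygon covers test.
    """
    ob, ib = outer.polygon.bounds, inner.polygon.bounds
    if ib[0] < ob[0] or ib[1] < ob[1] or ib[2] > ob[2] or ib[3] > ob[3]:
        return False
    return bool(outer.polygon.covers(inner.polygon))


def step_dissimilarity(prev: IsoContour, next: IsoContour) -> float:
    """Shape-change score between consecutive nested contours.

    max of the area-ratio deviation |1 - area(next)/area(prev)| and the
    centroid shift normalized by the previous contour's equivalent radius
    sqrt(area/pi).  Zero for identical contours.
    """
    if prev.area <= 0:
        raise ValueError("previous contour has zero area")
    area_dev = abs(1.0 - next.area / prev.area)
    (px, py), (nx, ny) = prev.centroid, next.centroid
    shift = float(np.hypot(nx - px, ny - py)) / np.sqrt(prev.area / np.pi)
    return max(area_dev, shift)


def _dissimilarity_components(prev: IsoContour, next: IsoContour) -> tuple[float, float]:
    if prev.area <= 0:
        raise ValueError("previous contour has zero area")
    area_dev = abs(1.0 - next.area / prev.area)
    (px, py), (nx, ny) = prev.centroid, next.centroid
    shift = float(np.hypot(nx - px, ny - py)) / np.sqrt(prev.area / np.pi)
    return area_dev, shift


def link_nested_chains(
    contours: list[IsoContour], params: NCAParams | None = None
) -> list[ContourNest]:
    """Link contours of successive levels into nested chains.

    Greedy, lowest level upward: a contour at level l+k is appended to the
    chain whose level-l tip contains it; a tip containing several
    next-level contours extends with the largest-area one (ties broken by
    smallest centroid shift) and the rest start new chains; contours with
    no containing tip start new chains.  Every contour joins exactly one
    chain.
    """
    del params  # linking is parameter-free; the signature mirrors the pipeline
    if not contours:
        return []
    levels = sorted({c.level for c in contours})
    by_level: dict[float, list[IsoContour]] = {lv: [] for lv in levels}
    for c in contours:
        by_level[c.level].append(c)

    chains: list[list[IsoContour]] = []
    tip_of_chain: dict[int, IsoContour] = {}
    # chains whose tip sits at the level just processed
    active: list[int] = []
    for idx, lv in enumerate(levels):
        current = by_level[lv]
        if idx == 0 or not active:
            assignments: dict[int, list[IsoContour]] = {}
            orphans = list(current)
        else:
            tips = [tip_of_chain[ci] for ci in active]
            tree = STRtree([t.polygon for t in tips])
            assignments = {}
            orphans = []
            for c in current:
                hits = tree.query(c.polygon, predicate="covered_by")
                if len(hits) == 0:
                    # fall back to exact test over bbox candidates (guards
                    # against borderline predicate misses on shared edges)
                    cand = [i for i in tree.query(c.polygon) if contains(tips[i], c)]
                    hits = np.array(cand, dtype=int)
                if len(hits) == 0:
                    orphans.append(c)
                    continue
                ti = int(min(hits, key=lambda i: tips[int(i)].area))
                assignments.setdefault(active[ti], []).append(c)
        next_active: list[int] = []
        for ci, children in assignments.items():
            tip = tip_of_chain[ci]
            children.sort(
                key=lambda c: (
                    -c.area,
                    float(np.hypot(c.centroid[0] - tip.centroid[0], c.centroid[1] - tip.centroid[1])),
                )
            )
            chains[ci].append(children[0])
            tip_of_chain[ci] = children[0]
            next_active.append(ci)
            for extra in children[1:]:
                chains.append([extra])
                tip_of_chain[len(chains) - 1] = extra
                next_active.append(len(chains) - 1)
        for c in orphans:
            chains.append([c])
            tip_of_chain[len(chains) - 1] = c
            next_active.append(len(chains) - 1)
        active = next_active
    return [ContourNest(contours=tuple(ch)) for ch in chains]


def prune_chains(
    nests: list[ContourNest], params: NCAParams, image_area: float | None = None
) -> list[ContourNest]:
    """Apply the discard rule and size/depth filters.

    A chain is cut at every step whose area-ratio deviation exceeds
    ``tau_area`` or whose normalized centroid shift exceeds ``tau_shift``:
    the offending contour no longer resembles its predecessor, so the chain
    up to the predecessor is terminated there — and the offending contour
    begins a chain of its own (a lesion nested inside larger parenchyma
    structure keeps its identity when the chain tracking that structure
    collapses onto it).  Every resulting maximal well-nested segment is then
    kept only if it is at least ``min_depth`` deep and its outermost contour
    area lies within [min_area, max_area].
    """
    max_area = (
        params.resolve_max_area(image_area)
        if image_area is not None
        else (params.max_area if params.max_area is not None else np.inf)
    )
    kept: list[ContourNest] = []
    for nest in nests:
        segments: list[tuple[int, int]] = []  # [start, end) indices
        start = 0
        for i, (a, b) in enumerate(zip(nest.contours[:-1], nest.contours[1:])):
            area_dev, shift = _dissimilarity_components(a, b)
            if area_dev > params.tau_area or shift > params.tau_shift:
                segments.append((start, i + 1))
                start = i + 1
        segments.append((start, nest.depth))
        for s, e in segments:
            contours = nest.contours[s:e]
            if len(contours) < params.min_depth:
                continue
            if not (params.min_area <= contours[0].area <= max_area):
                continue
            kept.append(
                ContourNest(
                    contours=contours,
                    dissimilarity_trace=nest.dissimilarity_trace[s : e - 1],
                )
            )
    return kept


def _circularity(contour: IsoContour) -> float:
    if contour.perimeter <= 0:
        return 0.0
    return 4.0 * np.pi * contour.area / contour.perimeter**2


def detect_lesions(
    image: GrayImage | np.ndarray, params: NCAParams | None = None
) -> list[LesionCandidate]:
    """Run the full nested-contours detector on a raw image.

    Pipeline: level contours -> nested-chain linking -> discard rule.  Each
    surviving chain yields one candidate whose representative contour is the
    chain's outermost retained contour; candidates whose boxes are nested
    one inside the other are merged, keeping the higher-scoring one (a deep
    circular nest outranks the shallower structure wrapped around it).  The
    score is depth-weighted circularity, depth * 4*pi*area/perimeter^2, and
    the result is sorted by descending score.  Deterministic for fixed
    input.
    """
    params = params or NCAParams()
    img = as_gray(image)
    arr = img.astype_float()
    rng_span = float(arr.max() - arr.min())
    if rng_span <= 0:
        return []
    k = params.resolve_k(rng_span)
    contours = build_level_contours(img, k, min_contour_area=params.min_contour_area)
    nests = link_nested_chains(contours, params)
    nests = prune_chains(nests, params, image_area=float(arr.size))

    candidates = [
        LesionCandidate(
            contour=nest.outermost,
            box=nest.outermost.bounding_box,
            depth=nest.depth,
            score=nest.depth * _circularity(nest.outermost),
        )
        for nest in nests
    ]
    # merge candidates whose boxes nest, keeping the higher-scoring one
    candidates.sort(key=lambda c: (-c.score, c.box.x_min, c.box.y_min))
    kept: list[LesionCandidate] = []
    for cand in candidates:
        if any(
            other.box.contains_box(cand.box) or cand.box.contains_box(other.box)
            for other in kept
        ):
            continue
        kept.append(cand)
    kept.sort(key=lambda c: (-c.score, c.box.x_min, c.box.y_min, c.box.x_max, c.box.y_max))
    return kept
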