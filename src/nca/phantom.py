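"""Seeded mammography-like phantoms with ground truth.

Phantoms are stylized, not photorealistic: a breast-shaped support holds a
band-limited parenchymal texture whose mean brightness and texture amplitude
rise with the ACR density class (A fatty ... D dense), and bright compact
lesions of the six mammographic appearance types are blended in additively.
Their purpose is to exercise the nested-contours detector across the
clinical difficulty spectrum — from high-contrast round masses down to
changes hidden in dense parenchyma — with exact, programmatic ground truth.

Lesion intensity patches are normalized so that a contrast of 1.0 uses the
full intensity headroom above the local background.  A blended lesion's
truth mask is its *discernible* extent — where the added intensity clears
the local fluctuation floor of the background (see compose_phantom) — and
the truth box is the tight axis-aligned box of that mask, clipped at the
image border.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage

from .image import GrayImage
from .metrics import DENSITY_CLASSES, LESION_TYPES, Annotation, BoundingBox

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "PhantomSample",
    "gen_background",
    "gen_lesion",
    "compose_phantom",
    "gen_test_set",
    "DEFAULT_TYPE_DISTRIBUTION",
    "DEFAULT_DENSITY_DISTRIBUTION",
    "DEFAULT_TYPE_CONTRAST",
]

#: test-set composition defaults: lesion-type counts per 100 positives
DEFAULT_TYPE_DISTRIBUTION: dict[str, int] = {
    "star_like": 16,
    "mass_unclear_border": 30,
    "round_oval_clear_border": 8,
    "asymmetric_density": 28,
    "invisible_dense_background": 16,
    "partly_visualized": 2,
}

#: ACR density-class counts per 100 positives
DEFAULT_DENSITY_DISTRIBUTION: dict[str, int] = {"A": 27, "B": 33, "C": 31, "D": 9}

#: default lesion contrast (fraction of available headroom) per type;
#: ordering encodes the clinical difficulty ranking — round/star-like masses
#: are conspicuous, asymmetric densities are faint, and lesions on dense
#: background sit near the texture amplitude
DEFAULT_TYPE_CONTRAST: dict[str, float] = {
    "star_like": 0.80,
    "mass_unclear_border": 0.45,
    "round_oval_clear_border": 0.90,
    "asymmetric_density": 0.30,
    "invisible_dense_background": 0.12,
    "partly_visualized": 0.85,
}

# per-class base intensity and texture amplitude (8-bit units at strength 1)
_CLASS_MEAN = {"A": 60.0, "B": 90.0, "C": 120.0, "D": 150.0}
_CLASS_TEXTURE = {"A": 4.0, "B": 8.0, "C": 14.0, "D": 22.0}

_MASK_FRACTION = 0.1  # lesion extent = patch >= 10% of peak amplitude


@dataclass(frozen=True)
class LesionSpec:
    lesion_type: str
    center: tuple[float, float]  # (x, y)
    size_px: float = 60.0
    contrast: float = 0.8
    n_spicula: int = 8

    def __post_init__(self) -> None:
        if self.lesion_type not in LESION_TYPES:
            raise ValueError(f"unknown lesion_type {self.lesion_type!r}")
        if not (0 < self.contrast <= 1):
            raise ValueError("contrast must lie in (0, 1]")
        if self.size_px <= 0:
            raise ValueError("size_px must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative recipe for one phantom image."""

    shape: tuple[int, int] = (512, 512)
    density_class: str = "B"
    lesions: tuple[LesionSpec, ...] = ()
    noise_sigma: float = 2.0
    texture_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_class not in DENSITY_CLASSES:
            raise ValueError(f"unknown density_class {self.density_class!r}")
        if self.texture_strength < 0 or self.noise_sigma < 0:
            raise ValueError("texture_strength and noise_sigma must be >= 0")
        object.__setattr__(self, "lesions", tuple(self.lesions))


@dataclass(frozen=True)
class PhantomSample:
    image: GrayImage
    annotations: tuple[Annotation, ...]
    spec: PhantomSpec


def _breast_support(shape: tuple[int, int]) -> np.ndarray:
    """Half-elliptical breast silhouette pressed against the left edge."""
    h, w = shape
    y, x = np.mgrid[0:h, 0:w]
    cy, rx, ry = (h - 1) / 2.0, 0.92 * w, 0.55 * h
    return (x / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0


def gen_background(
    density_class: str,
    shape: tuple[int, int] = (512, 512),
    texture_strength: float = 1.0,
    seed: int = 0,
) -> GrayImage:
    """Parenchymal background of one ACR density class.

    Base brightness and band-limited texture amplitude both rise from class
    A to class D; the breast support is zero outside.  Deterministic in the
    seed.
    """
    if density_class not in DENSITY_CLASSES:
        raise ValueError(f"unknown density_class {density_class!r}")
    rng = np.random.default_rng(seed)
    h, w = shape
    support = _breast_support(shape)
    base = np.full(shape, _CLASS_MEAN[density_class])
    if texture_strength > 0:
        # band-limited random field: heavily smoothed white noise, unit RMS
        field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=min(h, w) / 20)
        rms = field_.std()
        if rms > 0:
            field_ = field_ / rms
        base = base + texture_strength * _CLASS_TEXTURE[density_class] * field_
    base[~support] = 0.0
    return GrayImage(np.clip(np.rint(base), 0, 255).astype(np.uint8), bit_depth=8)


def _patch_grid(size_px: float) -> tuple[np.ndarray, np.ndarray, int]:
    half = int(np.ceil(size_px * 1.4))
    n = 2 * half + 1
    y, x = np.mgrid[0:n, 0:n]
    return x - half, y - half, half


def gen_lesion(
    lesion_type: str,
    size_px: float = 60.0,
    contrast: float = 0.8,
    n_spicula: int = 8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """One lesion as (intensity patch, boolean truth mask).

    The patch peaks at ``contrast`` (in units of the available intensity
    headroom above the local background); the mask marks where the patch
    reaches 10% of its peak.  Shapes by type:

    - star_like: Gaussian core with ``n_spicula`` thin radial ridges;
    - mass_unclear_border: broad Gaussian (gradual margin);
    - round_oval_clear_border: flat ellipse with a sharp sigmoid edge;
    - asymmetric_density: rotated anisotropic low-gradient blob;
    - invisible_dense_background: wide faint blob (contrast set low by the
      caller relative to the background texture);
    - partly_visualized: a clear round mass — its near-border placement is
      the composer's job.
    """
    if lesion_type not in LESION_TYPES:
        raise ValueError(f"unknown lesion_type {lesion_type!r}")
    if not (0 < contrast <= 1):
        raise ValueError("contrast must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    x, y, half = _patch_grid(size_px)
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)

    if lesion_type == "star_like":
        sigma = size_px / 4.0
        core = np.exp(-(r**2) / (2 * sigma**2))
        phase = rng.uniform(0, 2 * np.pi)
        angular = np.cos(n_spicula * (theta - phase))
        # spicule length ~ lesion radius: a Gaussian radial falloff with
        # scale 0.55*size bounds the ridges near the core, giving the
        # lesion a well-defined overall footprint
        ridges = (
            0.6
            * np.exp(-((1 - angular) ** 2) / (2 * 0.05**2))
            * np.exp(-((r / (0.55 * size_px)) ** 2))
            * (r > sigma)
        )
        patch = np.maximum(core, ridges)
    elif lesion_type == "mass_unclear_border":
        sigma = size_px / 2.5
        patch = np.exp(-(r**2) / (2 * sigma**2))
    elif lesion_type in ("round_oval_clear_border", "partly_visualized"):
        a = size_px / 2.0
        b = a * rng.uniform(0.7, 1.0)
        ang = rng.uniform(0, np.pi)
        xr = x * np.cos(ang) + y * np.sin(ang)
        yr = -x * np.sin(ang) + y * np.cos(ang)
        rho = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
        patch = 1.0 / (1.0 + np.exp((rho - 1.0) / 0.04))
    elif lesion_type == "asymmetric_density":
        sx = size_px / 2.0
        sy = sx * rng.uniform(0.35, 0.55)
        ang = rng.uniform(0, np.pi)
        xr = x * np.cos(ang) + y * np.sin(ang)
        yr = -x * np.sin(ang) + y * np.cos(ang)
        patch = np.exp(-((xr / sx) ** 2 + (yr / sy) ** 2))
    else:  # invisible_dense_background
        sigma = size_px / 2.0
        patch = np.exp(-(r**2) / (2 * sigma**2))

    patch = patch / patch.max() * contrast
    mask = patch >= _MASK_FRACTION * patch.max()
    return patch, mask


def _tight_box(mask: np.ndarray) -> BoundingBox | None:
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return None
    return BoundingBox(float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1))


def compose_phantom(spec: PhantomSpec) -> tuple[GrayImage, list[Annotation]]:
    """Render one phantom: background + lesions + pixel noise.

    Lesions are blended additively; each patch is scaled by its contrast
    times the headroom between the local background median and the top of
    the 8-bit range.  The truth mask of a blended lesion is where its added
    intensity is actually discernible: at least the local fluctuation floor
    (two noise sigmas plus the texture amplitude of the density class),
    clamped between 10% and 50% of the added peak so that faint lesions
    keep a non-empty annotation.  Truth boxes are tight boxes of these
    masks, clipped to the image; a lesion whose clipped mask is empty is
    dropped with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    bg = gen_background(
        spec.density_class, spec.shape, spec.texture_strength, seed=spec.seed
    )
    canvas = bg.astype_float()
    support = _breast_support(spec.shape)
    h, w = spec.shape
    annotations: list[Annotation] = []
    for li, lesion in enumerate(spec.lesions):
        patch, mask = gen_lesion(
            lesion.lesion_type,
            lesion.size_px,
            1.0,  # normalized; contrast applied against local headroom below
            lesion.n_spicula,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ph, pw = patch.shape
        cx, cy = lesion.center
        x0 = int(round(cx)) - pw // 2
        y0 = int(round(cy)) - ph // 2
        ix0, iy0 = max(x0, 0), max(y0, 0)
        ix1, iy1 = min(x0 + pw, w), min(y0 + ph, h)
        if ix0 >= ix1 or iy0 >= iy1:
            import warnings

            warnings.warn(f"lesion {li} falls entirely outside the image; dropped")
            continue
        sub = np.s_[iy0:iy1, ix0:ix1]
        psub = np.s_[iy0 - y0 : iy1 - y0, ix0 - x0 : ix1 - x0]
        local_bg = float(np.median(canvas[sub][mask[psub]])) if mask[psub].any() else 0.0
        headroom = max(255.0 - local_bg, 1.0)
        added = lesion.contrast * headroom * patch[psub]
        canvas[sub] += added
        # visible-extent truth mask: the added signal must clear the local
        # fluctuation floor of the background it sits on
        tex_amp = spec.texture_strength * _CLASS_TEXTURE[spec.density_class]
        peak = lesion.contrast * headroom * float(patch.max())
        floor = float(np.clip(2.0 * spec.noise_sigma + tex_amp, 0.1 * peak, 0.5 * peak))
        clipped_mask = (added >= floor) & support[sub]
        box = _tight_box(clipped_mask)
        if box is None:
            import warnings

            warnings.warn(f"lesion {li} truth mask empty after clipping; dropped")
            continue
        box = BoundingBox(box.x_min + ix0, box.y_min + iy0, box.x_max + ix0, box.y_max + iy0)
        annotations.append(
            Annotation(box=box, lesion_type=lesion.lesion_type, density_class=spec.density_class)
        )
    if spec.noise_sigma > 0:
        canvas[support] += rng.normal(0.0, spec.noise_sigma, int(support.sum()))
    canvas[~support] = 0.0
    img = GrayImage(np.clip(np.rint(canvas), 0, 255).astype(np.uint8), bit_depth=8)
    return img, annotations


def gen_test_set(
    n_positive: int = 100,
    n_negative: int = 100,
    type_distribution: Mapping[str, int] | None = None,
    density_distribution: Mapping[str, int] | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    type_contrast: Mapping[str, float] | None = None,
) -> list[PhantomSample]:
    """Full seeded test set: single-lesion positives plus lesion-free negatives.

    The default composition mirrors the clinical test-set tables: lesion
    types 16/30/8/28/16/2 and ACR densities 27/33/31/9 per 100 positives.
    Both distributions must sum to ``n_positive``.  Negatives draw their
    density class from the same proportions.  Fully reproducible by seed.
    """
    type_distribution = dict(
        DEFAULT_TYPE_DISTRIBUTION if type_distribution is None else type_distribution
    )
    density_distribution = dict(
        DEFAULT_DENSITY_DISTRIBUTION
        if density_distribution is None
        else density_distribution
    )
    type_contrast = dict(DEFAULT_TYPE_CONTRAST, **(type_contrast or {}))
    if sum(type_distribution.values()) != n_positive:
        raise ValueError("type_distribution must sum to n_positive")
    if sum(density_distribution.values()) != n_positive:
        raise ValueError("density_distribution must sum to n_positive")
    for t in type_distribution:
        if t not in LESION_TYPES:
            raise ValueError(f"unknown lesion_type {t!r}")
    for d in density_distribution:
        if d not in DENSITY_CLASSES:
            raise ValueError(f"unknown density_class {d!r}")

    rng = np.random.default_rng(seed)
    types = [t for t, n in type_distribution.items() for _ in range(n)]
    densities = [d for d, n in density_distribution.items() for _ in range(n)]
    rng.shuffle(types)
    rng.shuffle(densities)

    h, w = shape
    samples: list[PhantomSample] = []
    scale = min(h, w) / 512.0  # lesion sizes are defined at the 512 px scale
    for i in range(n_positive):
        lesion_type = types[i]
        size = float(rng.uniform(40, 80)) * scale
        if lesion_type == "partly_visualized":
            # place so >= 30% of the lesion extent falls outside the image
            edge_x = float(rng.uniform(0.0, 0.1 * size))
            center = (edge_x, float(rng.uniform(0.35 * h, 0.65 * h)))
        else:
            margin = 1.6 * size
            x_lo, x_hi = margin, max(0.75 * w - margin, margin + 1)
            y_lo, y_hi = margin + 0.15 * h, max(0.85 * h - margin, margin + 0.15 * h + 1)
            center = (
                float(rng.uniform(x_lo, x_hi) + 0.05 * w),
                float(rng.uniform(y_lo, y_hi)),
            )
        spec = PhantomSpec(
            shape=shape,
            density_class=densities[i],
            lesions=(
                LesionSpec(
                    lesion_type=lesion_type,
                    center=center,
                    size_px=size,
                    contrast=type_contrast[lesion_type],
                    n_spicula=int(rng.integers(6, 12)),
                ),
            ),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        img, anns = compose_phantom(spec)
        samples.append(PhantomSample(image=img, annotations=tuple(anns), spec=spec))
    if n_negative and density_distribution:
        neg_density = rng.choice(
            list(density_distribution.keys()),
            size=n_negative,
            p=np.array(list(density_distribution.values()), dtype=float) / n_positive,
        )
    elif n_negative:
        neg_density = rng.choice(list(DENSITY_CLASSES), size=n_negative)
    else:
        neg_density = []
    for i in range(n_negative):
        spec = PhantomSpec(
            shape=shape,
            density_class=str(neg_density[i]),
            lesions=(),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        img, anns = compose_phantom(spec)
        samples.append(PhantomSample(image=img, annotations=tuple(anns), spec=spec))
    return samples
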