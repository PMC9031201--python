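# Methods

## The detection model

The nested-contours algorithm treats a mammographic mass as the projection
of a compact 3-D lesion: brightness rises monotonically toward the interior,
so the level sets around a mass are closed curves that shrink steadily and
stay mutually similar as the level rises.  The implementation builds
marching-squares iso-contours (sub-pixel linear interpolation) at levels
`min + j·k` for `j = 1, 2, …` strictly below the image maximum.  The image
is padded with its minimum so every contour closes; contours cut by the
image border are thereby closed along the border, which keeps partly
visualized masses detectable.  Only contours enclosing
brighter-than-level regions are kept (masses are radiopaque: bright on
dark; the opposite polarity is not supported).

Chains are linked greedily from the lowest level upward.  Each contour at
level `ℓ+k` is appended to the chain whose level-`ℓ` tip contains it; a tip
containing several next-level contours extends with the largest-area one
(ties broken by smallest centroid shift, for determinism) and the remaining
ones start new chains; a contour with no containing tip starts a new chain.
Containment uses exact polygon coverage with an R-tree bounding-box
pre-filter; for iso-contours of one image the containment relation is a
forest, so each contour has at most one containing tip.

The discard rule compares consecutive contours with

    d(prev, next) = max( |1 − A(next)/A(prev)| ,
                         ‖c(next) − c(prev)‖ / sqrt(A(prev)/π) )

an area-growth term (parenchyma flooding) and a centroid-drift term in
units of the outer contour's equivalent radius (merging with adjacent
structure).  A chain is cut at every step whose area term exceeds
`tau_area` or whose shift term exceeds `tau_shift`.  The contour that
breaks the resemblance is not thrown away together with everything above
it: it starts a chain of its own, so each maximal well-nested segment
survives independently.  This matters on textured backgrounds, where the
chain that tracks a large parenchyma region often collapses onto the
lesion nested inside it; cutting to the prefix alone would lose the lesion
segment entirely.  Segments shallower than `min_depth` or whose outermost
contour area falls outside `[min_area, max_area]` are discarded.

Each surviving segment yields one candidate: representative contour = the
segment's outermost (lowest-level) retained contour, box = its axis-aligned
bounding box, score = depth × 4πA/P² (depth-weighted circularity — deep,
round nests are mass-like; the method itself provides no confidence, so
some ranking is needed for reporting).  Candidates whose boxes nest are
merged keeping the higher-scoring one: a deep circular nest outranks the
shallower structure wrapped around it, which is exactly the dense-background
situation where an irregular complex contour encloses a well-formed mass
nest.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | range/32 | gradation step, intensity units; the relative default makes detection invariant to affine intensity remapping |
| `min_depth` | 3 | minimum chain length for a mass |
| `tau_area` | 0.5 | max per-step area-ratio deviation |
| `tau_shift` | 0.5 | max per-step centroid shift, equivalent radii |
| `min_area` / `max_area` | 25 px² / 25% of image | bounds on the candidate's outer contour |
| `min_contour_area` | 4 px² | numerical floor: sub-resolution specks carry no shape information and are discarded before geometry is built |

All thresholds are configurable; the defaults aim to be scale-robust rather
than tuned to any particular acquisition.

## Pre-processing chain (for the CNN branch; the NCA runs on raw images)

1. **Truncation normalization** — effective bounds are intensity
   percentiles of the non-zero (breast) pixels at `low_fraction` and
   `1 − high_fraction` (defaults 0.01); a fraction of 0 means no truncation
   on that side, so the operation reduces to a pure min–max stretch.
   Intensities are clipped to the bounds and rescaled to the full bit-depth
   range.  Degenerate images (no dynamic range, or coincident bounds) are
   rejected explicitly.
2. **CLAHE** — classical tile-grid form (default 8×8): per-tile histograms
   clipped at `clip_limit` times the uniform bin height with the excess
   redistributed uniformly, equalization tables per tile, bilinear blending
   between the four surrounding tiles per pixel.  Flat tiles keep an
   identity mapping (equalizing them would invent contrast from nothing).
   With one tile and a large clip limit the operation reduces to textbook
   global histogram equalization, which the tests exploit as an oracle.
3. **3-channel synthesis** — channel 1 is the truncated/normalized image,
   channels 2 and 3 its CLAHE enhancements at clip limits 1.0 and 2.0
   (both configurable; the two limits must differ).

## Augmentation

`eightfold_augment` draws, per output, a uniform rotation angle in
[0°, 360°), two Bernoulli(0.5) mirrors and a uniform translation within
±10% of each dimension; corners exposed by the transform are filled with 0
(the mammographic background).  Boxes are mapped through the same affine,
re-axis-aligned as the bounding box of their transformed corners, clipped,
and dropped if no area remains.  The rotation-angle distribution and shift
range are this package's choices (the operators themselves are standard);
shifts pad rather than wrap.  `mosaic` scales each of exactly four inputs
into one quadrant around a center drawn uniformly from the central half of
the output, remaps boxes through the same scaling, and drops boxes losing
more than 80% of their area.  Both operators are bit-reproducible by seed.

## The phantom generator

Phantoms are deliberately stylized.  They exercise the detector's nesting
logic across the clinically meaningful difficulty spectrum — they do not
simulate radiographic physics, scatter, or the anatomy of real parenchyma,
so phantom results say nothing quantitative about clinical sensitivity.

* **Background**: a half-elliptical breast support against the left edge;
  base brightness and band-limited texture (white noise smoothed with a
  Gaussian of σ = min(H, W)/20, unit RMS) both rise with the ACR density
  class — means 60/90/120/150 and texture amplitudes 4/8/14/22 intensity
  units for classes A/B/C/D at 8 bits.  Pixel noise is additive Gaussian
  (σ = 2 by default) rather than Poisson: simpler, and sufficient for
  contour-stability testing.
* **Lesions** (six appearance types): star-like = Gaussian core
  (σ = size/4) plus thin radial ridges with Gaussian angular profile and
  Gaussian radial falloff of scale 0.55·size — spicule length of the order
  of the lesion radius, so the lesion has a well-defined overall footprint;
  unclear-border = broad Gaussian; round/oval = flat ellipse with a sharp
  sigmoid edge; asymmetric density = rotated anisotropic blob;
  invisible-on-dense-background = wide faint blob whose contrast default
  (0.12) sits at the texture amplitude of dense backgrounds;
  partly-visualized = a clear round mass centered off the image edge so
  ≥ 30% of it is outside.  Per-type default contrasts (0.80/0.45/0.90/
  0.30/0.12/0.85 of the available headroom) encode the clinical difficulty
  ordering.
* **Ground truth**: a lesion's truth mask is where its *added* intensity is
  discernible — at least the local fluctuation floor (2·noise σ + texture
  amplitude of the class), clamped between 10% and 50% of the added peak so
  faint lesions keep a non-empty annotation.  The truth box is the tight
  axis-aligned box of that mask clipped to the image.  Annotating at a
  fixed small fraction of the peak instead would label spicule tails lying
  far below the texture of dense backgrounds, extents no reader (human or
  algorithmic) could reproduce.
* **Test set**: 100 single-lesion positives with exact type counts
  16/30/8/28/16/2 and ACR density counts 27/33/31/9, plus 100 lesion-free
  negatives drawing their density from the same proportions; image size
  512×512 at 8 bits (full mammography resolution is unnecessary for
  desk-scale experiments).  Everything is reproducible from one seed.

## Evaluation conventions

* Boxes are 0-based, half-open, x = column, y = row — stated once, enforced
  by validators everywhere.
* Matching is greedy in descending score with one-to-one assignment.  Two
  qualification rules are provided: the benchmark rule (IoU ≥ 0.5, the
  default of `match_detections`) and the clinical marking rule
  (`mode="marking"`: IoU ≥ 0.5 *or* mutual center containment), which
  captures "the detector marked the lesion" even when the traced contour
  wraps adjacent structure and dilutes the IoU.  The end-to-end pipeline
  uses the marking rule by default, mirroring how clinical reading counts
  a hit; per-lesion-type tables record per-image binary outcomes (lesion
  marked or not; any spurious marking sets the image's FP flag), and
  detections on lesion-free images are tallied separately.
* F_beta uses the linear-in-beta denominator (1+β²)·P·R/(β·P+R).  This is
  not the textbook β² weighting; it is the form whose published reference
  values the package reproduces, and it is applied to the
  two-decimal-truncated precision and recall for the same reason.  Report
  rounding supports `truncate_2dp` (default) and `round_2dp`.
* The two-proportion comparison is a two-sided chi-square test on the 2×2
  table without continuity correction — the variant consistent with the
  reference p-value of 0.059 for 14/30 vs 7/30.

## Known limitations

* The discard rule is strictly per-step.  A chain that morphs *gradually*
  from an irregular parenchyma complex onto a small lesion can pass every
  consecutive-step test while shrinking several-fold overall; its
  representative (outermost) contour then overstates the lesion extent.
  This is the dominant failure mode on small lesions in class C/D phantoms
  and the reason the marking rule and the IoU rule disagree there.  A
  cumulative-similarity criterion would be the natural extension.
* Phantom backgrounds have stationary texture; real parenchyma has
  oriented, non-stationary structure (ducts, Cooper ligaments) that
  produces qualitatively different false positives.
* The detector assumes bright-on-dark polarity and a single brightness
  maximum per mass; ring-like or multi-focal enhancement patterns are out
  of scope.
* Lesion-free phantom images still contain texture maxima, and roughly
  87/100 of them receive at least one candidate under default parameters —
  consistent with the method's known high false-positive marking rate;
  downstream filtering is deliberately out of scope.
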