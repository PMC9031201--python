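"""Tests of the nested-contours detector, anchored on analytic level sets.

The main oracle is the isotropic Gaussian peak A*exp(-r^2 / 2 sigma^2): its
iso-contour at level L is the circle of radius sigma*sqrt(2*ln(A/L)), which
pins down contour counts, radii, nesting and chain depth in closed form.
"""

import math

import numpy as np
import pytest

from nca.core import (
    ContourNest,
    IsoContour,
    NCAParams,
    build_level_contours,
    contains,
    detect_lesions,
    link_nested_chains,
    prune_chains,
    step_dissimilarity,
)


def circle(cx, cy, r, n=256, level=0.0):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return IsoContour(level=level, vertices=np.c_[cx + r * np.cos(t), cy + r * np.sin(t)])


def square(x0, y0, side, level=0.0):
    return IsoContour(
        level=level,
        vertices=np.array(
            [[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]],
            dtype=float,
        ),
    )


class TestBuildLevelContours:
    def test_constant_image_yields_nothing(self):
        assert build_level_contours(np.full((32, 32), 7, dtype=np.uint8), 5) == []

    def test_gaussian_radii_match_analytic_level_sets(self, gaussian_peak):
        contours = build_level_contours(gaussian_peak, 10.0)
        levels = sorted(c.level for c in contours)
        assert levels == pytest.approx([10.0 * j for j in range(1, 10)])
        for c in contours:
            r_expected = 10.0 * math.sqrt(2 * math.log(100.0 / c.level))
            r_measured = math.sqrt(c.area / math.pi)
            assert r_measured == pytest.approx(r_expected, abs=0.15)

    def test_two_separated_peaks_give_two_contours_per_level(self, two_peaks):
        contours = build_level_contours(two_peaks, 20.0)
        by_level = {}
        for c in contours:
            by_level.setdefault(round(c.level), []).append(c)
        for level, group in by_level.items():
            assert len(group) == 2, f"level {level}"

    def test_border_touching_mass_is_closed_along_border(self):
        # half a Gaussian hangs off the left edge: contours must still close
        y, x = np.mgrid[0:64, 0:64]
        img = 100.0 * np.exp(-((x + 5) ** 2 + (y - 32) ** 2) / (2 * 12.0**2))
        contours = build_level_contours(img, 20.0)
        assert contours, "partly visualized mass must still produce contours"
        for c in contours:
            assert c.vertices[:, 0].min() >= 0.0
            assert c.area > 0

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            build_level_contours(np.eye(8), 0.0)


class TestContains:
    def test_concentric_squares(self):
        assert contains(square(0, 0, 10), square(3, 3, 4))

    def test_disjoint_squares(self):
        assert not contains(square(0, 0, 4), square(10, 10, 4))

    def test_overlapping_non_nested_l_shapes(self):
        outer = IsoContour(
            level=0,
            vertices=np.array(
                [[0, 0], [8, 0], [8, 3], [3, 3], [3, 8], [0, 8]], dtype=float
            ),
        )
        inner = IsoContour(
            level=1,
            vertices=np.array(
                [[2, 2], [10, 2], [10, 5], [5, 5], [5, 10], [2, 10]], dtype=float
            ),
        )
        assert not contains(outer, inner)
        assert not contains(inner, outer)


class TestStepDissimilarity:
    def test_identical_contours_give_zero(self):
        a, b = circle(50, 50, 10), circle(50, 50, 10)
        assert step_dissimilarity(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_concentric_discs_area_term(self):
        # areas 100*pi and 64*pi: |1 - 64/100| = 0.36
        assert step_dissimilarity(circle(50, 50, 10), circle(50, 50, 8)) == pytest.approx(
            0.36, abs=1e-6
        )

    def test_shifted_equal_disc_shift_term(self):
        # equivalent radius of a disc is its radius, so a shift by r
        # normalizes to exactly 1
        v = step_dissimilarity(circle(50, 50, 10), circle(60, 50, 10))
        assert v == pytest.approx(1.0, rel=1e-3)


class TestLinking:
    def test_gaussian_contours_form_single_depth_nine_chain(self, gaussian_peak):
        contours = build_level_contours(gaussian_peak, 10.0)
        nests = link_nested_chains(contours, NCAParams())
        assert len(nests) == 1
        assert nests[0].depth == 9
        levels = [c.level for c in nests[0].contours]
        assert levels == sorted(levels)

    def test_two_peaks_form_two_chains(self, two_peaks):
        contours = build_level_contours(two_peaks, 20.0)
        nests = link_nested_chains(contours, NCAParams())
        assert len(nests) == 2

    def test_empty_input(self):
        assert link_nested_chains([], NCAParams()) == []

    def test_nesting_soundness(self, two_peaks):
        contours = build_level_contours(two_peaks, 10.0)
        for nest in link_nested_chains(contours, NCAParams()):
            for outer, inner in zip(nest.contours[:-1], nest.contours[1:]):
                assert contains(outer, inner)

    def test_matches_brute_force_oracle_on_small_images(self):
        rng = np.random.default_rng(11)
        for trial in range(12):
            img = (rng.integers(0, 4, size=(rng.integers(8, 33), rng.integers(8, 33)))
                   * 60).astype(np.uint8)
            contours = build_level_contours(img, 60.0)
            got = link_nested_chains(contours, NCAParams())
            expected = _brute_force_chains(contours)
            got_keys = sorted(
                tuple((round(c.level, 6), round(c.area, 6)) for c in n.contours)
                for n in got
            )
            exp_keys = sorted(
                tuple((round(c.level, 6), round(c.area, 6)) for c in chain)
                for chain in expected
            )
            assert got_keys == exp_keys, f"trial {trial}"


def _brute_force_chains(contours):
    """Independent chain construction from the full containment matrix."""
    if not contours:
        return []
    levels = sorted({c.level for c in contours})
    by_level = {lv: [c for c in contours if c.level == lv] for lv in levels}
    chains = [[c] for c in by_level[levels[0]]]
    for prev_lv, lv in zip(levels[:-1], levels[1:]):
        tips = [ch for ch in chains if ch[-1].level == prev_lv]
        children = {id(ch): [] for ch in tips}
        fresh = []
        for c in by_level[lv]:
            parents = [ch for ch in tips if contains(ch[-1], c)]
            if not parents:
                fresh.append([c])
                continue
            parent = min(parents, key=lambda ch: ch[-1].area)
            children[id(parent)].append(c)
        for ch in tips:
            kids = children[id(ch)]
            if not kids:
                continue
            def shift(c, tip=ch[-1]):
                return math.hypot(
                    c.centroid[0] - tip.centroid[0], c.centroid[1] - tip.centroid[1]
                )
            kids.sort(key=lambda c: (-c.area, shift(c)))
            ch.append(kids[0])
            fresh.extend([k] for k in kids[1:])
        chains.extend(fresh)
    return chains


class TestPruning:
    def test_smooth_chain_with_generous_thresholds_kept_intact(self, gaussian_peak):
        contours = build_level_contours(gaussian_peak, 10.0)
        nests = link_nested_chains(contours, NCAParams())
        params = NCAParams(tau_area=10.0, tau_shift=10.0, min_depth=2, min_area=1.0)
        pruned = prune_chains(nests, params, image_area=128 * 128)
        assert len(pruned) == 1
        assert pruned[0].depth == 9

    def test_area_jump_truncates_then_depth_filter_drops(self):
        # 3rd contour 10x larger in linear scale: area step blows through tau
        chain = ContourNest(
            contours=(
                circle(50, 50, 20, level=10),
                circle(50, 50, 18, level=20),
                circle(50, 50, 5, level=30),
                circle(50, 50, 4, level=40),
            )
        )
        params = NCAParams(min_depth=3, min_area=1.0)
        pruned = prune_chains([chain], params, image_area=1e6)
        # both resulting segments are depth 2 -> everything dropped
        assert pruned == []
        params2 = NCAParams(min_depth=2, min_area=1.0)
        depths = sorted(n.depth for n in prune_chains([chain], params2, image_area=1e6))
        assert depths == [2, 2]

    def test_empty_input(self):
        assert prune_chains([], NCAParams()) == []

    def test_outer_area_bounds_enforced(self, gaussian_peak):
        contours = build_level_contours(gaussian_peak, 10.0)
        nests = link_nested_chains(contours, NCAParams())
        tiny_max = NCAParams(min_depth=2, min_area=1.0, max_area=10.0)
        assert prune_chains(nests, tiny_max, image_area=None) == []


class TestDetectLesions:
    def test_constant_background_yields_nothing(self):
        assert detect_lesions(np.full((64, 64), 40, dtype=np.uint8)) == []

    def test_single_mass_detected_with_box_over_center(self, gaussian_peak):
        img = np.rint(gaussian_peak).astype(np.uint8)
        cands = detect_lesions(img)
        assert len(cands) == 1
        box = cands[0].box
        assert box.x_min < 64 < box.x_max and box.y_min < 64 < box.y_max
        assert cands[0].depth >= NCAParams().min_depth

    def test_two_masses_give_two_disjoint_boxes(self, two_peaks):
        img = np.rint(two_peaks).astype(np.uint8)
        cands = detect_lesions(img)
        assert len(cands) == 2
        a, b = cands[0].box, cands[1].box
        assert a.x_max <= b.x_min or b.x_max <= a.x_min

    def test_determinism(self, two_peaks):
        img = np.rint(two_peaks).astype(np.uint8)
        first = detect_lesions(img)
        second = detect_lesions(img)
        assert len(first) == len(second)
        for c1, c2 in zip(first, second):
            assert c1.box == c2.box
            assert c1.score == c2.score
            assert np.array_equal(c1.contour.vertices, c2.contour.vertices)

    def test_affine_intensity_invariance(self, gaussian_peak):
        # levels are placed relative to the brightness range, so a*I + b
        # must yield the same candidate geometry
        img8 = np.rint(gaussian_peak).astype(np.uint8)
        img16 = (img8.astype(np.uint16) * 37) + 1000
        base = detect_lesions(img8)
        scaled = detect_lesions(img16)
        assert len(base) == len(scaled) == 1
        for cb, cs in zip(base, scaled):
            assert cb.box.x_min == pytest.approx(cs.box.x_min, abs=1e-6)
            assert cb.box.y_min == pytest.approx(cs.box.y_min, abs=1e-6)
            assert cb.box.x_max == pytest.approx(cs.box.x_max, abs=1e-6)
            assert cb.box.y_max == pytest.approx(cs.box.y_max, abs=1e-6)
            assert cb.depth == cs.depth

    def test_min_depth_monotonicity(self, two_peaks):
        img = np.rint(two_peaks).astype(np.uint8)
        counts = [
            len(detect_lesions(img, NCAParams(min_depth=d))) for d in (2, 3, 5, 8, 12)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_scores_sorted_descending(self, two_peaks):
        img = np.rint(two_peaks).astype(np.uint8)
        cands = detect_lesions(img)
        scores = [c.score for c in cands]
        assert scores == sorted(scores, reverse=True)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k": -1.0},
            {"min_depth": 1},
            {"tau_area": 0.0},
            {"tau_shift": -0.5},
            {"min_area": 30.0, "max_area": 20.0},
            {"polarity": "dark_on_bright"},
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            NCAParams(**kwargs)
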