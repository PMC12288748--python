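"""The 19 pattern measurements against analytic and brute-force oracles."""

import colorsys

import numpy as np
import pytest

import scutepattern as sp
from scutepattern.extraction import BinaryPattern
from scutepattern.measures import MEASURE_NAMES, convex_hull_pixels

from conftest import flat_image, rect_scute


def pat(arr, mpp=1.0):
    return BinaryPattern(np.asarray(arr, bool), mpp)


def flood_fill_labels(arr, connectivity=8):
    """Brute-force connected components by BFS, as an independent oracle.

    Returns the partition of pixel coordinates as a set of frozensets.
    """
    arr = np.asarray(arr, bool)
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = set()
    comps = set()
    for r, c in map(tuple, np.argwhere(arr)):
        if (r, c) in seen:
            continue
        comp, stack = set(), [(r, c)]
        while stack:
            p = stack.pop()
            if p in comp:
                continue
            comp.add(p)
            for dr, dc in nbrs:
                q = (p[0] + dr, p[1] + dc)
                if (
                    0 <= q[0] < arr.shape[0]
                    and 0 <= q[1] < arr.shape[1]
                    and arr[q]
                    and q not in comp
                ):
                    stack.append(q)
        seen |= comp
        comps.add(frozenset(comp))
    return comps


class TestLabelObjects:
    def test_two_squares(self):
        arr = np.zeros((10, 12), bool)
        arr[1:4, 1:4] = True
        arr[6:9, 7:10] = True
        objs = sp.label_objects(pat(arr, mpp=0.5))
        assert len(objs) == 2
        assert sorted(o.pixel_count for o in objs.objects) == [9, 9]
        assert objs.objects[0].area_mm2 == pytest.approx(9 * 0.25)
        assert objs.objects[0].centroid == (2.0, 2.0)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(3)
        for _ in range(5):
            arr = rng.random((30, 30)) < 0.4
            objs = sp.label_objects(pat(arr), connectivity)
            got = set()
            for o in objs.objects:
                got.add(frozenset(map(tuple, np.argwhere(objs.labels == o.label))))
            assert got == flood_fill_labels(arr, connectivity)

    def test_eccentricity_extremes(self):
        disc = np.zeros((40, 40), bool)
        rr, cc = np.mgrid[0:40, 0:40]
        disc |= (rr - 20) ** 2 + (cc - 20) ** 2 <= 15**2
        assert sp.label_objects(pat(disc)).eccentricities[0] < 0.1
        line = np.zeros((40, 40), bool)
        line[20, 5:35] = True
        assert sp.label_objects(pat(line)).eccentricities[0] > 0.99

    def test_single_pixel_eccentricity_zero(self):
        arr = np.zeros((5, 5), bool)
        arr[2, 2] = True
        assert sp.label_objects(pat(arr)).eccentricities[0] == 0.0

    def test_areas_partition_pattern(self):
        rng = np.random.default_rng(4)
        arr = rng.random((30, 30)) < 0.3
        objs = sp.label_objects(pat(arr))
        assert objs.pixel_counts.sum() == arr.sum()

    def test_empty_pattern(self):
        assert len(sp.label_objects(pat(np.zeros((5, 5))))) == 0


class TestFractionalArea:
    def test_trivials(self):
        mask = rect_scute((16, 16), (0, 0, 16, 16))
        assert sp.fractional_area(pat(mask.mask), mask) == 1.0
        assert sp.fractional_area(pat(np.zeros((16, 16))), mask) == 0.0
        quarter = np.zeros((16, 16), bool)
        quarter[:8, :8] = True
        assert sp.fractional_area(pat(quarter), mask) == 0.25


class TestPeakLength:
    def test_stripe_wavelength(self):
        # vertical stripes of period 8 px (4 on, 4 off) in a rectangular scute
        shape = (40, 64)
        mask = rect_scute(shape, (0, 0, *shape))
        arr = np.zeros(shape, bool)
        for c0 in range(0, 64, 8):
            arr[:, c0 : c0 + 4] = True
        mpp = 0.25
        pl = sp.peak_length(pat(arr, mpp), mask)
        assert pl == pytest.approx(8 * mpp, abs=2 * mpp)

    def test_empty_pattern_uses_background_skeleton(self):
        shape = (12, 30)
        mask = rect_scute(shape, (0, 0, *shape))
        from skimage.morphology import skeletonize

        sk_neg = int(skeletonize(mask.mask).sum())
        pl = sp.peak_length(pat(np.zeros(shape)), mask)
        assert pl == pytest.approx(2 * mask.n_pixels / sk_neg)


class TestPerimeterArea:
    def test_square_ratio(self):
        arr = np.zeros((20, 20), bool)
        arr[5:15, 5:15] = True  # 10 x 10 square
        mpp = 0.3
        objs = sp.label_objects(pat(arr, mpp))
        pa = sp.perimeter_area_ratio(objs)
        assert pa == pytest.approx(4 / 10 / mpp, rel=0.15)

    def test_duplicated_object_same_ratio(self):
        arr1 = np.zeros((20, 40), bool)
        arr1[5:15, 5:15] = True
        arr2 = arr1.copy()
        arr2[5:15, 25:35] = True
        pa1 = sp.perimeter_area_ratio(sp.label_objects(pat(arr1)))
        pa2 = sp.perimeter_area_ratio(sp.label_objects(pat(arr2)))
        assert pa1 == pytest.approx(pa2)

    def test_empty_is_nan(self):
        assert np.isnan(sp.perimeter_area_ratio(sp.label_objects(pat(np.zeros((4, 4))))))


class TestMeanHSB:
    def test_pure_red(self):
        img = flat_image((6, 6), (0.8, 0.0, 0.0))
        p = pat(np.ones((6, 6)))
        h, s, b = sp.mean_hsb(img, p)
        assert h == pytest.approx(0.0)
        assert s == pytest.approx(1.0)
        assert b == pytest.approx(0.8)

    def test_gray_is_unsaturated(self):
        img = flat_image((6, 6), (0.4, 0.4, 0.4))
        _, s, _ = sp.mean_hsb(img, pat(np.ones((6, 6))))
        assert s == pytest.approx(0.0)

    def test_mixed_patch_matches_colorsys(self):
        img = flat_image((2, 2), (0, 0, 0))
        img.pixels[0, 0] = (0.8, 0.2, 0.1)
        img.pixels[0, 1] = (0.1, 0.6, 0.9)
        img.pixels[1, 0] = (0.3, 0.3, 0.3)
        img.pixels[1, 1] = (0.9, 0.9, 0.1)
        p = pat(np.ones((2, 2)))
        got = sp.mean_hsb(img, p)
        hsv = [colorsys.rgb_to_hsv(*img.pixels[i, j]) for i in (0, 1) for j in (0, 1)]
        expect = np.mean(hsv, axis=0)
        assert got == pytest.approx(tuple(expect), abs=1e-12)

    def test_empty_pattern_nan(self):
        img = flat_image((4, 4), (0.5, 0.5, 0.5))
        assert all(np.isnan(v) for v in sp.mean_hsb(img, pat(np.zeros((4, 4)))))


class TestChannelContrasts:
    def two_tone(self):
        shape = (10, 10)
        img = flat_image(shape, (0.2, 0.15, 0.1))
        arr = np.zeros(shape, bool)
        arr[2:6, 2:6] = True
        img.pixels[arr] = (0.5, 0.55, 0.1)
        mask = rect_scute(shape, (0, 0, *shape))
        return img, pat(arr), mask

    def test_exact_values(self):
        img, p, mask = self.two_tone()
        c = sp.channel_contrasts(img, p, mask)
        assert c["RC"] == pytest.approx(0.3)
        assert c["GC"] == pytest.approx(0.4)
        assert c["BC"] == pytest.approx(0.0, abs=1e-12)
        assert c["ED"] == pytest.approx(0.5)  # 3-4-5 triangle
        # yellow = min(R, G): 0.5 vs 0.15
        assert c["YC"] == pytest.approx(0.35)
        w = (0.2989, 0.5870, 0.1140)
        ic = sum(a * b for a, b in zip(w, (0.5, 0.55, 0.1))) - sum(
            a * b for a, b in zip(w, (0.2, 0.15, 0.1))
        )
        assert c["IC"] == pytest.approx(ic)

    def test_identical_colors_zero(self):
        img = flat_image((8, 8), (0.3, 0.2, 0.1))
        arr = np.zeros((8, 8), bool)
        arr[2:4, 2:4] = True
        mask = rect_scute((8, 8), (0, 0, 8, 8))
        c = sp.channel_contrasts(img, pat(arr), mask)
        for k in ("RC", "GC", "BC", "YC", "IC", "ED"):
            assert c[k] == pytest.approx(0.0, abs=1e-12)

    def test_direct_recomputation_on_scene(self, analyzed_scene):
        _, cal, mask, pattern, _ = analyzed_scene
        c = sp.channel_contrasts(cal, pattern, mask)
        bg = mask.mask & ~pattern.pattern
        for i, k in enumerate(("RC", "GC", "BC")):
            direct = cal.pixels[..., i][pattern.pattern].mean() - cal.pixels[..., i][bg].mean()
            assert c[k] == pytest.approx(direct, abs=1e-12)
        assert c["ED"] == pytest.approx(np.sqrt(c["RC"]**2 + c["GC"]**2 + c["BC"]**2), abs=1e-12)


class TestCentralityRatio:
    def test_central_dot_below_one(self):
        shape = (21, 21)
        mask = rect_scute(shape, (0, 0, *shape))
        arr = np.zeros(shape, bool)
        arr[9:12, 9:12] = True
        assert sp.centrality_ratio(pat(arr), mask) < 1.0

    def test_direct_recomputation(self, analyzed_scene):
        _, _, mask, pattern, _ = analyzed_scene
        cy, cx = np.argwhere(mask.mask).mean(axis=0)
        d = lambda m: np.hypot(*(np.argwhere(m) - (cy, cx)).T).mean()
        expect = d(pattern.pattern & mask.mask) / d(mask.mask & ~pattern.pattern)
        assert sp.centrality_ratio(pattern, mask) == pytest.approx(expect, abs=1e-12)


class TestOccupationFactor:
    def test_convex_pattern_equals_fa(self):
        shape = (20, 20)
        mask = rect_scute(shape, (0, 0, *shape))
        arr = np.zeros(shape, bool)
        arr[4:12, 6:15] = True
        p = pat(arr)
        assert sp.occupation_factor(p, mask) == pytest.approx(sp.fractional_area(p, mask))

    def test_two_distant_dots_hull_much_larger(self):
        shape = (30, 30)
        mask = rect_scute(shape, (0, 0, *shape))
        arr = np.zeros(shape, bool)
        arr[2:4, 2:4] = True
        arr[26:28, 26:28] = True
        p = pat(arr)
        assert sp.occupation_factor(p, mask) > 5 * sp.fractional_area(p, mask)

    def test_hull_matches_half_plane_oracle(self):
        from scipy.spatial import ConvexHull

        rng = np.random.default_rng(5)
        for _ in range(5):
            arr = rng.random((25, 25)) < 0.1
            if arr.sum() < 3:
                continue
            got = convex_hull_pixels(arr)
            # oracle: hull of pixel corner points, count pixel centers inside
            pts = np.argwhere(arr).astype(float)
            corners = np.concatenate(
                [pts + d for d in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
            )
            hull = ConvexHull(corners)
            rr, cc = np.mgrid[0:25, 0:25]
            centers = np.column_stack([rr.ravel(), cc.ravel(), np.ones(625)])
            inside = (centers @ hull.equations.T <= 1e-9).all(axis=1)
            # boundary pixels may tie differently between the two routes
            assert abs(got - int(inside.sum())) <= 0.02 * max(got, 1) + 2

    def test_of_at_least_fa(self, analyzed_scene):
        _, _, mask, pattern, _ = analyzed_scene
        assert sp.occupation_factor(pattern, mask) >= sp.fractional_area(pattern, mask)


class TestNormalizedOffset:
    def test_centered_pattern_zero(self):
        shape = (21, 21)
        mask = rect_scute(shape, (0, 0, *shape))
        arr = np.zeros(shape, bool)
        arr[9:12, 9:12] = True
        assert sp.normalized_offset(pat(arr), mask) == pytest.approx(0.0)

    def test_offset_dot_analytic(self):
        shape = (21, 21)
        mask = rect_scute(shape, (0, 0, *shape))  # centroid (10, 10), N = 441
        arr = np.zeros(shape, bool)
        arr[10, 16] = True  # distance 6
        assert sp.normalized_offset(pat(arr), mask) == pytest.approx(6 / np.sqrt(441))


class TestMeasureAll:
    def test_exactly_19_measures(self, analyzed_scene):
        _, cal, mask, pattern, _ = analyzed_scene
        ms = sp.measure_all(cal, mask, pattern)
        assert set(ms.values) == set(MEASURE_NAMES)
        assert len(MEASURE_NAMES) == 19

    def test_three_discs_count_and_area(self):
        spec = sp.random_disc_scene(seed=21, n_objects=3, radius_mm_range=(2.5, 2.5))
        img, gt = sp.generate_scene(spec)
        mask = sp.extract_scute_mask(img)
        cal = sp.calibrate_gray_card(img, spec.card_rect, mm_per_pixel=spec.mm_per_pixel)
        pattern = sp.extract_pattern(cal, mask)
        ms = sp.measure_all(cal, mask, pattern)
        assert ms["Ob"] == 3
        assert ms["OA"] == pytest.approx(np.pi * 2.5**2, rel=0.05)

    def test_empty_pattern_sentinels(self):
        shape = (16, 16)
        mask = rect_scute(shape, (0, 0, *shape))
        img = flat_image(shape, (0.3, 0.3, 0.3))
        empty = pat(np.zeros(shape))
        ms = sp.measure_all(img, mask, empty)
        assert ms["FA"] == 0.0
        assert ms["Ob"] == 0
        for k in ("E", "H", "S", "B", "Sy", "RC", "OA", "CR", "OF", "NO"):
            assert np.isnan(ms[k])

    def test_ed_identity_everywhere(self, analyzed_scene):
        _, cal, mask, pattern, _ = analyzed_scene
        ms = sp.measure_all(cal, mask, pattern)
        assert ms["ED"] ** 2 == pytest.approx(
            ms["RC"] ** 2 + ms["GC"] ** 2 + ms["BC"] ** 2, abs=1e-9
        )

    @pytest.mark.parametrize("transform", ["fliplr", "rot90"])
    def test_isometry_invariance(self, analyzed_scene, transform):
        _, cal, mask, pattern, _ = analyzed_scene
        f = {"fliplr": np.fliplr, "rot90": np.rot90}[transform]
        import dataclasses

        from scutepattern.calibration import CalibratedImage, ScuteMask

        cal2 = CalibratedImage(f(cal.pixels).copy(), cal.mm_per_pixel, cal.meta)
        mask2 = ScuteMask(f(mask.mask).copy(), f(mask.outline).copy())
        pattern2 = dataclasses.replace(pattern, pattern=f(pattern.pattern).copy())
        grid = sp.SymmetrySearchGrid(angle_step=15, trans_range=6, refine_angle_step=None)
        m1 = sp.measure_all(cal, mask, pattern, grid)
        m2 = sp.measure_all(cal2, mask2, pattern2, grid)
        for k in MEASURE_NAMES:
            if k in ("PL", "PA"):  # skeleton/perimeter estimates: near-exact
                assert m2[k] == pytest.approx(m1[k], rel=0.01)
            else:
                assert m2[k] == pytest.approx(m1[k], abs=1e-9)
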