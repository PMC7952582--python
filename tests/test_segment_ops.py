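"""Imaging operators checked against hand-rolled, shared-nothing oracles."""

import math

import numpy as np
import pytest
from scipy import signal

from organoquant import (
    SceneParams,
    SegmentationParams,
    apply_area_filter,
    area_histogram,
    canny_edges,
    connected_components,
    fill_holes,
    gaussian_blur,
    measure_objects,
    morph_close,
    morph_open,
    render_scene,
    sample_true_areas,
    segment_organoids,
    smear_edges,
    suggest_tail_cut,
    to_greyscale,
)
from organoquant.segment import OrganoidObject

from oracles import (
    accumulate_measurements,
    border_reachable_fill,
    canny_step_oracle,
    component_areas,
    gaussian_kernel_2d,
    union_find_components,
)


# --------------------------------------------------------------------------- #
# greyscale conversion
# --------------------------------------------------------------------------- #
class TestToGreyscale:
    def test_achromatic_identity(self):
        img = np.full((4, 4, 3), 255, dtype=np.uint8)
        assert np.all(to_greyscale(img) == 255)

    def test_rec601_red_pixel(self):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[0, 0, 0] = 255
        assert to_greyscale(img)[0, 0] == 76  # 0.299 * 255 rounded

    def test_grey_passthrough(self, rng):
        img = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        assert np.array_equal(to_greyscale(img), img)

    def test_rejects_other_channel_counts(self):
        with pytest.raises(ValueError):
            to_greyscale(np.zeros((4, 4, 2)))


# --------------------------------------------------------------------------- #
# gaussian blur
# --------------------------------------------------------------------------- #
class TestGaussianBlur:
    def test_constant_invariance(self):
        img = np.full((16, 16), 37.0)
        assert np.allclose(gaussian_blur(img, 2.5), img)

    def test_sigma_zero_identity(self, rng):
        img = rng.random((8, 8)) * 255
        assert np.array_equal(gaussian_blur(img, 0.0), img)

    def test_impulse_equals_explicit_kernel(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        out = gaussian_blur(img, 1.0)
        kernel = gaussian_kernel_2d(1.0)
        expected = signal.convolve2d(img, kernel, mode="same", boundary="symm")
        assert np.allclose(out, expected, atol=1e-12)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_blur(np.zeros((4, 4)), -1.0)


# --------------------------------------------------------------------------- #
# canny
# --------------------------------------------------------------------------- #
class TestCanny:
    def test_constant_image_no_edges(self):
        assert not canny_edges(np.full((16, 16), 99.0), 10, 50).any()

    def test_step_edge_single_line_matches_oracle(self):
        """Vertical intensity step: one ~1-px line at the step column."""
        img = np.zeros((16, 16))
        img[:, 8] = 100.0
        img[:, 9:] = 200.0
        got = canny_edges(img, 10, 50)
        expected = canny_step_oracle(img, 10, 50)
        assert np.array_equal(got, expected)
        cols = np.unique(np.where(got)[1])
        assert list(cols) == [8]
        assert got.sum() == 14  # all interior rows, 1-px wide

    def test_hard_step_matches_oracle(self):
        """A symmetric 0->200 step keeps both tied NMS columns."""
        img = np.zeros((16, 16))
        img[:, 8:] = 200.0
        got = canny_edges(img, 10, 50)
        expected = canny_step_oracle(img, 10, 50)
        assert np.array_equal(got, expected)
        assert set(np.unique(np.where(got)[1])) == {7, 8}

    def test_thresholds_above_max_gradient_give_empty_mask(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 200.0
        assert not canny_edges(img, 1e6, 2e6).any()

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            canny_edges(np.zeros((8, 8)), 50, 10)


# --------------------------------------------------------------------------- #
# smear
# --------------------------------------------------------------------------- #
class TestSmearEdges:
    def test_empty_mask_stays_empty(self):
        assert not smear_edges(np.zeros((8, 8), bool), 1.5, 0.2).any()

    def test_bridges_collinear_gap(self):
        """Two collinear segments 2 px apart fuse into one component.

        The binarize level (0.1) is below the summed kernel mass in the
        gap (~0.14 by direct convolution), so the fragments must fuse;
        the whole map is cross-checked against an explicit convolution.
        """
        mask = np.zeros((15, 21), bool)
        mask[7, 4:8] = True
        mask[7, 10:14] = True  # gap at columns 8-9
        out = smear_edges(mask, 1.5, 0.1)
        labels = connected_components(out, 8)
        assert labels.max() == 1
        # independent check: explicit convolution with the blur kernel
        kernel = gaussian_kernel_2d(1.5)
        conv = signal.convolve2d(mask.astype(float), kernel, mode="same",
                                 boundary="symm")
        assert np.array_equal(out, conv > 0.1)

    def test_monotone_shrinking_in_level(self, rng):
        mask = rng.random((24, 24)) < 0.1
        prev = None
        for level in (0.05, 0.15, 0.3, 0.6, 0.9):
            out = smear_edges(mask, 1.5, level)
            if prev is not None:
                assert not (out & ~prev).any()  # never grows as level rises
            prev = out

    def test_level_bounds(self):
        with pytest.raises(ValueError):
            smear_edges(np.zeros((4, 4), bool), 1.0, 0.0)
        with pytest.raises(ValueError):
            smear_edges(np.zeros((4, 4), bool), 1.0, 1.0)


# --------------------------------------------------------------------------- #
# morphology
# --------------------------------------------------------------------------- #
class TestMorphology:
    def test_close_bridges_one_pixel_gap(self):
        """Two 3-px blocks a single column apart fuse under a radius-1 disc.

        Hand dilate/erode: the dilation spans the gap everywhere, and the
        erosion keeps the centre-row bridge pixel (its full diamond lies
        inside the dilation) while trimming the top/bottom gap pixels.
        """
        mask = np.zeros((5, 9), bool)
        mask[1:4, 1:4] = True
        mask[1:4, 5:8] = True  # 1-px gap at column 4
        out = morph_close(mask, 1)
        assert out[2, 4] and not out[1, 4] and not out[3, 4]
        assert connected_components(out, 8).max() == 1
        assert not (mask & ~out).any()  # closing is extensive

    def test_close_leaves_solid_rectangle(self):
        mask = np.zeros((12, 12), bool)
        mask[3:9, 2:10] = True
        assert np.array_equal(morph_close(mask, 2), mask)

    def test_open_removes_isolated_pixel(self):
        mask = np.zeros((9, 9), bool)
        mask[4, 4] = True
        assert not morph_open(mask, 1).any()

    def test_open_rounds_square_corners_only(self):
        """Opening a 20x20 square with a radius-1 disc: interior intact,
        exactly the 4 corner pixels rounded off (hand erosion/dilation:
        the diamond element cannot reproduce a right-angle corner)."""
        mask = np.zeros((26, 26), bool)
        mask[3:23, 3:23] = True
        out = morph_open(mask, 1)
        removed = mask & ~out
        assert set(map(tuple, np.argwhere(removed))) == {
            (3, 3), (3, 22), (22, 3), (22, 22),
        }
        assert not (out & ~mask).any()

    @pytest.mark.parametrize("op", [morph_open, morph_close])
    def test_idempotence(self, op, random_masks):
        for mask in random_masks[:10]:
            once = op(mask, 2)
            assert np.array_equal(op(once, 2), once)

    def test_open_subset_close_superset(self, random_masks):
        for mask in random_masks[:10]:
            opened = morph_open(mask, 1)
            closed = morph_close(mask, 1)
            assert not (opened & ~mask).any()   # open(x) <= x
            assert not (mask & ~closed).any()   # x <= close(x)

    def test_parameter_checks(self):
        with pytest.raises(ValueError):
            morph_open(np.zeros((4, 4), bool), 0)
        with pytest.raises(ValueError):
            morph_close(np.zeros((4, 4), bool), 1, 0)


# --------------------------------------------------------------------------- #
# hole filling
# --------------------------------------------------------------------------- #
class TestFillHoles:
    def test_annulus_becomes_disc(self):
        yy, xx = np.mgrid[0:21, 0:21]
        r2 = (yy - 10) ** 2 + (xx - 10) ** 2
        ring = (r2 <= 81) & (r2 >= 36)
        disc = r2 <= 81
        assert np.array_equal(fill_holes(ring, 4), disc)

    def test_no_holes_unchanged(self, random_masks):
        mask = np.zeros((9, 9), bool)
        mask[2:5, 2:5] = True
        mask[0, 8] = True
        assert np.array_equal(fill_holes(mask, 4), mask)

    def test_connectivity_dependent_channel(self):
        """A diagonal-only escape channel seals under 8-connected foreground.

        The pocket drains through a diagonal background path: reachable
        under 8-connected background, sealed under 4-connected background.
        """
        mask = np.array(
            [
                [0, 0, 0, 0, 0],
                [0, 1, 1, 1, 0],
                [0, 1, 0, 1, 0],
                [0, 1, 1, 0, 0],
                [0, 0, 0, 0, 0],
            ],
            dtype=bool,
        )
        for conn in (4, 8):
            got = fill_holes(mask, conn)
            assert np.array_equal(got, border_reachable_fill(mask, conn)), conn
        assert fill_holes(mask, 4)[2, 2]        # sealed: filled
        assert not fill_holes(mask, 8)[2, 2]    # drains diagonally: untouched

    def test_agrees_with_reachability_oracle(self, random_masks):
        for mask in random_masks:
            for conn in (4, 8):
                assert np.array_equal(
                    fill_holes(mask, conn), border_reachable_fill(mask, conn)
                )

    def test_idempotent_and_never_clears_foreground(self, random_masks):
        for mask in random_masks[:10]:
            out = fill_holes(mask, 4)
            assert not (mask & ~out).any()
            assert np.array_equal(fill_holes(out, 4), out)


# --------------------------------------------------------------------------- #
# connected components
# --------------------------------------------------------------------------- #
class TestConnectedComponents:
    def test_two_blocks(self):
        mask = np.zeros((6, 6), bool)
        mask[0:2, 0:2] = True
        mask[4:6, 4:6] = True
        labels = connected_components(mask, 8)
        assert labels.max() == 2
        assert component_areas(labels) == [4, 4]

    def test_diagonal_pair_connectivity(self):
        mask = np.array([[1, 0], [0, 1]], dtype=bool)
        assert connected_components(mask, 8).max() == 1
        assert connected_components(mask, 4).max() == 2
        oracle = union_find_components(mask, 4)
        assert component_areas(connected_components(mask, 4)) == component_areas(oracle)

    def test_empty_mask(self):
        labels = connected_components(np.zeros((5, 5), bool), 8)
        assert labels.max() == 0

    def test_raster_discovery_order(self):
        mask = np.zeros((5, 5), bool)
        mask[4, 0] = True   # later in raster order
        mask[0, 4] = True   # earlier
        labels = connected_components(mask, 8)
        assert labels[0, 4] == 1
        assert labels[4, 0] == 2

    def test_agrees_with_union_find_oracle(self, random_masks):
        for mask in random_masks[:12]:
            for conn in (4, 8):
                got = connected_components(mask, conn)
                oracle = union_find_components(mask, conn)
                assert got.max() == oracle.max()
                assert component_areas(got) == component_areas(oracle)


# --------------------------------------------------------------------------- #
# measurement
# --------------------------------------------------------------------------- #
class TestMeasureObjects:
    def test_single_block_mean(self):
        labels = np.zeros((4, 4), int)
        labels[1:3, 1:3] = 1
        img = np.zeros((4, 4))
        img[1:3, 1:3] = [[10, 20], [30, 40]]
        (obj,) = measure_objects(labels, img)
        assert obj.area_px == 4
        assert obj.mean_intensity == 25.0
        assert obj.bbox == (1, 1, 3, 3)

    def test_centroid_by_symmetry(self):
        labels = np.zeros((5, 5), int)
        labels[0:3, 0:3] = 1
        (obj,) = measure_objects(labels, np.ones((5, 5)))
        assert obj.centroid == (1.0, 1.0)

    def test_matches_accumulation_oracle(self, rng):
        labels = np.zeros((16, 16), int)
        labels[1:6, 2:8] = 1
        labels[8:14, 1:5] = 2
        labels[9:15, 9:15] = 3
        img = rng.random((16, 16)) * 255
        objs = measure_objects(labels, img)
        oracle = accumulate_measurements(labels, img)
        assert len(objs) == 3
        for o in objs:
            ref = oracle[o.label]
            assert o.area_px == ref["area"]
            assert o.centroid == pytest.approx(ref["centroid"])
            assert o.mean_intensity == pytest.approx(ref["mean_intensity"])
        # pixel conservation
        assert sum(o.area_px for o in objs) == int((labels > 0).sum())

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            measure_objects(np.zeros((4, 4), int), np.zeros((5, 5)))


# --------------------------------------------------------------------------- #
# area filter & histogram
# --------------------------------------------------------------------------- #
def _obj(area: int) -> OrganoidObject:
    return OrganoidObject(label=1, area_px=area, centroid=(0.0, 0.0),
                          bbox=(0, 0, 1, 1), mean_intensity=0.0)


class TestAreaFilter:
    def test_tail_threshold_boundary_inclusive(self):
        """Objects *above* 40,000 px are noise; exactly 40,000 is retained."""
        objs = [_obj(a) for a in (100, 39_999, 40_000, 40_001)]
        kept = apply_area_filter(objs, max_area_px=40_000)
        assert [o.area_px for o in kept] == [100, 39_999, 40_000]

    def test_empty_input(self):
        assert apply_area_filter([], 40_000) == []

    def test_retention_monotone_in_threshold(self, rng):
        for _ in range(20):
            objs = [_obj(int(a)) for a in rng.integers(1, 100_000, size=30)]
            counts = [
                len(apply_area_filter(objs, max_area_px=t))
                for t in sorted(rng.integers(1, 120_000, size=10))
            ]
            assert counts == sorted(counts)


class TestAreaHistogram:
    def test_single_bin(self):
        edges, counts = area_histogram([1, 1, 1], 1)
        assert counts.tolist() == [3]
        assert len(edges) == 2

    def test_counts_conserved(self, rng):
        for _ in range(10):
            areas = rng.integers(1, 5000, size=rng.integers(1, 200))
            edges, counts = area_histogram(areas, 13)
            assert counts.sum() == len(areas)
            assert np.all(np.diff(edges) > 0)

    def test_invalid_bins(self):
        with pytest.raises(ValueError):
            area_histogram([1, 2], 0)

    def test_tail_cut_separates_planted_outliers(self, rng):
        """The suggested cut lands between the main mass and planted outliers."""
        areas = sample_true_areas(SceneParams(), 300, rng=rng).astype(float)
        p99 = np.quantile(areas, 0.99)
        outliers = [10 * p99, 10.5 * p99, 11 * p99]
        cut = suggest_tail_cut(np.concatenate([areas, outliers]))
        assert cut is not None
        assert areas.max() < cut < min(outliers)


# --------------------------------------------------------------------------- #
# full chain
# --------------------------------------------------------------------------- #
class TestSegmentOrganoids:
    def test_blank_image_no_objects(self):
        labels, objs = segment_organoids(np.full((128, 128), 200, dtype=np.uint8))
        assert objs == []
        assert labels.max() == 0

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            segment_organoids(np.zeros((0, 0)))

    def _single_scene(self, dark: bool) -> "tuple":
        p = SceneParams(
            height=160,
            width=160,
            n_organoids=1,
            radius_log_mu=math.log(30.0),
            radius_log_sigma=0.0,
            eccentricity_max=0.0,
            dark_centre_fraction=1.0 if dark else 0.0,
            noise_sd=3.0,
            n_debris=0,
            n_bubbles=0,
            seed=21,
        )
        return render_scene(p)

    def test_single_organoid_area_within_15_percent(self):
        st = self._single_scene(dark=False)
        labels, objs = segment_organoids(st.image)
        assert len(objs) == 1
        truth = st.objects[0].area_px
        assert abs(objs[0].area_px - truth) / truth <= 0.15

    def test_dark_centre_mask_covered_via_hole_filling(self):
        """The dark interior disc must be inside the segmented mask."""
        st = self._single_scene(dark=True)
        labels, objs = segment_organoids(st.image)
        assert len(objs) == 1
        truth_mask = st.label_mask > 0
        covered = (truth_mask & (labels > 0)).sum() / truth_mask.sum()
        assert covered >= 0.95

    def test_relabelled_consecutively_and_connected(self, default_scene):
        labels, objs = segment_organoids(default_scene.image)
        ids = sorted(np.unique(labels[labels > 0]))
        assert ids == list(range(1, len(objs) + 1))
        for o in objs:
            region = labels == o.label
            assert connected_components(region, 8).max() == 1

    def test_deterministic(self, default_scene):
        l1, o1 = segment_organoids(default_scene.image)
        l2, o2 = segment_organoids(default_scene.image)
        assert np.array_equal(l1, l2)
        assert o1 == o2

    def test_params_validation(self):
        with pytest.raises(ValueError):
            SegmentationParams(canny_low=0.5, canny_high=0.2)
        with pytest.raises(ValueError):
            SegmentationParams(object_connectivity=6)
        with pytest.raises(ValueError):
            SegmentationParams(max_area_px=10, min_area_px=10)
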