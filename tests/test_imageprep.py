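import numpy as np
import pytest
from skimage import morphology

from histograph.imageprep import (
    LabelMask,
    clean_binary,
    connected_components,
    decompose_labels,
    filter_small_regions,
    prepare_mask,
    read_mask,
    reconcile_partition,
    region_properties,
    write_mask,
)

from conftest import random_label_mask


def mask_of(rows, n_labels=4):
    return LabelMask(np.array(rows, dtype=np.int32), n_labels=n_labels)


class TestLabelMask:
    def test_rejects_out_of_range_labels(self):
        with pytest.raises(ValueError):
            mask_of([[1, 5]], n_labels=4)
        with pytest.raises(ValueError):
            mask_of([[-1, 0]])

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            LabelMask(np.zeros((2, 2, 2), dtype=np.int32))


class TestDecomposeLabels:
    def test_two_label_mask_splits_into_indicator_images(self):
        m = mask_of([[1, 2], [1, 2]])
        b = decompose_labels(m, 4)
        assert len(b) == 4
        assert b[0].tolist() == [[True, False], [True, False]]
        assert b[1].tolist() == [[False, True], [False, True]]
        assert not b[2].any() and not b[3].any()

    def test_uniform_mask(self):
        b = decompose_labels(mask_of([[3, 3], [3, 3]]), 4)
        assert b[2].all()
        assert not (b[0].any() or b[1].any() or b[3].any())

    def test_label_above_n_labels_rejected(self):
        m = mask_of([[1, 4]], n_labels=4)
        with pytest.raises(ValueError):
            decompose_labels(m, 3)


class TestCleanBinary:
    def test_isolated_speck_removed(self):
        m = np.zeros((11, 11), dtype=bool)
        m[5, 5] = True
        assert not clean_binary(m, 2).any()

    def test_large_solid_block_essentially_unchanged(self):
        # a disk element rounds the 4 square corners (correct morphology);
        # everything else, interior and edges, must pass through untouched
        m = np.zeros((30, 30), dtype=bool)
        m[5:25, 5:25] = True
        out = clean_binary(m, 2)
        assert np.array_equal(out & ~m, np.zeros_like(m))  # no growth
        diff = m & ~out
        assert diff.sum() <= 12  # only corner pixels shaved
        assert not diff[7:23, 7:23].any()
        # idempotence: an already-open shape is a fixed point
        assert np.array_equal(clean_binary(out, 2), out)

    def test_narrow_gap_bridged(self):
        m = np.zeros((12, 25), dtype=bool)
        m[1:11, 1:11] = True
        m[1:11, 12:22] = True  # 1-px vertical gap
        out = clean_binary(m, 2)
        # the closing bridges the gap into one component; pixelwise match of
        # the defining composition closing^2 then opening^2 (disk element)
        selem = morphology.disk(2)
        ref = m
        for _ in range(2):
            ref = morphology.closing(ref, selem)
        for _ in range(2):
            ref = morphology.opening(ref, selem)
        assert np.array_equal(out, ref.astype(bool))
        from scipy import ndimage

        _, n = ndimage.label(out)
        assert n == 1


class TestReconcilePartition:
    def test_round_trip_without_morphology(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            m = random_label_mask(rng)
            out = reconcile_partition(decompose_labels(m), m)
            assert np.array_equal(out.pixels, m.pixels)

    def test_lowest_label_wins_on_overlap(self):
        m = mask_of([[2]])
        claimed = [np.zeros((1, 1), bool) for _ in range(4)]
        claimed[1][0, 0] = True  # label 2
        claimed[2][0, 0] = True  # label 3
        assert reconcile_partition(claimed, m).pixels[0, 0] == 2

    def test_unclaimed_pixel_restores_original(self):
        m = mask_of([[4]])
        empty = [np.zeros((1, 1), bool) for _ in range(4)]
        assert reconcile_partition(empty, m).pixels[0, 0] == 4

    def test_shape_mismatch_rejected(self):
        m = mask_of([[1, 2]])
        with pytest.raises(ValueError):
            reconcile_partition([np.zeros((3, 3), bool)] * 4, m)


def _flood_regions(pixels, connectivity):
    """Brute-force flood fill used as the component-labeling oracle."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros(pixels.shape, dtype=bool)
    regions = []
    for r in range(pixels.shape[0]):
        for c in range(pixels.shape[1]):
            if pixels[r, c] == 0 or seen[r, c]:
                continue
            stack, comp = [(r, c)], set()
            seen[r, c] = True
            while stack:
                y, x = stack.pop()
                comp.add((y, x))
                for dy, dx in offsets:
                    yy, xx = y + dy, x + dx
                    if (
                        0 <= yy < pixels.shape[0]
                        and 0 <= xx < pixels.shape[1]
                        and not seen[yy, xx]
                        and pixels[yy, xx] == pixels[r, c]
                    ):
                        seen[yy, xx] = True
                        stack.append((yy, xx))
            regions.append(frozenset(comp))
    return set(regions)


class TestConnectedComponents:
    def test_two_disjoint_blocks_same_label(self):
        m = mask_of([[1, 0, 1], [1, 0, 1]])
        rm = connected_components(m)
        assert len(rm) == 2
        assert all(r.label == 1 for r in rm.regions)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_agrees_with_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(7)
        for _ in range(10):
            m = random_label_mask(rng, shape=(12, 12))
            rm = connected_components(m, connectivity=connectivity)
            got = {
                frozenset(zip(r.rows.tolist(), r.cols.tolist())) for r in rm.regions
            }
            assert got == _flood_regions(m.pixels, connectivity)

    def test_checkerboard_under_4_connectivity(self):
        px = np.indices((4, 4)).sum(axis=0) % 2 + 1
        rm = connected_components(mask_of(px.tolist()), connectivity=4)
        assert len(rm) == 16 and all(r.area == 1 for r in rm.regions)

    def test_l_shaped_region(self):
        m = mask_of([[1, 0], [1, 0], [1, 1], [0, 1]])
        rm = connected_components(m)
        assert len(rm) == 1 and rm.regions[0].area == 5

    def test_ids_follow_raster_order_of_first_pixels(self):
        m = mask_of([[2, 0, 1], [2, 0, 1]])
        rm = connected_components(m)
        assert [r.id for r in rm.regions] == [1, 2]
        assert rm.regions[0].label == 2  # leftmost region first


class TestFilterSmallRegions:
    def test_threshold_drops_small_regions(self):
        m = mask_of([[1] * 10] * 10)
        px = m.pixels.copy()
        px[0, 0] = 0
        px[5:8, 5:8] = 2  # 9-px region inside the big one
        rm = connected_components(LabelMask(px))
        rm2 = filter_small_regions(rm, 50)
        assert [r.label for r in rm2.regions] == [1]
        assert (rm2.assignment > 0).sum() == rm2.regions[0].area

    def test_min_area_zero_is_identity(self):
        rng = np.random.default_rng(1)
        rm = connected_components(random_label_mask(rng))
        assert len(filter_small_regions(rm, 0)) == len(rm)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        rm = connected_components(random_label_mask(rng))
        counts = [len(filter_small_regions(rm, t)) for t in (0, 2, 5, 10, 50)]
        assert counts == sorted(counts, reverse=True)

    def test_all_below_threshold_gives_empty_map(self):
        rm = connected_components(mask_of([[1, 0], [0, 2]]))
        rm2 = filter_small_regions(rm, 10)
        assert len(rm2) == 0 and not (rm2.assignment > 0).any()


class TestRegionProperties:
    @pytest.mark.parametrize(
        "shape, expected_perimeter",
        [
            (np.ones((3, 3), bool), 8.0),  # 8 unit steps around the ring
            (np.ones((2, 2), bool), 4.0),
            (np.ones((1, 4), bool), 6.0),  # down the bar and back
            (np.ones((2, 3), bool), 6.0),
        ],
    )
    def test_perimeter_matches_hand_traced_contour(self, shape, expected_perimeter):
        rows, cols = np.nonzero(shape)
        area, perimeter, _ = region_properties(rows, cols)
        assert area == shape.sum()
        assert perimeter == pytest.approx(expected_perimeter)

    def test_diagonal_pair_uses_sqrt2_steps(self):
        rows, cols = np.array([0, 1]), np.array([0, 1])
        _, perimeter, _ = region_properties(rows, cols)
        assert perimeter == pytest.approx(2 * np.sqrt(2))

    def test_single_pixel_degenerate(self):
        area, perimeter, centroid = region_properties(np.array([3]), np.array([5]))
        assert (area, perimeter, centroid) == (1, 1.0, (3.0, 5.0))

    def test_centroid_of_bar(self):
        _, _, centroid = region_properties(np.zeros(4, int), np.arange(4))
        assert centroid == (0.0, 1.5)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            region_properties(np.array([]), np.array([]))

    def test_centroid_inside_bounding_box(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            m = random_label_mask(rng, shape=(15, 15))
            for r in connected_components(m).regions:
                cr, cc = r.centroid
                assert r.rows.min() <= cr <= r.rows.max()
                assert r.cols.min() <= cc <= r.cols.max()


class TestPartitionConservation:
    def test_region_areas_sum_to_non_background_pixels(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            m = random_label_mask(rng)
            rm = connected_components(m)
            assert sum(r.area for r in rm.regions) == int((m.pixels > 0).sum())

    def test_prepare_mask_pipeline_runs_end_to_end(self):
        rng = np.random.default_rng(5)
        m = random_label_mask(rng, shape=(40, 40))
        rm = prepare_mask(m, struct_radius=1, min_area=3)
        assert all(r.area >= 3 for r in rm.regions)


class TestMaskIO:
    @pytest.mark.parametrize("ext", ["png", "tif"])
    def test_round_trip(self, tmp_path, ext):
        rng = np.random.default_rng(6)
        m = random_label_mask(rng)
        path = tmp_path / f"mask.{ext}"
        write_mask(m, path)
        assert np.array_equal(read_mask(path).pixels, m.pixels)
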