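import numpy as np
import pytest
from shapely.geometry import box
from shapely.ops import unary_union

from oracles import cluster_oracle, meanshift_oracle, merge_oracle
from swardmap.rasters import GridSpec
from swardmap.segment import (
    SegmentationParams,
    cluster_modes,
    meanshift_filter,
    merge_small_regions,
    segment_image,
    vectorize,
)


def params(**kw):
    defaults = dict(spatialr=2, ranger=1.0, minsize=1, max_iter=10,
                    conv_threshold=0.01)
    defaults.update(kw)
    return SegmentationParams(**defaults)


class TestMeanShiftFilter:
    def test_constant_image_one_iteration(self):
        img = np.full((5, 5, 2), 3.0)
        modes = meanshift_filter(img, params())
        np.testing.assert_allclose(modes, 3.0, atol=1e-12)

    def test_two_blocks_converge_to_block_means(self):
        img = np.zeros((6, 6, 1))
        img[:, 3:] = 100.0
        modes = meanshift_filter(img, params(spatialr=2, ranger=5.0))
        np.testing.assert_allclose(modes[:, :3], 0.0, atol=1e-9)
        np.testing.assert_allclose(modes[:, 3:], 100.0, atol=1e-9)

    def test_global_mean_limit(self, rng):
        img = rng.uniform(0, 1, (5, 5, 1))
        modes = meanshift_filter(
            img, params(spatialr=10, ranger=1e9, max_iter=100,
                        conv_threshold=1e-12))
        np.testing.assert_allclose(modes, img.mean(), atol=1e-9)

    def test_matches_oracle_on_random_rasters(self, rng):
        for _ in range(20):
            h, w = rng.integers(2, 8, 2)
            nb = int(rng.integers(1, 3))
            img = rng.uniform(0, 10, (h, w, nb)).round(1)
            p = params(spatialr=int(rng.integers(1, 4)),
                       ranger=float(rng.uniform(0.5, 8)),
                       max_iter=int(rng.integers(1, 6)),
                       conv_threshold=float(rng.uniform(0.001, 0.5)))
            got = meanshift_filter(img, p)
            expected = meanshift_oracle(img, p.spatialr, p.ranger, p.max_iter,
                                        p.conv_threshold)
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_nonfinite_rejected(self):
        img = np.full((3, 3, 1), np.nan)
        with pytest.raises(ValueError):
            meanshift_filter(img, params())


class TestClusterModes:
    def test_constant_grid_one_label(self):
        labels = cluster_modes(np.full((4, 4, 1), 2.0), params())
        assert labels.max() == 1
        assert (labels == 1).all()

    def test_two_blocks_two_labels(self):
        modes = np.zeros((4, 6, 1))
        modes[:, 3:] = 10.0
        labels = cluster_modes(modes, params(ranger=1.0))
        assert labels.max() == 2
        assert len(np.unique(labels[:, :3])) == 1
        assert len(np.unique(labels[:, 3:])) == 1

    def test_checkerboard_all_singletons(self):
        modes = np.indices((4, 4)).sum(axis=0) % 2 * 10.0
        labels = cluster_modes(modes[..., None], params(ranger=1.0))
        assert labels.max() == 16

    def test_row_major_numbering(self):
        modes = np.zeros((2, 4, 1))
        modes[:, 2:] = 10.0
        labels = cluster_modes(modes, params(ranger=1.0))
        assert labels[0, 0] == 1 and labels[0, 3] == 2

    def test_matches_bfs_oracle(self, rng):
        for _ in range(30):
            h, w = rng.integers(2, 8, 2)
            nb = int(rng.integers(1, 3))
            modes = rng.integers(0, 4, (h, w, nb)).astype(float)
            ranger = float(rng.uniform(0.5, 3))
            got = cluster_modes(modes, params(ranger=ranger))
            expected = cluster_oracle(modes, ranger)
            np.testing.assert_array_equal(got, expected)

    def test_nodata_gets_zero(self):
        modes = np.zeros((3, 3, 1))
        valid = np.ones((3, 3), bool)
        valid[0, 0] = False
        labels = cluster_modes(modes, params(), valid=valid)
        assert labels[0, 0] == 0
        assert (labels[valid] > 0).all()


class TestMergeSmallRegions:
    def test_no_op_when_all_large(self):
        labels = np.array([[1, 1, 2, 2]] * 4)
        values = labels.astype(float)
        out = merge_small_regions(labels, values, minsize=4)
        assert out.max() == 2
        np.testing.assert_array_equal(out, labels)

    def test_whole_image_smaller_than_minsize(self):
        labels = np.array([[1, 2], [3, 4]])
        values = np.arange(4.0).reshape(2, 2)
        out = merge_small_regions(labels, values, minsize=100)
        assert out.max() == 1

    def test_merges_into_spectrally_nearest(self):
        # 8x8: left block value 10, right block value 25, 3-pixel region value 15
        labels = np.ones((8, 8), dtype=int)
        labels[:, 4:] = 2
        labels[3:6, 4] = 3
        values = np.where(labels == 1, 10.0, 25.0)
        values[labels == 3] = 15.0  # distance 5 to region 1, 10 to region 2
        out = merge_small_regions(labels, values, minsize=4)
        assert out.max() == 2
        assert len(np.unique(out[3:6, 4])) == 1
        assert (out[3:6, 4] == out[0, 0]).all()  # joined the left block

    def test_matches_simulation_oracle(self, rng):
        for _ in range(25):
            h, w = rng.integers(2, 8, 2)
            nb = int(rng.integers(1, 3))
            modes = rng.integers(0, 3, (h, w, nb)).astype(float)
            ranger = float(rng.uniform(0.5, 2.5))
            labels = cluster_modes(modes, params(ranger=ranger))
            minsize = int(rng.integers(1, 8))
            got = merge_small_regions(labels, modes, minsize)
            expected = merge_oracle(labels, modes, minsize)
            np.testing.assert_array_equal(got, expected)

    def test_minimum_size_invariant(self, rng):
        modes = rng.integers(0, 3, (10, 10, 1)).astype(float)
        labels = cluster_modes(modes, params(ranger=0.5))
        out = merge_small_regions(labels, modes, minsize=5)
        sizes = np.bincount(out.ravel())[1:]
        sizes = sizes[sizes > 0]
        assert (sizes >= 5).all() or len(sizes) == 1


class TestVectorize:
    def test_single_2x2_region_area(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[1:3, 1:3] = 1
        grid = GridSpec(0.0, 4 * 0.002, 0.002, 4, 4)
        polys = vectorize(labels, grid)
        assert polys[1].area == pytest.approx(4 * 0.002**2, rel=1e-9)

    def test_partition_conserves_area(self, rng, unit_grid):
        labels = rng.integers(1, 5, (8, 8))
        polys = vectorize(labels, unit_grid)
        total = sum(p.area for p in polys.values())
        assert total == pytest.approx(64.0, rel=1e-9)

    def test_pixel_count_oracle_20_random_grids(self, rng, unit_grid):
        for _ in range(20):
            labels = rng.integers(1, 4, (8, 8))
            polys = vectorize(labels, unit_grid)
            for lab, poly in polys.items():
                count = (labels == lab).sum()
                assert poly.area == pytest.approx(count * 1.0, rel=1e-9)

    def test_agrees_with_box_union_oracle(self, rng, unit_grid):
        for _ in range(5):
            labels = rng.integers(1, 4, (6, 6))
            polys = vectorize(labels, unit_grid)
            for lab, poly in polys.items():
                boxes = []
                for r, c in zip(*np.nonzero(labels == lab)):
                    x0 = unit_grid.origin_x + c * unit_grid.pixel_size
                    y1 = unit_grid.origin_y - r * unit_grid.pixel_size
                    boxes.append(box(x0, y1 - unit_grid.pixel_size,
                                     x0 + unit_grid.pixel_size, y1))
                expected = unary_union(boxes)
                assert poly.symmetric_difference(expected).area < 1e-12

    def test_hole_preserved(self, unit_grid):
        labels = np.ones((8, 8), dtype=int)
        labels[3:5, 3:5] = 2
        polys = vectorize(labels, unit_grid)
        assert polys[1].area == pytest.approx(60.0)
        outer = polys[1]
        assert len(outer.interiors) == 1

    def test_nodata_skipped(self, unit_grid):
        labels = np.zeros((8, 8), dtype=int)
        labels[0, 0] = 1
        polys = vectorize(labels, unit_grid)
        assert set(polys) == {1}


class TestSegmentImage:
    def test_two_class_scene_two_segments(self):
        img = np.zeros((16, 16, 1))
        img[:, 8:] = 50.0
        p = params(spatialr=3, ranger=5.0, minsize=1)
        sm = segment_image(img, p)
        assert sm.n_segments == 2

    def test_minsize_monotonicity(self, rng):
        img = rng.integers(0, 5, (20, 20, 1)).astype(float)
        counts = []
        for minsize in (1, 4, 16):
            sm = segment_image(img, params(spatialr=2, ranger=1.0,
                                           minsize=minsize),
                               vectorize_output=False)
            counts.append(sm.n_segments)
        assert counts[0] >= counts[1] >= counts[2]

    def test_tiled_equals_untiled(self, rng):
        img = (rng.integers(0, 3, (32, 32, 1)) * 10).astype(float)
        p_untiled = params(spatialr=2, ranger=2.0, minsize=2, max_iter=3)
        p_tiled = SegmentationParams(spatialr=2, ranger=2.0, minsize=2,
                                     max_iter=3, conv_threshold=0.01,
                                     tile_size=16)
        a = segment_image(img, p_untiled, vectorize_output=False).labels
        b = segment_image(img, p_tiled, vectorize_output=False).labels
        np.testing.assert_array_equal(a, b)

    def test_band_permutation_safety(self, rng):
        img = rng.integers(0, 3, (12, 12, 3)).astype(float) * 4
        p = params(spatialr=2, ranger=2.0, minsize=2)
        a = segment_image(img, p, vectorize_output=False).labels
        b = segment_image(img[..., ::-1], p, vectorize_output=False).labels
        np.testing.assert_array_equal(a, b)

    def test_partition_property(self, rng):
        img = rng.integers(0, 4, (10, 10, 2)).astype(float)
        sm = segment_image(img, params(spatialr=2, ranger=1.5, minsize=2))
        assert (sm.labels > 0).all()
        total = sum(p.area for p in sm.polygons.values())
        assert total == pytest.approx(100.0, rel=1e-6)

    def test_polygon_count_matches_segments(self, rng):
        img = rng.integers(0, 4, (10, 10, 1)).astype(float)
        sm = segment_image(img, params(spatialr=1, ranger=0.5, minsize=1))
        assert set(sm.polygons) == set(sm.segment_ids().tolist())


class TestParams:
    @pytest.mark.parametrize("kw", [
        dict(spatialr=0, ranger=1.0, minsize=1),
        dict(spatialr=1, ranger=0.0, minsize=1),
        dict(spatialr=1, ranger=1.0, minsize=0),
    ])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            SegmentationParams(**kw)

    def test_table_grids_representable(self):
        for sr, rr, ms in [(10, 10, 30), (30, 30, 200), (5, 0.01, 2),
                           (15, 0.02, 14)]:
            SegmentationParams(spatialr=sr, ranger=rr, minsize=ms)
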