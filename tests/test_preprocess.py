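import colorsys

import numpy as np
import pytest
from scipy.spatial import Delaunay

from oracles import nearest_neighbor_oracle, tin_oracle
from swardmap.rasters import GridSpec, RasterStack
from swardmap.preprocess import (
    GroundPointSet,
    align_rasters,
    compute_chm,
    compute_dtm_tin,
    compute_vis_ms,
    compute_vis_rgb,
    his_to_rgb,
    rgb_to_his,
)


class TestTin:
    def test_plane_reproduced_exactly(self, rng):
        x = rng.uniform(0, 10, 25)
        y = rng.uniform(0, 10, 25)
        z = 2 * x + 3 * y + 1
        grid = GridSpec(2.0, 8.0, 0.5, 10, 10)  # interior of the hull
        dtm, outside = compute_dtm_tin(GroundPointSet(x, y, z), grid)
        xs, ys = grid.cell_centers()
        inside = ~outside
        np.testing.assert_allclose(dtm[inside], (2 * xs + 3 * ys + 1)[inside],
                                   atol=1e-9)

    def test_grid_node_at_input_point(self):
        # cell center (1.5, 1.5) coincides with an input point
        pts = GroundPointSet([0, 3, 0, 3, 1.5], [0, 0, 3, 3, 1.5],
                             [5.0, 6.0, 7.0, 8.0, 42.0])
        grid = GridSpec(0.0, 3.0, 1.0, 3, 3)
        dtm, _ = compute_dtm_tin(pts, grid)
        assert dtm[1, 1] == pytest.approx(42.0, abs=1e-9)

    def test_against_barycentric_oracle(self, rng):
        x = rng.uniform(0, 10, 20)
        y = rng.uniform(0, 10, 20)
        z = rng.normal(size=20)
        pts = GroundPointSet(x, y, z)
        grid = GridSpec(3.0, 7.0, 0.4, 10, 10)
        dtm, outside = compute_dtm_tin(pts, grid)
        tri = Delaunay(np.column_stack([x, y]))
        xs, ys = grid.cell_centers()
        queries = list(zip(xs.ravel(), ys.ravel()))
        expected = tin_oracle(list(zip(x, y, z)), queries,
                              tri.simplices.tolist()).reshape(grid.shape)
        inside = ~outside & np.isfinite(expected)
        assert inside.sum() > 50
        np.testing.assert_allclose(dtm[inside], expected[inside], atol=1e-9)

    def test_outside_hull_filled_and_flagged(self):
        pts = GroundPointSet([2, 8, 5], [2, 2, 8], [1.0, 2.0, 3.0])
        grid = GridSpec(0.0, 10.0, 1.0, 10, 10)
        dtm, outside = compute_dtm_tin(pts, grid)
        assert outside.any()
        assert np.isfinite(dtm).all()

    def test_collinear_points_rejected(self):
        pts = GroundPointSet([0, 1, 2, 3], [0, 1, 2, 3], [1, 2, 3, 4])
        grid = GridSpec(0.0, 3.0, 1.0, 3, 3)
        with pytest.raises(ValueError, match="degenerate"):
            compute_dtm_tin(pts, grid)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            GroundPointSet([0, 1], [0, 1], [0, 1])


class TestChm:
    def test_equal_grids_zero(self):
        z = np.full((4, 4), 7.0)
        np.testing.assert_array_equal(compute_chm(z, z), np.zeros((4, 4)))

    def test_constant_offset(self):
        dsm = np.full((3, 3), 10.5)
        dtm = np.full((3, 3), 10.0)
        np.testing.assert_allclose(compute_chm(dsm, dtm), 0.5)

    def test_elementwise_oracle(self, rng):
        dsm = rng.normal(10, 1, (4, 4))
        dtm = rng.normal(9, 1, (4, 4))
        chm = compute_chm(dsm, dtm, clamp_negative=False)
        for i in range(4):
            for j in range(4):
                assert chm[i, j] == dsm[i, j] - dtm[i, j]

    def test_negative_clamped(self):
        chm = compute_chm(np.zeros((2, 2)), np.ones((2, 2)))
        assert (chm == 0).all()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            compute_chm(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_nodata_propagates(self):
        dsm = np.array([[np.nan, 1.0]])
        chm = compute_chm(dsm, np.zeros((1, 2)))
        assert np.isnan(chm[0, 0]) and chm[0, 1] == 1.0


class TestHis:
    def test_pure_red_anchor(self):
        h, i, s = rgb_to_his(np.array([[255.0]]), np.array([[0.0]]),
                             np.array([[0.0]]))
        assert h[0, 0] == 0.0
        assert s[0, 0] == pytest.approx(1.0)
        assert i[0, 0] == pytest.approx(0.5)

    def test_gray_has_no_chroma(self):
        g = np.array([[128.0]])
        h, i, s = rgb_to_his(g, g, g)
        assert s[0, 0] == 0.0
        assert h[0, 0] == 0.0  # achromatic hue convention

    def test_roundtrip_within_1_dn(self, rng):
        r, g, b = rng.uniform(0, 255, (3, 10, 10))
        h, i, s = rgb_to_his(r, g, b)
        r2, g2, b2 = his_to_rgb(h, i, s)
        np.testing.assert_allclose(r2, r, atol=1.0)
        np.testing.assert_allclose(g2, g, atol=1.0)
        np.testing.assert_allclose(b2, b, atol=1.0)

    def test_against_colorsys(self, rng):
        for _ in range(100):
            r, g, b = rng.uniform(0, 255, 3)
            h, i, s = rgb_to_his(np.array([[r]]), np.array([[g]]),
                                 np.array([[b]]))
            ch, cl, cs = colorsys.rgb_to_hls(r / 255, g / 255, b / 255)
            assert h[0, 0] == pytest.approx(ch * 360.0, abs=1e-6)
            assert i[0, 0] == pytest.approx(cl, abs=1e-9)
            assert s[0, 0] == pytest.approx(cs, abs=1e-6)

    def test_out_of_range_clipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            h, i, s = rgb_to_his(np.array([[300.0]]), np.array([[0.0]]),
                                 np.array([[0.0]]))
        assert "clipping" in caplog.text
        assert i[0, 0] == pytest.approx(0.5)

    def test_scaled_output(self):
        h, i, s = rgb_to_his(np.array([[255.0]]), np.array([[0.0]]),
                             np.array([[0.0]]), scale_255=True)
        assert s[0, 0] == pytest.approx(255.0)
        assert i[0, 0] == pytest.approx(127.5)


class TestRgbVis:
    def _stack(self, r, g, b):
        grid = GridSpec(0.0, 1.0, 1.0, 1, 1)
        st = RasterStack(grid, value_domain="dn_0_255")
        st.add_band("red", np.array([[float(r)]]))
        st.add_band("green", np.array([[float(g)]]))
        st.add_band("blue", np.array([[float(b)]]))
        return st

    def test_achromatic_pixel(self):
        vis = compute_vis_rgb(self._stack(100, 100, 100))
        assert vis["ExG"][0, 0] == pytest.approx(0.0, abs=1e-12)
        assert vis["NGRDI"][0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_pure_green(self):
        vis = compute_vis_rgb(self._stack(0, 255, 0))
        assert vis["ExG"][0, 0] == pytest.approx(2.0)
        assert vis["ExR"][0, 0] == pytest.approx(-1.0)
        assert vis["ExGR"][0, 0] == pytest.approx(3.0)
        assert vis["NGRDI"][0, 0] == pytest.approx(1.0)

    def test_exgr_identity(self, rgb_stack):
        vis = compute_vis_rgb(rgb_stack)
        np.testing.assert_allclose(vis["ExGR"], vis["ExG"] - vis["ExR"],
                                   atol=1e-12)

    def test_zero_sum_pixel_is_nodata(self):
        vis = compute_vis_rgb(self._stack(0, 0, 0))
        assert np.isnan(vis["ExG"][0, 0])
        assert vis.nodata_mask[0, 0]

    def test_ngrdi_in_unit_interval(self, rgb_stack):
        vis = compute_vis_rgb(rgb_stack)
        vals = vis["NGRDI"][~np.isnan(vis["NGRDI"])]
        assert (np.abs(vals) <= 1.0).all()

    def test_missing_band(self):
        grid = GridSpec(0.0, 1.0, 1.0, 1, 1)
        st = RasterStack(grid)
        st.add_band("red", np.zeros((1, 1)))
        with pytest.raises(ValueError, match="green"):
            compute_vis_rgb(st)


class TestMsVis:
    def _stack(self, **bands):
        grid = GridSpec(0.0, 1.0, 1.0, 1, 1)
        st = RasterStack(grid, value_domain="reflectance_0_1")
        defaults = dict(blue444=0.03, blue475=0.04, green531=0.06, green560=0.08,
                        red650=0.05, red668=0.05, re705=0.2, re717=0.25,
                        re740=0.3, nir840=0.5)
        defaults.update(bands)
        for name, val in defaults.items():
            st.add_band(name, np.array([[float(val)]]))
        return st

    def test_ndvi_zero_when_nir_equals_red(self):
        vis = compute_vis_ms(self._stack(nir840=0.1, red668=0.1))
        assert vis["NDVI"][0, 0] == pytest.approx(0.0, abs=1e-12)
        assert vis["MSAVI"][0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_ndvi_hand_value(self):
        vis = compute_vis_ms(self._stack(nir840=0.5, red668=0.1))
        assert vis["NDVI"][0, 0] == pytest.approx(0.4 / 0.6, abs=1e-9)

    def test_gndvi_zero_when_nir_equals_green(self):
        vis = compute_vis_ms(self._stack(nir840=0.08, green560=0.08))
        assert vis["GNDVI"][0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_all_eight_indices_present(self):
        vis = compute_vis_ms(self._stack())
        assert vis.band_names == ["CIg", "EVI", "GARI", "GNDVI", "MCARI",
                                  "MSAVI", "NDVI", "SR_717"]

    def test_cig_hand_value(self):
        vis = compute_vis_ms(self._stack(nir840=0.4, green560=0.08))
        assert vis["CIg"][0, 0] == pytest.approx(0.4 / 0.08 - 1.0)

    def test_zero_denominator_nodata(self):
        vis = compute_vis_ms(self._stack(nir840=0.0, re717=0.0))
        assert np.isnan(vis["SR_717"][0, 0])


class TestAlign:
    def test_identity_resample(self, rng):
        grid = GridSpec(0.0, 4.0, 1.0, 4, 4)
        vals = rng.normal(size=(4, 4))
        out = align_rasters([("x", vals, grid)], grid)
        np.testing.assert_array_equal(out["x"], vals)

    def test_upsample_2x_replicates_blocks(self):
        src = GridSpec(0.0, 2.0, 1.0, 2, 2)
        dst = GridSpec(0.0, 2.0, 0.5, 4, 4)
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = align_rasters([("x", vals, src)], dst)["x"]
        expected = np.repeat(np.repeat(vals, 2, axis=0), 2, axis=1)
        np.testing.assert_array_equal(out, expected)

    def test_half_pixel_offset_matches_oracle(self, rng):
        src = GridSpec(0.0, 6.0, 1.0, 6, 6)
        dst = GridSpec(0.5, 5.5, 1.0, 5, 5)
        vals = rng.normal(size=(6, 6))
        out = align_rasters([("x", vals, src)], dst)["x"]
        expected = nearest_neighbor_oracle(vals, src, dst)
        np.testing.assert_array_equal(np.nan_to_num(out), np.nan_to_num(expected))

    def test_disjoint_extents_rejected(self):
        src = GridSpec(0.0, 2.0, 1.0, 2, 2)
        dst = GridSpec(100.0, 2.0, 1.0, 2, 2)
        with pytest.raises(ValueError, match="overlap"):
            align_rasters([("x", np.zeros((2, 2)), src)], dst)

    def test_idempotent(self, rng):
        grid = GridSpec(0.0, 3.0, 1.0, 3, 3)
        vals = rng.normal(size=(3, 3))
        once = align_rasters([("x", vals, grid)], grid)
        twice = align_rasters([("x", once["x"], grid)], grid)
        np.testing.assert_array_equal(once["x"], twice["x"])

    def test_duplicate_names_rejected(self):
        grid = GridSpec(0.0, 2.0, 1.0, 2, 2)
        with pytest.raises(ValueError, match="duplicate"):
            align_rasters([("x", np.zeros((2, 2)), grid),
                           ("x", np.ones((2, 2)), grid)], grid)
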