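import numpy as np
import pandas as pd
import pytest

import phenoprofiles as pp
from phenoprofiles.heights import (aggregate_local_maxima, binarize_vegetation,
                                   compute_csm, compute_ngrdi, validate_heights,
                                   zonal_mean_height)
from phenoprofiles.raster import GridMismatchError, RasterGrid


def grid(values, cell=1.0, origin=(0.0, 0.0)):
    return RasterGrid(origin, cell, np.asarray(values, float))


class TestCsm:
    def test_identity_and_offset(self):
        dem = grid(np.full((3, 3), 5.0))
        assert np.all(compute_csm(dem, dem).values == 0)
        dsm = grid(np.full((3, 3), 7.5))
        assert np.all(compute_csm(dsm, dem).values == 2.5)

    def test_nodata_propagates_and_negatives_clamp(self):
        dsm = grid([[1.0, np.nan], [0.5, 2.0]])
        dem = grid([[1.5, 1.0], [1.0, 1.0]])
        csm = compute_csm(dsm, dem)
        assert np.isnan(csm.values[0, 1])
        assert csm.values[0, 0] == 0.0          # clamped, not -0.5
        assert csm.values[1, 1] == 1.0

    def test_geometry_mismatch(self):
        with pytest.raises(GridMismatchError):
            compute_csm(grid(np.zeros((2, 2))), grid(np.zeros((3, 3))))


class TestNgrdi:
    @pytest.mark.parametrize("g,r,expected", [
        (0.4, 0.4, 0.0),
        (0.75, 0.25, 0.5),
        (0.2, 0.3, -0.2),
    ])
    def test_pointwise_values(self, g, r, expected):
        out = compute_ngrdi(grid([[g]]), grid([[r]]))
        assert out.values[0, 0] == pytest.approx(expected)

    def test_zero_denominator_is_nodata_and_range(self):
        g = grid([[0.0, 0.9], [0.1, 0.0]])
        r = grid([[0.0, 0.1], [0.0, 0.8]])
        out = compute_ngrdi(g, r).values
        assert np.isnan(out[0, 0])
        valid = out[~np.isnan(out)]
        assert np.all((valid >= -1) & (valid <= 1))

    def test_negative_reflectance_rejected(self):
        with pytest.raises(ValueError):
            compute_ngrdi(grid([[-0.1]]), grid([[0.2]]))


class TestVegetationMask:
    def test_all_soil_empty_mask(self):
        mask = binarize_vegetation(grid([[-0.2, -0.05]]), 0.0)
        assert not mask.mask.any()

    def test_mixed_and_lower_bound(self):
        ngrdi = grid([[-0.2, 0.5]])
        assert binarize_vegetation(ngrdi, 0.0).mask.tolist() == [[False, True]]
        assert binarize_vegetation(ngrdi, -1.0).mask.all()

    def test_nodata_is_false(self):
        mask = binarize_vegetation(grid([[np.nan, 0.3]]), 0.0)
        assert mask.mask.tolist() == [[False, True]]


class TestAggregateLocalMaxima:
    def test_constant_csm(self):
        csm = grid(np.full((4, 4), 1.8))
        out = aggregate_local_maxima(csm, 2)
        assert np.all(out.values == 1.8)

    def test_known_blocks(self):
        csm = grid(np.arange(1, 17, dtype=float).reshape(4, 4))
        out = aggregate_local_maxima(csm, 2)
        assert out.values.tolist() == [[6.0, 8.0], [14.0, 16.0]]

    def test_window_one_is_identity(self):
        vals = np.random.default_rng(0).random((5, 5))
        out = aggregate_local_maxima(grid(vals), 1)
        assert np.allclose(out.values, vals)

    def test_window_larger_than_raster_raises(self):
        with pytest.raises(ValueError):
            aggregate_local_maxima(grid(np.zeros((3, 3))), 10)

    def test_mask_refinement_never_raises_block_maxima(self):
        rng = np.random.default_rng(1)
        vals = rng.random((8, 8))
        full = binarize_vegetation(grid(np.ones((8, 8))), 0.5)
        partial_vals = (rng.random((8, 8)) > 0.4).astype(float)
        partial = binarize_vegetation(grid(partial_vals), 0.5)
        b_full = aggregate_local_maxima(grid(vals), 2, mask=full).values
        b_part = aggregate_local_maxima(grid(vals), 2, mask=partial).values
        ok = ~np.isnan(b_part)
        assert np.all(b_part[ok] <= b_full[ok] + 1e-12)


class TestZonalMean:
    def _design(self):
        return pp.FieldDesign(
            rects=np.array([[0.0, 0.0, 2.0, 2.0], [2.0, 0.0, 4.0, 2.0]]),
            plot_ids=["A", "B"], backgrounds=["x", "y"],
            plot_width_m=2.0, plot_length_m=2.0)

    def test_constant_blocks_convert_to_cm(self):
        blocks = RasterGrid((0.0, 0.0), 0.5, np.full((4, 8), 2.10))
        out = zonal_mean_height(blocks, self._design(), 45)
        assert np.allclose(out["height_cm"], 210.0)
        assert out["n_pixels_used"].tolist() == [16, 16]

    def test_plot_without_blocks_is_missing(self):
        vals = np.full((4, 8), np.nan)
        vals[:, :4] = 1.0                       # only plot A covered
        out = zonal_mean_height(RasterGrid((0.0, 0.0), 0.5, vals),
                                self._design(), 45)
        row_b = out[out.plot_id == "B"].iloc[0]
        assert np.isnan(row_b.height_cm) and row_b.n_pixels_used == 0

    def test_empty_design_raises(self):
        blocks = RasterGrid((0.0, 0.0), 0.5, np.ones((2, 2)))
        design = self._design()
        design.rects = np.empty((0, 4))
        design.plot_ids, design.backgrounds = [], []
        with pytest.raises(ValueError):
            zonal_mean_height(blocks, design, 45)


class TestPipelineProperties:
    def test_dsm_shift_raises_heights_by_same_amount(self, noiseless_scene):
        """Raising every DSM cell by delta raises each plot height by
        exactly 100*delta cm (noiseless, fixed mask)."""
        scene = noiseless_scene
        day = scene.days[-1]
        delta = 0.30
        mask = binarize_vegetation(
            compute_ngrdi(scene.green_band[day], scene.red_band[day]), 0.0)

        def extract(dsm):
            csm = compute_csm(dsm, scene.dem_truth)
            blocks = aggregate_local_maxima(csm, 10, mask=mask)
            return zonal_mean_height(blocks, scene.design, day)["height_cm"]

        base = extract(scene.dsm[day])
        shifted = extract(scene.dsm[day].copy_with(scene.dsm[day].values + delta))
        assert np.allclose(shifted - base, 100 * delta, atol=1e-9)


class TestValidateHeights:
    def _frame(self, heights):
        return pd.DataFrame({"plot_id": [f"P{i}" for i in range(len(heights))],
                             "das": 74, "height_cm": heights})

    def test_identity(self):
        ref = self._frame([100, 150, 200, 250])
        out = validate_heights(ref, ref)
        assert out["r2"] == pytest.approx(1.0)
        assert out["rmse_cm"] == pytest.approx(0.0)

    def test_constant_offset(self):
        ref = self._frame([100.0, 150.0, 200.0, 250.0])
        est = self._frame([110.0, 160.0, 210.0, 260.0])
        out = validate_heights(est, ref)
        assert out["r2"] == pytest.approx(1.0)
        assert out["rmse_cm"] == pytest.approx(0.0, abs=1e-9)
        assert out["intercept"] == pytest.approx(10.0)

    def test_hand_computed_ols(self):
        # closed-form OLS for these points: slope 1, intercept 2.5,
        # residuals (7.5, -7.5, -7.5, 7.5), R^2 = 1 - 225/12725
        ref = self._frame([100.0, 150.0, 200.0, 250.0])
        est = self._frame([110.0, 145.0, 195.0, 260.0])
        out = validate_heights(est, ref)
        assert out["slope"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(2.5)
        assert out["r2"] == pytest.approx(1 - 225 / 12725)
        assert out["rmse_cm"] == pytest.approx(7.5)

    def test_too_few_pairs(self):
        ref = self._frame([100, 150])
        with pytest.raises(ValueError):
            validate_heights(ref, ref)
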