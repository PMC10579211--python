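import numpy as np
import pytest
from hypothesis import given, strategies as st

from petiq.iq_metrics import (
    MetricError,
    PlacementError,
    background_variability,
    build_metrics_table,
    central_sphere_slice,
    contrast_recovery,
    lung_error,
    place_background_rois,
    place_sphere_vois,
    recovery_coefficient,
    relative_difference,
    sphere_contrast_and_snr,
)
from petiq.phantom import LABEL_BACKGROUND, sphere_label


class TestRoiPlacement:
    def test_sixty_rois_on_default_phantom(self, phantom_3d):
        rois = place_background_rois(phantom_3d)
        assert len(rois) == 60
        central = rois.meta["central_slice"]
        assert sum(r.slice_index == central for r in rois.rois) == 12

    def test_clearance_from_spheres_and_edge(self, phantom_3d):
        from petiq.iq_metrics import _sphere_surface_distance

        rois = place_background_rois(phantom_3d)
        grid = phantom_3d.grid
        zc = grid.axis_coords(0)
        for roi in rois.rois:
            y, x = roi.center_mm
            d = _sphere_surface_distance(phantom_3d, y, x, float(zc[roi.slice_index]))
            assert d >= 15.0
        # ROIs fully inside the background region
        for roi in rois.rois:
            assert np.all(phantom_3d.labels[roi.voxel_index] == LABEL_BACKGROUND)

    def test_placement_is_deterministic(self, phantom_3d):
        a = place_background_rois(phantom_3d)
        b = place_background_rois(phantom_3d)
        assert [r.center_mm for r in a.rois] == [r.center_mm for r in b.rois]

    def test_single_roi_farthest_from_spheres(self, phantom_2d):
        from petiq.iq_metrics import _sphere_surface_distance

        rois = place_background_rois(phantom_2d, n_per_slice=1, n_slices=1)
        assert len(rois) == 1
        y, x = rois.rois[0].center_mm
        d = _sphere_surface_distance(phantom_2d, y, x, 0.0)
        # far clear of the 15 mm minimum: nothing nearby beats this point
        assert d > 40.0

    def test_infeasible_clearance_raises(self, phantom_2d):
        with pytest.raises(PlacementError):
            place_background_rois(phantom_2d, clearance_mm=120.0, n_slices=1)

    def test_central_slice_maximizes_sphere_area(self, phantom_3d):
        k = central_sphere_slice(phantom_3d)
        sphere = np.isin(phantom_3d.labels, phantom_3d.sphere_labels())
        per_slice = sphere.reshape(sphere.shape[0], -1).sum(axis=1)
        assert per_slice[k] == per_slice.max() > 0


class TestVoiPlacement:
    def test_one_voi_per_sphere_with_matching_diameter(self, phantom_3d):
        vois = place_sphere_vois(phantom_3d)
        assert len(vois) == 6
        for voi, d in zip(vois, phantom_3d.meta["sphere_diameters_mm"]):
            assert voi.diameter_mm == d
            assert voi.n_voxels > 0

    def test_voi_mean_on_truth_equals_hot_concentration(self, phantom_3d):
        vois = place_sphere_vois(phantom_3d)
        hot = 4.9 * 4
        for voi in vois:
            assert voi.mean(phantom_3d.activity) == pytest.approx(hot)


class TestMetricDefinitions:
    def test_contrast_recovery_examples(self):
        assert contrast_recovery(8.0, 2.0, 4.0) == pytest.approx(1.0, abs=1e-12)
        assert contrast_recovery(2.0, 2.0, 4.0) == 0.0
        assert contrast_recovery(3.0, 1.0, 4.0) == pytest.approx(2.0 / 3.0, abs=1e-12)
        with pytest.raises(MetricError):
            contrast_recovery(3.0, 1.0, 1.0)

    def test_recovery_coefficient_examples(self):
        assert recovery_coefficient(7.0, 7.0) == 1.0
        assert recovery_coefficient(0.0, 7.0) == 0.0
        assert recovery_coefficient(20.4, 40.0) == pytest.approx(0.51, abs=1e-12)
        with pytest.raises(MetricError):
            recovery_coefficient(1.0, 0.0)

    def test_lung_error_examples(self):
        assert lung_error(0.0, 10.0) == 0.0
        assert lung_error(5.0, 5.0) == 100.0
        assert lung_error(1.46, 10.0) == pytest.approx(14.6, abs=1e-12)

    def test_contrast_and_snr_example(self):
        contrast, snr = sphere_contrast_and_snr(8.0, 2.0, 0.5)
        assert contrast == pytest.approx(4.0, abs=1e-12)
        assert snr == pytest.approx(16.0, abs=1e-12)
        c2, _ = sphere_contrast_and_snr(16.0, 4.0, 0.5)
        assert c2 == contrast  # ratio invariance
        with pytest.raises(MetricError):
            sphere_contrast_and_snr(8.0, 2.0, 0.0)

    def test_relative_difference_examples(self):
        assert relative_difference(5.0, 5.0) == 0.0
        assert relative_difference(12.63, 14.62) == pytest.approx(-15.756136, abs=1e-4)
        assert relative_difference(3.0, 0.0) == 100.0
        with pytest.raises(MetricError):
            relative_difference(0.0, 1.0)

    @given(
        a=st.floats(0.01, 1e4), b=st.floats(0.0, 1e4)
    )
    def test_relative_difference_against_oracle(self, a, b):
        assert relative_difference(a, b) == (a - b) / a * 100.0

    def test_background_variability_hand_value(self, phantom_2d):
        rois = place_background_rois(phantom_2d, n_per_slice=2, n_slices=1)
        img = np.zeros_like(phantom_2d.activity)
        img[rois.rois[0].voxel_index] = 9.0
        img[rois.rois[1].voxel_index] = 11.0
        # means {9, 11}: population SD 1, mean 10 -> 10%
        assert background_variability(rois, img) == pytest.approx(10.0, abs=1e-12)
        assert background_variability(rois, 7 * img) == pytest.approx(10.0, abs=1e-12)

    def test_bv_zero_for_flat_image(self, phantom_2d):
        rois = place_background_rois(phantom_2d, n_slices=1)
        assert background_variability(rois, phantom_2d.activity) == 0.0


class TestMetricsTable:
    def test_cardinality_for_six_recons(self, phantom_2d):
        recons = [(f"r{i}", phantom_2d.activity.copy()) for i in range(6)]
        table = build_metrics_table(recons, phantom_2d)
        assert len(table.sphere_metrics) == 36
        assert len(table.recon_metrics) == 6

    def test_perfect_image_gives_ideal_metrics(self, phantom_2d):
        table = build_metrics_table([("truth", phantom_2d.activity)], phantom_2d)
        assert np.allclose(table.sphere_metrics["CR"], 1.0)
        assert np.allclose(table.sphere_metrics["RC"], 1.0)
        assert table.recon_value("truth", "BV_pct") == 0.0
        assert table.recon_value("truth", "LE_pct") == 0.0
        # suvmax analog of a perfectly recovered hot sphere equals the LBR
        assert np.allclose(table.sphere_metrics["suvmax"], 4.0)

    def test_rescaled_image_leaves_ratios_unchanged(self, phantom_2d):
        t1 = build_metrics_table([("a", phantom_2d.activity)], phantom_2d)
        t2 = build_metrics_table([("a", 3.7 * phantom_2d.activity)], phantom_2d)
        for col in ("CR", "contrast"):
            assert np.allclose(t1.sphere_metrics[col], t2.sphere_metrics[col])
        assert t1.recon_value("a", "BV_pct") == t2.recon_value("a", "BV_pct")

    def test_grid_mismatch_rejected(self, phantom_2d):
        with pytest.raises(MetricError, match="grid"):
            build_metrics_table([("bad", np.ones((16, 16)))], phantom_2d)
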