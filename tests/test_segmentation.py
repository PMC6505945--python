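import dataclasses

import numpy as np
import pytest

import adiposeg as ap
from conftest import SMALL_ROI, make_small_spec
import _oracles


def _as_mask(data, geom, label="custom"):
    return ap.Mask(data=data, geometry=geom, region_label=label)


class TestSelectRoi:
    def test_51_slice_window(self):
        geom = ap.VoxelGeometry(1.25, 1.25, 3.0, 150)
        data = np.zeros((150, 4, 4))
        data[50] = 1.0  # marker at the first ROI slice
        data[100] = 2.0  # marker at the last ROI slice
        vol = ap.ImageVolume(data, geom)
        roi = ap.RoiSpec(l4l5_index=75, half_width=25)
        sub = ap.select_roi(vol, roi)
        assert sub.geometry.n_slices == 51
        assert sub.data[0, 0, 0] == 1.0
        assert sub.data[50, 0, 0] == 2.0

    def test_degenerate_half_width(self):
        geom = ap.VoxelGeometry(1, 1, 1, 10)
        vol = ap.ImageVolume(np.arange(10, dtype=float)[:, None, None]
                             * np.ones((10, 2, 2)), geom)
        roi = ap.RoiSpec(l4l5_index=4, half_width=0, central_count=1)
        sub = ap.select_roi(vol, roi)
        assert sub.geometry.n_slices == 1
        assert sub.data[0, 0, 0] == 4.0

    def test_insufficient_slices_names_deficit(self):
        geom = ap.VoxelGeometry(1.25, 1.25, 3.0, 150)
        vol = ap.ImageVolume(np.zeros((150, 4, 4)), geom)
        with pytest.raises(ap.BoundsError, match="missing"):
            ap.select_roi(vol, ap.RoiSpec(l4l5_index=10, half_width=25))


def test_central_slab_convention():
    assert ap.central_slab(25, 30) == (11, 41)  # 30-of-51, centre included
    assert ap.central_slab(25, 51) == (0, 51)
    assert ap.central_slab(5, 1) == (5, 6)


class TestBodyMask:
    def test_all_zero_volume_fails(self):
        geom = ap.VoxelGeometry(1, 1, 1, 2)
        vol = ap.ImageVolume(np.zeros((2, 8, 8)), geom, "in_phase")
        with pytest.raises(ap.SegmentationFailure):
            ap.build_body_mask(vol, ap.SegmentationParams())

    def test_elliptical_body_area_within_1_percent(self):
        # noise-free body with 150 x 100 mm semi-axes: per-slice mask area
        # within 1% of pi * 150 * 100
        spec = ap.PhantomSpec(
            geometry=ap.VoxelGeometry(1.25, 1.25, 3.0, 9),
            n_rows=192, n_cols=272, body_semi_axes=(150.0, 100.0),
            sat_thickness=25.0, vat_blobs=(), organs=(), marrow=None,
            noise_sd=0.0, l4l5_index=4,
        )
        pair, _, _ = ap.generate_phantom(spec, seed=1, central_count=3)
        body = ap.build_body_mask(pair.in_phase, ap.SegmentationParams())
        analytic = np.pi * 150.0 * 100.0
        areas = body.data.sum(axis=(1, 2)) * spec.geometry.dx * spec.geometry.dy
        assert np.abs(areas / analytic - 1).max() < 0.01

    def test_interior_air_pocket_filled(self, small_clean):
        spec, pair, _, _ = small_clean
        ip_roi = ap.select_roi(pair.in_phase, SMALL_ROI)
        data = np.array(ip_roi.data)
        # 5-voxel air pocket inside the body on one slice
        r, c = data.shape[1] // 2, data.shape[2] // 2
        data[5, r, c - 2:c + 3] = 0.0
        vol = ap.ImageVolume(data, ip_roi.geometry, "in_phase")
        body = ap.build_body_mask(vol, ap.SegmentationParams())
        assert body.data[5, r, c - 2:c + 3].all()


class TestFatMask:
    def test_zero_fat_image_gives_empty_mask_with_warning(self, caplog):
        geom = ap.VoxelGeometry(1, 1, 1, 1)
        fat = ap.ImageVolume(np.zeros((1, 8, 8)), geom, "fat_only")
        body = _as_mask(np.ones((1, 8, 8), bool), geom, "body")
        with caplog.at_level("WARNING", logger="adiposeg"):
            mask = ap.build_fat_mask(fat, body, ap.ThresholdSpec("fixed", 10.0))
        assert mask.voxel_count() == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_separable_intensities_exact(self, small_clean):
        """Fat 1000 vs non-fat background, fixed threshold 500: the mask
        equals the ground-truth fat support exactly."""
        spec, _, fat_only, truth = small_clean
        fat_roi = ap.select_roi(fat_only, SMALL_ROI)
        body = ap.crop_mask_to_roi(truth.body, SMALL_ROI)
        mask = ap.build_fat_mask(
            fat_roi, body, ap.ThresholdSpec("fixed", 500.0),
            ap.SegmentationParams(fat_open_radius=0),
        )
        assert np.array_equal(mask.data,
                              ap.crop_mask_to_roi(truth.fat, SMALL_ROI).data)

    def test_otsu_on_noisy_phantom_dice(self, small_noisy):
        spec, pair, fat_only, truth = small_noisy
        fat_roi = ap.select_roi(fat_only, SMALL_ROI)
        ip_roi = ap.select_roi(pair.in_phase, SMALL_ROI)
        body = ap.build_body_mask(ip_roi, ap.SegmentationParams())
        mask = ap.build_fat_mask(fat_roi, body)
        d = ap.dice_coefficient(mask, ap.crop_mask_to_roi(truth.fat, SMALL_ROI))
        assert d >= 0.95

    def test_low_fixed_threshold_warns(self, small_noisy, caplog):
        spec, pair, fat_only, truth = small_noisy
        fat_roi = ap.select_roi(fat_only, SMALL_ROI)
        body = ap.crop_mask_to_roi(truth.body, SMALL_ROI)
        with caplog.at_level("WARNING", logger="adiposeg"):
            ap.build_fat_mask(fat_roi, body, ap.ThresholdSpec("fixed", 5.0))
        assert any("background" in r.message for r in caplog.records)


class TestSplitSatVat:
    def test_exact_recovery_on_truth_inputs(self, small_clean):
        spec, _, _, truth = small_clean
        body = ap.crop_mask_to_roi(truth.body, SMALL_ROI)
        fat = ap.crop_mask_to_roi(truth.fat, SMALL_ROI)
        res = ap.split_sat_vat(
            _as_mask(fat.data, fat.geometry, "fat"),
            _as_mask(body.data, body.geometry, "body"),
            ap.SegmentationParams(), roi=SMALL_ROI,
        )
        assert np.array_equal(res.sat.data,
                              ap.crop_mask_to_roi(truth.sat, SMALL_ROI).data)
        assert np.array_equal(res.vat.data,
                              ap.crop_mask_to_roi(truth.vat, SMALL_ROI).data)

    def test_zero_ring_all_fat_is_visceral(self, caplog):
        spec = make_small_spec(sat_thickness=0.0, marrow=None, noise_sd=0.0)
        _, fat_only, truth = ap.generate_phantom(spec, seed=1, central_count=10)
        body = ap.crop_mask_to_roi(truth.body, SMALL_ROI)
        fat = ap.crop_mask_to_roi(truth.fat, SMALL_ROI)
        with caplog.at_level("WARNING", logger="adiposeg"):
            res = ap.split_sat_vat(
                _as_mask(fat.data, fat.geometry, "fat"),
                _as_mask(body.data, body.geometry, "body"),
                ap.SegmentationParams(), roi=SMALL_ROI,
            )
        assert res.sat.voxel_count() == 0
        assert np.array_equal(res.vat.data, fat.data)
        assert any("shell" in r.message for r in caplog.records)

    def test_marrow_counts_towards_tat_only(self, small_clean):
        """A fat marrow core inside a non-fat vertebra embedded in the body
        wall is neither SAT nor VAT, so TAT > SAT + VAT."""
        spec, _, _, truth = small_clean
        body = ap.crop_mask_to_roi(truth.body, SMALL_ROI)
        fat = ap.crop_mask_to_roi(truth.fat, SMALL_ROI)
        res = ap.split_sat_vat(
            _as_mask(fat.data, fat.geometry, "fat"),
            _as_mask(body.data, body.geometry, "body"),
            ap.SegmentationParams(), roi=SMALL_ROI,
        )
        vols = ap.compute_volumes(res, spec.geometry, SMALL_ROI)
        assert vols.tat_ml > vols.vat_ml + vols.sat_ml

    def test_fat_outside_body_rejected(self):
        geom = ap.VoxelGeometry(1, 1, 1, 1)
        fat = _as_mask(np.ones((1, 4, 4), bool), geom, "fat")
        body = _as_mask(np.zeros((1, 4, 4), bool), geom, "body")
        with pytest.raises(ap.SegmentationFailure):
            ap.split_sat_vat(fat, body)


class TestComputeVolumes:
    def _result_with_uniform_masks(self, geom, n_fat_voxels):
        # geom.n_slices must be odd so the ROI covers the whole grid
        assert geom.n_slices % 2 == 1
        shape = (geom.n_slices, 10, 10)
        fat = np.zeros(shape, dtype=bool)
        fat.ravel()[:n_fat_voxels] = True
        body = np.ones(shape, dtype=bool)
        empty = np.zeros(shape, dtype=bool)
        roi = ap.RoiSpec(l4l5_index=geom.n_slices // 2,
                         half_width=(geom.n_slices - 1) // 2,
                         central_count=geom.n_slices)
        return ap.SegmentationResult(
            body=_as_mask(body, geom, "body"),
            fat=_as_mask(fat, geom, "fat"),
            sat=_as_mask(empty, geom, "SAT"),
            vat=_as_mask(empty, geom, "VAT"),
            cavity=_as_mask(empty, geom, "cavity"),
            roi=roi, params=ap.SegmentationParams(),
        ), roi

    def test_empty_masks_zero_volumes(self):
        geom = ap.VoxelGeometry(1.25, 1.25, 3.0, 5)
        res, roi = self._result_with_uniform_masks(geom, 0)
        vols = ap.compute_volumes(res, geom, roi)
        assert vols.vat_ml == vols.sat_ml == vols.tat_ml == 0.0

    def test_1000_voxels_at_default_resolution(self):
        geom = ap.VoxelGeometry(1.25, 1.25, 3.0, 11)
        res, roi = self._result_with_uniform_masks(geom, 1000)
        vols = ap.compute_volumes(res, geom, roi)
        assert vols.tat_ml == pytest.approx(4.6875)

    def test_doubling_dz_doubles_volumes(self):
        geom = ap.VoxelGeometry(1.25, 1.25, 3.0, 11)
        res, roi = self._result_with_uniform_masks(geom, 1000)
        v1 = ap.compute_volumes(res, geom, roi)
        geom2 = ap.VoxelGeometry(1.25, 1.25, 6.0, 11)
        v2 = ap.compute_volumes(res, geom2, roi)
        assert v2.tat_ml == pytest.approx(2 * v1.tat_ml)
        assert v2.abdominal_ml == pytest.approx(2 * v1.abdominal_ml)

    def test_central_count_exceeding_roi_rejected(self, small_clean):
        spec, _, _, truth = small_clean
        body = ap.crop_mask_to_roi(truth.body, SMALL_ROI)
        fat = ap.crop_mask_to_roi(truth.fat, SMALL_ROI)
        res = ap.split_sat_vat(_as_mask(fat.data, fat.geometry, "fat"),
                               _as_mask(body.data, body.geometry, "body"),
                               roi=SMALL_ROI)
        big = ap.RoiSpec(l4l5_index=20, half_width=30, central_count=61)
        with pytest.raises(ap.BoundsError):
            ap.compute_volumes(res, spec.geometry, big)


class TestPipelineProperties:
    def test_threshold_monotonicity(self, small_noisy):
        """Lowering the fixed fat threshold never decreases TAT."""
        spec, pair, fat_only, _ = small_noisy
        tats = []
        for value in (700.0, 500.0, 300.0):
            _, vols = ap.segment_abdomen(
                fat_only, pair.in_phase, SMALL_ROI,
                ap.ThresholdSpec("fixed", value),
            )
            tats.append(vols.tat_ml)
        assert tats[0] <= tats[1] <= tats[2]

    def test_partition_and_ordering_invariants(self, small_noisy):
        spec, pair, fat_only, _ = small_noisy
        res, vols = ap.segment_abdomen(fat_only, pair.in_phase, SMALL_ROI)
        res.validate()
        assert not (res.sat.data & res.vat.data).any()
        assert ((res.sat.data | res.vat.data) <= res.fat.data).all()
        assert (res.fat.data <= res.body.data).all()
        assert vols.vat_ml + vols.sat_ml <= vols.tat_ml <= vols.abdominal_ml

    def test_zero_noise_volume_recovery_within_surface_bound(self, small_clean):
        from test_phantom import _surface_voxel_bound_ml

        spec, pair, fat_only, truth = small_clean
        _, vols = ap.segment_abdomen(fat_only, pair.in_phase, SMALL_ROI)
        lo, hi = ap.central_slab(spec.l4l5_index, SMALL_ROI.central_count)
        for est, ana, mask in [
            (vols.vat_ml, truth.volumes_analytic.vat_ml, truth.vat),
            (vols.sat_ml, truth.volumes_analytic.sat_ml, truth.sat),
            (vols.tat_ml, truth.volumes_analytic.tat_ml, truth.fat),
            (vols.abdominal_ml, truth.volumes_analytic.abdominal_ml, truth.body),
        ]:
            bound = _surface_voxel_bound_ml(mask, lo, hi)
            assert abs(est - ana) <= bound

    def test_exclusion_mask_removes_marrow_from_tat(self, small_clean):
        spec, pair, fat_only, truth = small_clean
        marrow = truth.fat.data & ~truth.sat.data & ~truth.vat.data
        excl = ap.Mask(data=marrow, geometry=spec.geometry, region_label="custom")
        _, vols_excl = ap.segment_abdomen(
            fat_only, pair.in_phase, SMALL_ROI,
            ap.ThresholdSpec("fixed", 500.0), exclude=excl,
        )
        _, vols = ap.segment_abdomen(
            fat_only, pair.in_phase, SMALL_ROI, ap.ThresholdSpec("fixed", 500.0),
        )
        assert vols_excl.tat_ml < vols.tat_ml
        assert vols_excl.vat_ml == pytest.approx(vols.vat_ml)


class TestMorphologyOracles:
    """Connected components and hole filling must match brute-force flood
    fill exactly on small grids."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_connected_components_match_flood_fill(self, seed, connectivity):
        from skimage.measure import label as cc_label

        rng = np.random.default_rng(seed)
        grid = rng.random((5, 32, 32)) < 0.4
        conn = 2 if connectivity == 8 else 1
        for sl in grid:
            lab = cc_label(sl, connectivity=conn)
            got = set()
            for i in range(1, lab.max() + 1):
                got.add(frozenset(map(tuple, np.argwhere(lab == i))))
            expected = set(_oracles.flood_components(sl.tolist(), connectivity))
            assert got == expected

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_hole_filling_matches_flood_fill(self, seed):
        from scipy.ndimage import binary_fill_holes

        rng = np.random.default_rng(seed)
        grid = rng.random((5, 24, 24)) < 0.55
        for sl in grid:
            got = binary_fill_holes(sl)
            expected = np.array(_oracles.fill_holes(sl.tolist()))
            assert np.array_equal(got, expected)
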