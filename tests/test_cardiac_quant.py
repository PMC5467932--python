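import numpy as np
import pytest

from petph.cardiac_quant import (cavity_volume, ejection_metrics, extract_ed_es,
                                 measure_cardiac, rv_lv_ratio, segment_rv_cavity,
                                 wall_max_suv)
from petph.core_io import GatedPetSeries, VoxelGrid, to_suv
from petph.errors import (ContourabilityError, DomainError,
                          SeedAboveThresholdError)
from petph.phantom import PhantomSpec, make_thorax
from petph.pipeline import _center_of_mask


def _series(frame_values):
    frames = [VoxelGrid(np.asarray(v, dtype=float), (2.0, 2.0, 2.0))
              for v in frame_values]
    return GatedPetSeries(frames, 370.0, 74.0)


class TestExtractEdEs:
    def test_constant_series(self):
        c = 3.7
        series = _series([np.full((4, 4, 4), c)] * 8)
        ed, es = extract_ed_es(series)
        np.testing.assert_allclose(ed.values, c)
        np.testing.assert_allclose(es.values, c)

    def test_frame_mean_rule(self):
        # frame1 = 2, frame8 = 4, others 0 -> ed = 3, es = 0
        shape = (3, 3, 3)
        vals = [np.zeros(shape) for _ in range(8)]
        vals[0] = np.full(shape, 2.0)
        vals[7] = np.full(shape, 4.0)
        ed, es = extract_ed_es(_series(vals))
        np.testing.assert_allclose(ed.values, 3.0)
        np.testing.assert_allclose(es.values, 0.0)

    def test_sum_mode_doubles_constant(self):
        series = _series([np.full((3, 3, 3), 1.5)] * 8)
        ed, _ = extract_ed_es(series, sum_mode=True)
        np.testing.assert_allclose(ed.values, 3.0)

    def test_invariant_to_cyclic_relabeling_within_gate_pairs(self):
        # swapping frames 1<->8 and 4<->5 leaves ED/ES unchanged
        rng = np.random.default_rng(0)
        vals = [rng.uniform(size=(4, 4, 4)) for _ in range(8)]
        swapped = list(vals)
        swapped[0], swapped[7] = swapped[7], swapped[0]
        swapped[3], swapped[4] = swapped[4], swapped[3]
        ed1, es1 = extract_ed_es(_series(vals))
        ed2, es2 = extract_ed_es(_series(swapped))
        np.testing.assert_allclose(ed1.values, ed2.values)
        np.testing.assert_allclose(es1.values, es2.values)


@pytest.fixture(scope="module")
def cardiac_phantom():
    spec = PhantomSpec.cardiac(seed=3)
    series, ct, truth = make_thorax(spec)
    suv = [to_suv(f, spec.injected_dose_mbq, spec.body_weight_kg)
           for f in series.frames]
    ss = GatedPetSeries(suv, spec.injected_dose_mbq, spec.body_weight_kg)
    ed, es = extract_ed_es(ss)
    return spec, truth, ed, es


class TestSegmentation:
    def test_cavity_volume_within_two_percent_of_truth(self, cardiac_phantom):
        spec, truth, ed, es = cardiac_phantom
        seed = _center_of_mask(truth.rois.rv_cavity_es)
        mask = segment_rv_cavity(ed, seed, threshold_fraction=0.5)
        assert cavity_volume(mask) == pytest.approx(truth.edv, rel=0.02)

    def test_segmentation_is_deterministic(self, cardiac_phantom):
        _, truth, ed, _ = cardiac_phantom
        seed = _center_of_mask(truth.rois.rv_cavity_es)
        m1 = segment_rv_cavity(ed, seed)
        m2 = segment_rv_cavity(ed, seed)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_uniform_uptake_is_not_contourable(self):
        img = VoxelGrid(np.full((20, 20, 20), 2.0), (2.0, 2.0, 2.0))
        with pytest.raises(ContourabilityError):
            segment_rv_cavity(img, (10, 10, 10))

    def test_wall_equal_to_cavity_uptake_fails(self):
        # no boundary exists when the wall is as cold as the cavity
        spec = PhantomSpec.cardiac(seed=3)
        spec.uptake["rv_wall"] = spec.uptake["blood"]
        spec.uptake["septum"] = spec.uptake["blood"]
        spec.uptake["lv_wall"] = spec.uptake["blood"]
        series, ct, truth = make_thorax(spec)
        ed, _ = extract_ed_es(series)
        seed = _center_of_mask(truth.rois.rv_cavity_es)
        with pytest.raises(ContourabilityError):
            segment_rv_cavity(ed, seed)

    def test_seed_on_hot_wall_rejected(self, cardiac_phantom):
        _, truth, ed, _ = cardiac_phantom
        wall_idx = np.argwhere(truth.rois.walls["rv_wall"].values)[0]
        with pytest.raises(SeedAboveThresholdError):
            segment_rv_cavity(ed, tuple(wall_idx))

    def test_bad_threshold_rejected(self, cardiac_phantom):
        _, truth, ed, _ = cardiac_phantom
        seed = _center_of_mask(truth.rois.rv_cavity_es)
        with pytest.raises(DomainError):
            segment_rv_cavity(ed, seed, threshold_fraction=1.5)


class TestVolumesAndMetrics:
    def test_unit_voxel_bookkeeping(self):
        m = np.zeros((12, 12, 12), np.uint8)
        m.flat[:1000] = 1
        assert cavity_volume(VoxelGrid(m, (1, 1, 1))) == pytest.approx(1.0)

    def test_empty_mask_zero_volume(self):
        assert cavity_volume(VoxelGrid(np.zeros((4, 4, 4)), (2, 2, 2))) == 0.0

    def test_ellipsoid_mask_matches_closed_form(self):
        # voxelized ellipsoid volume vs 4/3*pi*a*b*c
        a, b, c = 11.0, 8.0, 14.0
        sp = 1.0
        n = 40
        coords = (np.arange(n) - (n - 1) / 2) * sp
        X, Y, Z = np.meshgrid(coords, coords, coords, indexing="ij")
        mask = ((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1).astype(np.uint8)
        vol = cavity_volume(VoxelGrid(mask, (sp, sp, sp)))
        analytic = 4 / 3 * np.pi * a * b * c / 1000.0
        assert vol == pytest.approx(analytic, rel=0.02)

    def test_ejection_metrics_arithmetic(self):
        ef, sv = ejection_metrics(200.0, 120.0)
        assert ef == pytest.approx(40.0)
        assert sv == pytest.approx(80.0)

    def test_degenerate_heart_zero_ef(self):
        ef, sv = ejection_metrics(150.0, 150.0)
        assert ef == 0.0 and sv == 0.0

    @pytest.mark.parametrize("edv,esv", [(0.0, 0.0), (100.0, 120.0), (100.0, -5.0)])
    def test_invalid_volumes_rejected(self, edv, esv):
        with pytest.raises(DomainError):
            ejection_metrics(edv, esv)


class TestWallSuv:
    def test_constant_field(self):
        suv = VoxelGrid(np.full((5, 5, 5), 2.5), (1, 1, 1))
        roi = VoxelGrid(np.ones((5, 5, 5), np.uint8), (1, 1, 1))
        assert wall_max_suv(suv, roi) == 2.5

    def test_single_hot_voxel(self):
        vals = np.ones((5, 5, 5))
        vals[2, 3, 1] = 7.3
        suv = VoxelGrid(vals, (1, 1, 1))
        roi = VoxelGrid(np.ones((5, 5, 5), np.uint8), (1, 1, 1))
        assert wall_max_suv(suv, roi) == 7.3

    def test_matches_bruteforce_scan_on_random_grids(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            vals = rng.uniform(0, 5, size=(6, 5, 4))
            roi = (rng.uniform(size=vals.shape) < 0.4).astype(np.uint8)
            if roi.sum() == 0:
                roi[0, 0, 0] = 1
            best = -np.inf
            for i in range(6):
                for j in range(5):
                    for k in range(4):
                        if roi[i, j, k] and vals[i, j, k] > best:
                            best = vals[i, j, k]
            assert wall_max_suv(VoxelGrid(vals, (1, 1, 1)),
                                VoxelGrid(roi, (1, 1, 1))) == best

    def test_empty_roi_rejected(self):
        suv = VoxelGrid(np.ones((4, 4, 4)), (1, 1, 1))
        with pytest.raises(DomainError):
            wall_max_suv(suv, VoxelGrid(np.zeros((4, 4, 4), np.uint8), (1, 1, 1)))


class TestRvLvRatio:
    @pytest.mark.parametrize("rv,lv,expected", [(2.0, 2.0, 1.0), (3.0, 2.0, 1.5)])
    def test_arithmetic(self, rv, lv, expected):
        assert rv_lv_ratio(rv, lv) == pytest.approx(expected)

    def test_nonpositive_lv_rejected(self):
        with pytest.raises(DomainError):
            rv_lv_ratio(2.0, 0.0)

    def test_phantom_recovers_configured_wall_ratio(self, thorax, thorax_suv):
        spec, _, _, truth = thorax
        suv_series, static = thorax_suv
        ed, es = extract_ed_es(suv_series)
        measure = measure_cardiac(static, ed, es, truth.rois.walls,
                                  seed_ed=_center_of_mask(truth.rois.rv_cavity_es))
        expected = spec.uptake["rv_wall"] / spec.uptake["lv_wall"]
        assert measure.rv_lv_ratio == pytest.approx(expected, rel=1e-6)
        assert measure.contourable
        assert measure.ef == pytest.approx(truth.ef, abs=3.0)
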