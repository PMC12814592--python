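"""Tests of 3D segmentation, object sizing, mass conversion and
organ-burden extrapolation."""

import math

import numpy as np
import pytest

from conftest import constant_blob_stack
from nanoburden.confocal import (PolymerSpec, equivalent_sphere_diameter,
                                 extract_objects, filter_noise,
                                 lod_volume_fraction, object_mass,
                                 organ_burden, scanned_volume, segment,
                                 size_histogram, tissue_concentration)
from nanoburden.stack import ImageGrid, ImageStack
from nanoburden.synthetic import (Agglomerate, GroundTruthScene,
                                  generate_stack)

PS = PolymerSpec("PS-NR", density_g_cm3=1.05, packing=0.64)


class TestSegment:
    def test_uniform_background_yields_no_objects(self, small_grid):
        stack = ImageStack(np.full(small_grid.shape, 7.0), small_grid)
        assert segment(stack, "otsu").max() == 0

    def test_nan_voxels_rejected(self, small_grid):
        data = np.ones(small_grid.shape)
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            segment(ImageStack(data, small_grid), "otsu")

    def test_well_separated_spheres_get_distinct_labels(self, small_grid, psf):
        scene = GroundTruthScene(
            [Agglomerate(3, 3, 4, 0.8, 200.0), Agglomerate(8, 8, 6, 0.8, 200.0)],
            background=5.0, fade_length_um=1e6, seed=1)
        stack, _ = generate_stack(small_grid, scene, psf)
        assert segment(stack, "otsu").max() == 2

    def test_spheres_below_lateral_resolution_merge(self, small_grid, psf):
        # centers 150 nm apart, below the ~200 nm lateral resolution
        scene = GroundTruthScene(
            [Agglomerate(5.0, 5.0, 4.8, 0.3, 200.0),
             Agglomerate(5.15, 5.0, 4.8, 0.3, 200.0)],
            background=5.0, fade_length_um=1e6, seed=1)
        stack, _ = generate_stack(small_grid, scene, psf)
        assert segment(stack, "otsu").max() == 1

    def test_lowering_threshold_never_loses_separated_objects(self, small_grid, psf):
        scene = GroundTruthScene(
            [Agglomerate(3, 3, 4, 0.8, 200.0), Agglomerate(8, 8, 6, 0.8, 200.0)],
            background=5.0, fade_length_um=1e6, seed=1)
        stack, _ = generate_stack(small_grid, scene, psf)
        counts = [segment(stack, "absolute", threshold=t).max()
                  for t in (150.0, 100.0, 60.0, 30.0)]
        assert counts == sorted(counts)


class TestExtractObjects:
    def test_single_voxel_closed_form(self, small_grid):
        stack, labels = constant_blob_stack(small_grid, [(5, 10, 10)])
        (obj,) = extract_objects(labels, stack)
        assert obj.volume_um3 == pytest.approx(0.00432)
        assert obj.eq_diameter_um == pytest.approx(0.2018, abs=5e-4)
        assert obj.deepest_z_um == pytest.approx(5.5 * 0.30)
        assert not obj.touches_edge

    def test_six_voxel_closed_form(self, small_grid):
        idx = [(5, 10, 10 + i) for i in range(6)]
        stack, labels = constant_blob_stack(small_grid, idx)
        (obj,) = extract_objects(labels, stack)
        assert obj.voxels == 6
        assert obj.volume_um3 == pytest.approx(0.02592)
        assert obj.eq_diameter_um == pytest.approx(0.367, abs=5e-4)

    def test_edge_object_flagged_and_excluded_from_totals(self, small_grid):
        idx = [(5, 10, 0), (5, 10, 1)]  # touches the x=0 face
        stack, labels = constant_blob_stack(small_grid, idx)
        (obj,) = extract_objects(labels, stack)
        assert obj.touches_edge
        result = tissue_concentration([obj], small_grid.volume, PS)
        assert result.objects_kept == 0
        assert result.mass_ng_per_100um3 == 0.0

    def test_halfmax_refinement_strips_blur_shoulder(self, small_grid):
        # core at 200 over a dim shoulder at 30: only the core is sized
        data = np.zeros(small_grid.shape)
        data[4:7, 10:16, 10:16] = 30.0
        data[5, 12:14, 12:14] = 200.0
        labels = (data > 0).astype(np.int32)
        stack = ImageStack(data, small_grid)
        (obj,) = extract_objects(labels, stack)
        assert obj.voxels == 4


class TestFilterNoise:
    def test_printed_noise_rule(self, small_grid):
        five = constant_blob_stack(small_grid, [(5, 10, 10 + i) for i in range(5)])
        six = constant_blob_stack(small_grid, [(8, 20, 20 + i) for i in range(6)])
        objs = (extract_objects(five[1], five[0])
                + extract_objects(six[1], six[0]))
        kept = filter_noise(objs, min_voxels=6)
        assert [o.voxels for o in kept] == [6]

    def test_empty_and_idempotent(self):
        assert filter_noise([]) == []

    def test_idempotence(self, small_grid):
        stack, labels = constant_blob_stack(
            small_grid, [(5, 10, 10 + i) for i in range(8)])
        objs = extract_objects(labels, stack)
        once = filter_noise(objs)
        assert filter_noise(once) == once


class TestObjectMass:
    def _obj(self, volume_um3):
        from nanoburden.confocal import SegmentedObject
        return SegmentedObject(1, 1, volume_um3,
                               equivalent_sphere_diameter(volume_um3),
                               1.0, 0.15, False)

    def test_one_micron_sphere(self):
        obj = self._obj(math.pi / 6.0)  # d = 1.0 µm
        assert object_mass(obj, PS) == pytest.approx(0.352e-12, rel=1e-3)

    def test_smallest_quantifiable_agglomerate(self):
        obj = self._obj(0.0004)
        assert object_mass(obj, PS) == pytest.approx(2.69e-16, rel=2e-3)
        assert obj.eq_diameter_um == pytest.approx(0.091, abs=5e-4)

    def test_unit_identity(self):
        obj = self._obj(1.0)
        unit = PolymerSpec("unit", density_g_cm3=1.0, packing=1.0)
        assert object_mass(obj, unit) == pytest.approx(1e-12)


class TestConcentrationAndBurden:
    def test_no_objects_gives_zero(self):
        r = tissue_concentration([], 1e6, PS)
        assert r.number_per_100um3 == 0 and r.mass_ng_per_100um3 == 0

    def test_reference_block_concentration(self, small_grid):
        # objects totalling 0.42 ng in exactly (100 µm)³ of tissue
        from nanoburden.confocal import SegmentedObject
        volume = 0.42e-9 / (PS.packing * PS.density_g_cm3 * 1e-12)
        obj = SegmentedObject(1, 100, volume,
                              equivalent_sphere_diameter(volume), 1.0, 1.0, False)
        r = tissue_concentration([obj], 1e6, PS)
        assert r.mass_ng_per_100um3 == pytest.approx(0.42, rel=1e-9)

    def test_doubling_scanned_volume_halves_concentrations(self, small_grid):
        stack, labels = constant_blob_stack(
            small_grid, [(5, 10, 10 + i) for i in range(8)])
        objs = extract_objects(labels, stack)
        r1 = tissue_concentration(objs, 1e6, PS)
        r2 = tissue_concentration(objs, 2e6, PS)
        assert r2.number_per_100um3 == pytest.approx(r1.number_per_100um3 / 2)
        assert r2.mass_ng_per_100um3 == pytest.approx(r1.mass_ng_per_100um3 / 2)

    def test_lung_and_node_extrapolation(self):
        from nanoburden.confocal import TissueScanResult
        lung = organ_burden(TissueScanResult(1, 1e6, 1.0, 0.42), 10.0, 1.63)
        assert lung.total_mass_mg == pytest.approx(4.2)
        assert lung.mass_per_g_mg == pytest.approx(2.577, abs=2e-3)
        node = organ_burden(TissueScanResult(1, 1e6, 1.0, 0.48), 0.03,
                            organ="LN")
        assert node.total_mass_mg * 1000 == pytest.approx(14.4)

    def test_conservation_object_masses_vs_burden_numerator(self, small_grid):
        stack, labels = constant_blob_stack(
            small_grid, [(5, 10, 10 + i) for i in range(8)])
        objs = extract_objects(labels, stack)
        r = tissue_concentration(objs, small_grid.volume, PS)
        assert r.total_mass_g == pytest.approx(
            sum(object_mass(o, PS) for o in objs), rel=1e-12)

    def test_zero_scanned_volume_rejected(self):
        with pytest.raises(ValueError):
            tissue_concentration([], 0.0, PS)


class TestSizeHistogram:
    def _obj(self, d):
        from nanoburden.confocal import SegmentedObject
        v = math.pi / 6 * d**3
        return SegmentedObject(1, 10, v, d, 1.0, 1.0, False)

    def test_single_object_single_bin(self):
        h = size_histogram([self._obj(0.7)], [0.0, 0.5, 1.0, 2.0])
        assert h["frequency"].sum() == pytest.approx(1.0)
        assert h["frequency"].tolist() == [0.0, 1.0, 0.0]

    def test_normalized_nonnegative(self):
        objs = [self._obj(d) for d in (0.3, 0.6, 0.8, 1.4, 1.4)]
        h = size_histogram(objs, np.linspace(0, 2, 9))
        assert (h["frequency"] >= 0).all()
        assert h["frequency"].sum() == pytest.approx(1.0)

    def test_empty_input(self):
        assert size_histogram([], [0, 1]).empty

    def test_mode_recovered_from_lognormal_sample(self):
        rng = np.random.default_rng(0)
        diam = 0.75 * np.exp(rng.normal(0, math.log(1.3), 400))
        objs = [self._obj(d) for d in diam]
        edges = np.linspace(0, 3, 16)  # 0.2 µm bins
        h = size_histogram(objs, edges)
        mode_bin = h["frequency"].idxmax()
        assert abs(h.loc[mode_bin, "bin_left_um"] + 0.1 - 0.75) <= 0.2


class TestScannedVolumeAndLimits:
    def test_lod_volume_fraction(self):
        assert lod_volume_fraction(0.0004, 0.43e9) == pytest.approx(9.3e-13,
                                                                    rel=1e-2)

    def test_detected_mode_truncates_at_deepest_object(self, small_grid):
        stack, labels = constant_blob_stack(small_grid, [(5, 10, 10)])
        objs = extract_objects(labels, stack)
        nominal = scanned_volume(small_grid, "nominal")
        detected = scanned_volume(small_grid, "detected", objs)
        assert nominal == pytest.approx(small_grid.volume)
        assert detected == pytest.approx(
            small_grid.field_x * small_grid.field_y * objs[0].deepest_z_um)
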