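import math

import numpy as np
import pytest

from gliomics import (ThresholdRule, VoxelGrid, centroid, centroid_distances,
                      geom_features, max_diameter, normalized_scd, pet_features,
                      rim_width, segment_threshold, sphericity, surface_area,
                      volumes)


class TestVolumes:
    def test_counts_times_voxel_volume(self, sphere_phantom):
        grid, _ = sphere_phantom(radius=10.0, necrotic_core_radius=5.0)
        ls = segment_threshold(grid, ThresholdRule(fraction_of_max=0.5))
        active, inner, total = volumes(ls, 1)
        lesion = ls.lesions[1]
        assert active == pytest.approx(lesion.n_active * 1.0)
        assert inner == pytest.approx(lesion.n_inner * 1.0)
        assert total == pytest.approx(active + inner)

    def test_shell_inner_volume_close_to_analytic(self, sphere_phantom):
        grid, _ = sphere_phantom(radius=10.0, spacing=0.5, necrotic_core_radius=5.0)
        ls = segment_threshold(grid, ThresholdRule(fraction_of_max=0.5))
        _, inner, total = volumes(ls, 1)
        assert inner == pytest.approx(4 / 3 * math.pi * 5 ** 3, rel=0.05)
        assert total == pytest.approx(4 / 3 * math.pi * 10 ** 3, rel=0.05)


class TestSurfaceAndSphericity:
    def test_voxelized_sphere_surface_close_to_analytic(self, sphere_phantom):
        grid, _ = sphere_phantom(radius=10.0, spacing=0.5)
        ls = segment_threshold(grid, ThresholdRule(fraction_of_max=0.5))
        s = surface_area(ls.lesions[1].filled_mask, grid.spacing)
        assert s == pytest.approx(4 * math.pi * 100, rel=0.03)

    def test_refinement_consistency(self, sphere_phantom):
        areas = []
        for spacing in (1.0, 0.5):
            grid, _ = sphere_phantom(radius=10.0, spacing=spacing)
            ls = segment_threshold(grid, ThresholdRule(fraction_of_max=0.5))
            areas.append(surface_area(ls.lesions[1].filled_mask, grid.spacing))
        assert areas[0] == pytest.approx(areas[1], rel=0.03)

    def test_single_voxel_area_positive_finite(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        s = surface_area(mask, (1, 1, 1))
        assert np.isfinite(s) and s > 0

    def test_sphericity_closed_forms(self):
        r = 7.0
        assert sphericity(4 / 3 * math.pi * r ** 3, 4 * math.pi * r ** 2) == pytest.approx(1.0)
        a = 3.0
        expected_cube = math.pi ** (1 / 3) * 6 ** (2 / 3) / 6
        assert sphericity(a ** 3, 6 * a ** 2) == pytest.approx(expected_cube)
        assert expected_cube == pytest.approx(0.8060, abs=1e-4)

    def test_voxelized_sphere_sphericity_near_one(self, sphere_phantom):
        grid, _ = sphere_phantom(radius=10.0, spacing=0.5)
        ls = segment_threshold(grid, ThresholdRule(fraction_of_max=0.5))
        gf = geom_features(grid, ls, 1)
        assert gf.sphericity == pytest.approx(1.0, abs=0.02)

    def test_sphericity_decreases_with_bumpiness(self, sphere_phantom):
        values = []
        for b in (0.0, 0.12, 0.25):
            grid, _ = sphere_phantom(radius=12.0, bumpiness=b, seed=7)
            ls = segment_threshold(grid, ThresholdRule(fraction_of_max=0.5))
            values.append(geom_features(grid, ls, 1).sphericity)
        assert values[0] > values[1] > values[2]
        assert values[0] <= 1.02

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            sphericity(0.0, 10.0)


class TestMaxDiameter:
    def test_sphere_diameter(self, sphere_phantom):
        grid, _ = sphere_phantom(radius=10.0, spacing=1.0)
        ls = segment_threshold(grid, ThresholdRule(fraction_of_max=0.5))
        d = max_diameter(ls.lesions[1].filled_mask, grid.spacing)
        assert d == pytest.approx(20.0, abs=math.sqrt(3))  # one voxel diagonal

    def test_two_voxel_3_4_5(self):
        mask = np.zeros((6, 7, 3), bool)
        mask[0, 0, 0] = True
        mask[3, 4, 0] = True
        assert max_diameter(mask, (1, 1, 1)) == pytest.approx(5.0)

    def test_single_voxel_zero(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = True
        assert max_diameter(mask, (1, 1, 1)) == 0.0

    def test_anisotropic_spacing_enters_distance(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        mask[3, 0, 0] = True
        assert max_diameter(mask, (2.0, 1.0, 1.0)) == pytest.approx(6.0)


class TestCentroidAndDistances:
    def test_symmetric_sphere_centroid_at_center(self, sphere_phantom):
        grid, truth = sphere_phantom(radius=10.0)
        ls = segment_threshold(grid, ThresholdRule(fraction_of_max=0.5))
        c = centroid(ls.lesions[1].active_mask, grid.spacing, grid.origin)
        np.testing.assert_allclose(c, truth["lesions"][0]["center"], atol=0.5)

    def test_single_and_pair(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1, 2, 3] = True
        assert centroid(mask, (1, 1, 1)) == (1.0, 2.0, 3.0)
        mask[3, 2, 1] = True
        assert centroid(mask, (1, 1, 1)) == (2.0, 2.0, 2.0)

    def test_weighted_variant(self):
        mask = np.zeros((5, 1, 1), bool)
        mask[0, 0, 0] = mask[4, 0, 0] = True
        w = np.zeros((5, 1, 1))
        w[0, 0, 0], w[4, 0, 0] = 3.0, 1.0
        c = centroid(mask, (1, 1, 1), weights=w)
        assert c[0] == pytest.approx(1.0)  # (0*3 + 4*1) / 4

    def test_distances(self):
        c = (10.0, 10.0, 10.0)
        smcd, spcd = centroid_distances(c, (13.0, 14.0, 10.0), c)
        assert smcd == pytest.approx(5.0)
        assert spcd == 0.0

    def test_translation_invariance(self, sphere_phantom):
        grid, _ = sphere_phantom(radius=9.0, hotspot_radial_fraction=0.5,
                                 hotspot_suv=3.0)
        ls = segment_threshold(grid, ThresholdRule(absolute=1.0))
        pf = pet_features(grid, ls, 1)
        gf1 = geom_features(grid, ls, 1, pet=pf)
        moved = VoxelGrid(grid.values, grid.spacing, origin=(50.0, -20.0, 5.0))
        pf2 = pet_features(moved, ls, 1)
        gf2 = geom_features(moved, ls, 1, pet=pf2)
        assert gf2.smcd_mm == pytest.approx(gf1.smcd_mm, rel=1e-9)
        assert gf2.spcd_mm == pytest.approx(gf1.spcd_mm, rel=1e-9)


class TestNormalizedScd:
    def test_msr_closed_form(self):
        msr, nspcd, cls = normalized_scd(0.0, 4 / 3 * math.pi * 1000.0)
        assert msr == pytest.approx(10.0)
        assert nspcd == 0.0 and cls == "central"

    def test_classification_cut(self):
        v = 4 / 3 * math.pi * 1000.0
        assert normalized_scd(6.5, v)[2] == "central"
        assert normalized_scd(6.6, v)[2] == "peripheral"   # nspcd = 0.66 >= cut
        assert normalized_scd(6.5, v, cut=0.5)[2] == "peripheral"

    @pytest.mark.parametrize("fraction", [0.0, 0.5, 0.9])
    def test_hotspot_fraction_recovery(self, sphere_phantom, fraction):
        grid, _ = sphere_phantom(radius=15.0, shape=(44, 44, 44),
                                 hotspot_radial_fraction=fraction,
                                 hotspot_suv=4.0, background_suv=0.5, seed=3)
        ls = segment_threshold(grid, ThresholdRule(absolute=1.0))
        pf = pet_features(grid, ls, 1)
        gf = geom_features(grid, ls, 1, pet=pf)
        assert gf.nspcd == pytest.approx(fraction, abs=0.1)


class TestRimWidth:
    def test_shell_closed_form(self):
        v_out = 4 / 3 * math.pi * 10 ** 3
        v_in = 4 / 3 * math.pi * 5 ** 3
        assert rim_width(v_out, v_in) == pytest.approx(5.0)
        assert rim_width(v_out, 0.0) == pytest.approx(10.0)  # = MSR

    def test_voxelized_shell(self, sphere_phantom):
        grid, _ = sphere_phantom(radius=10.0, spacing=0.5, necrotic_core_radius=5.0)
        ls = segment_threshold(grid, ThresholdRule(fraction_of_max=0.5))
        gf = geom_features(grid, ls, 1)
        assert gf.rim_width_cm * 10 == pytest.approx(5.0, rel=0.05)

    def test_inner_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            rim_width(1.0, 2.0)


class TestScaleInvariance:
    def test_geometry_independent_of_intensity_rescale(self, sphere_phantom):
        grid, _ = sphere_phantom(radius=9.0, bumpiness=0.15,
                                 hotspot_radial_fraction=0.6, hotspot_suv=2.0, seed=5)
        ls = segment_threshold(grid, ThresholdRule(fraction_of_max=0.4))
        pf = pet_features(grid, ls, 1)
        gf1 = geom_features(grid, ls, 1, pet=pf)
        scaled = VoxelGrid(grid.values * 3.1, grid.spacing)
        ls2 = segment_threshold(scaled, ThresholdRule(fraction_of_max=0.4))
        pf2 = pet_features(scaled, ls2, 1)
        gf2 = geom_features(scaled, ls2, 1, pet=pf2)
        assert gf2.sphericity == pytest.approx(gf1.sphericity, rel=1e-9)
        assert gf2.nspcd == pytest.approx(gf1.nspcd, rel=1e-9)
        assert gf2.volume_total_ml == pytest.approx(gf1.volume_total_ml, rel=1e-12)
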