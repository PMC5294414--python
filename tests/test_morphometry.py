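import math

import numpy as np
import pytest

import vascmorph as vm
from conftest import make_cylinder_mask
from vascmorph.morphometry import section_indices


class TestVascularVolumeFraction:
    def test_empty_vessel_mask_gives_zero(self):
        tissue = vm.BinaryMask(np.ones((3, 3, 3), bool), 1.0)
        vessel = vm.BinaryMask(np.zeros((3, 3, 3), bool), 1.0)
        assert vm.vascular_volume_fraction(vessel, tissue) == 0.0

    def test_vessel_equal_tissue_gives_one(self, rng):
        data = rng.random((4, 4, 4)) > 0.5
        data[0, 0, 0] = True
        m = vm.BinaryMask(data, 1.0)
        assert vm.vascular_volume_fraction(m, m) == 1.0

    def test_cylinder_in_box_matches_analytic_ratio(self):
        # r=10 μm, L=100 μm cylinder in a 110x30x30 μm box at 1 μm voxels
        _, truth, t = make_cylinder_mask(10.0, 100.0)
        box = vm.BinaryMask(np.ones(truth.shape, bool), 1.0)
        analytic = math.pi * 10.0**2 * 100.0 / truth.data.size
        assert vm.vascular_volume_fraction(truth, box) == pytest.approx(
            analytic, rel=0.05
        )

    def test_invariant_under_axis_permutation(self, phantom):
        _, truth, _ = phantom
        tissue = vm.tissue_mask(truth, method="bounding_hull")
        ref = vm.vascular_volume_fraction(truth, tissue)
        perm = (1, 2, 0)
        v2 = vm.BinaryMask(truth.data.transpose(perm), 1.0)
        t2 = vm.BinaryMask(tissue.data.transpose(perm), 1.0)
        assert vm.vascular_volume_fraction(v2, t2) == ref

    def test_empty_tissue_raises(self):
        empty = vm.BinaryMask(np.zeros((2, 2, 2), bool), 1.0)
        with pytest.raises(ZeroDivisionError):
            vm.vascular_volume_fraction(empty, empty)


class TestEquidistantSections:
    def test_single_section_is_the_middle_slice(self):
        assert section_indices(101, 1) == [50]

    def test_twenty_sections_of_200_follow_midpoint_rule(self):
        assert section_indices(200, 20) == list(range(5, 200, 10))

    def test_indices_strictly_increase_after_collision_fix(self):
        idx = section_indices(10, 10)
        assert idx == list(range(10))
        idx = section_indices(7, 5)
        assert all(b > a for a, b in zip(idx, idx[1:]))

    @pytest.mark.parametrize("n", [0, 12])
    def test_out_of_range_section_counts_raise(self, n):
        mask = vm.BinaryMask(np.ones((10, 4, 4), bool), 1.0)
        with pytest.raises(ValueError):
            vm.extract_equidistant_sections(mask, n)

    def test_extracted_sections_come_from_the_right_slices(self, phantom):
        _, truth, _ = phantom
        secs = vm.extract_equidistant_sections(truth, 5, axis=0)
        idx = section_indices(truth.shape[0], 5)
        for s, i in zip(secs, idx):
            np.testing.assert_array_equal(s, truth.data[i])


def _disc_section(radius_px, size=64):
    yy, xx = np.mgrid[:size, :size]
    c = size / 2 - 0.5
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2


class TestCrossSections:
    def test_empty_section_yields_no_profiles(self):
        assert vm.measure_cross_sections(np.zeros((8, 8), bool), 1.0) == []

    def test_disc_equivalent_diameter_within_3pct(self):
        cs = vm.measure_cross_sections(_disc_section(10), 1.0)
        assert len(cs) == 1
        assert cs[0].equiv_diameter_um == pytest.approx(20.0, rel=0.03)

    def test_separate_discs_are_two_profiles_merged_discs_one(self):
        two = np.zeros((40, 40), bool)
        two[5:15, 5:15] = True
        two[25:35, 25:35] = True
        assert len(vm.measure_cross_sections(two, 1.0)) == 2
        merged = np.zeros((40, 40), bool)
        merged[5:15, 5:20] = True
        merged[14:30, 15:30] = True  # 8-connected bridge
        assert len(vm.measure_cross_sections(merged, 1.0)) == 1

    def test_border_policy_censors_edge_profiles(self):
        sec = np.zeros((20, 20), bool)
        sec[0:5, 0:5] = True  # touches border
        sec[10:14, 10:14] = True
        assert len(vm.measure_cross_sections(sec, 1.0, border_policy="exclude")) == 1
        assert len(vm.measure_cross_sections(sec, 1.0, border_policy="include")) == 2

    def test_min_area_filter_drops_specks(self):
        sec = np.zeros((20, 20), bool)
        sec[5, 5] = True
        sec[10:14, 10:14] = True
        assert len(vm.measure_cross_sections(sec, 1.0, min_area_px=2)) == 1


class TestDiameterDistribution:
    def _from_diameters(self, diameters, **kw):
        cs = [
            vm.VesselCrossSection(0, math.pi * (d / 2) ** 2, d, (0.0, 0.0))
            for d in diameters
        ]
        return vm.diameter_distribution(cs, **kw)

    def test_single_value_occupies_one_bin(self):
        dist = self._from_diameters([15.0] * 7)
        assert dist.median_um == 15.0
        occupied = dist.proportions[dist.proportions > 0]
        assert occupied.tolist() == [1.0]

    def test_hand_computed_three_diameter_case(self):
        dist = self._from_diameters(
            [10.0, 20.0, 30.0], bin_edges_um=np.array([0.0, 15.0, 25.0, 40.0])
        )
        np.testing.assert_allclose(dist.proportions, [1 / 3, 1 / 3, 1 / 3])
        assert dist.median_um == 20.0

    def test_lognormal_median_recovered_within_2pct(self, rng):
        # sort-based oracle: the empirical median of the draws themselves
        d = rng.lognormal(math.log(13.0), 0.3, size=10_000)
        dist = self._from_diameters(d)
        oracle = float(np.sort(d)[len(d) // 2 - 1 : len(d) // 2 + 1].mean())
        assert dist.median_um == pytest.approx(oracle, rel=1e-12)
        assert dist.median_um == pytest.approx(13.0, rel=0.02)

    def test_proportions_sum_to_one_and_overflow_bin_appended(self, rng):
        d = rng.uniform(1.0, 60.0, size=200)
        dist = self._from_diameters(d, bin_edges_um=np.array([0.0, 20.0, 40.0]))
        assert dist.proportions.sum() == pytest.approx(1.0, abs=1e-12)
        assert dist.bin_edges_um[-1] >= d.max()

    def test_empty_distribution_marker(self):
        dist = vm.diameter_distribution([])
        assert dist.is_empty and math.isnan(dist.median_um)

    def test_median_invariant_to_bin_choice(self, rng):
        d = rng.uniform(3.0, 50.0, size=99)
        a = self._from_diameters(d, bin_width_um=5.0)
        b = self._from_diameters(d, bin_width_um=2.0)
        assert a.median_um == b.median_um


class TestCompareDistributions:
    def _dist(self, proportions, median, edges=(0.0, 10.0, 20.0, 30.0)):
        return vm.DiameterDistribution(
            bin_edges_um=np.asarray(edges),
            proportions=np.asarray(proportions, dtype=float),
            n=100,
            median_um=median,
        )

    def test_identical_distributions_give_unit_ratios_zero_shift(self):
        a = self._dist([0.2, 0.5, 0.3], 15.0)
        cmp = vm.compare_size_distributions(a, a)
        np.testing.assert_allclose(cmp["ratio"], 1.0)
        assert cmp["median_shift_um"] == 0.0

    def test_one_bin_shift_reflected_in_ratios_and_median(self):
        a = self._dist([0.0, 0.5, 0.5], 20.0)  # shifted up one 10-μm bin
        b = self._dist([0.5, 0.5, 0.0], 10.0)
        cmp = vm.compare_size_distributions(a, b)
        assert cmp["undefined"].tolist() == [False, False, True]
        np.testing.assert_allclose(cmp["ratio"][:2], [0.0, 1.0])
        assert cmp["median_shift_um"] == 10.0

    def test_empty_or_mismatched_inputs_raise(self):
        a = self._dist([0.2, 0.5, 0.3], 15.0)
        empty = vm.diameter_distribution([])
        with pytest.raises(ValueError):
            vm.compare_size_distributions(a, empty)
        b = self._dist([0.2, 0.5, 0.3], 15.0, edges=(0.0, 5.0, 20.0, 30.0))
        with pytest.raises(ValueError):
            vm.compare_size_distributions(a, b)


class TestShrinkage:
    def test_equal_volumes_mean_no_shrinkage(self):
        rep = vm.shrinkage_report([("a", 1000.0), ("b", 1000.0)])
        assert rep.retained_percent == [100.0]
        assert rep.shrinkage_percent == [0.0]

    def test_swelling_reports_retained_109(self):
        rep = vm.shrinkage_report([("fresh", 1000.0), ("fixed", 1090.0)])
        assert rep.retained_percent[0] == pytest.approx(109.0)
        assert rep.shrinkage_percent[0] == pytest.approx(-9.0)

    def test_dehydration_reports_63pct_shrinkage(self):
        rep = vm.shrinkage_report([("fixed", 1000.0), ("dehydrated", 370.0)])
        assert rep.shrinkage_percent[0] == pytest.approx(63.0)
        assert rep.retained_percent[0] == pytest.approx(37.0)

    def test_multi_stage_chain_and_scale_factor(self):
        rep = vm.shrinkage_report(
            [("fresh", 1000.0), ("fixed", 1090.0), ("dehydrated", 403.3)]
        )
        assert len(rep.pairs()) == 2
        assert rep.cumulative_scale_factor() == pytest.approx(0.4033 ** (1 / 3))

    @pytest.mark.parametrize("stages", [[("a", 1.0)], [("a", 1.0), ("b", -2.0)]])
    def test_invalid_stage_lists_raise(self, stages):
        with pytest.raises(ValueError):
            vm.shrinkage_report(stages)


class TestPhantomDiameterRecovery:
    def test_perpendicular_cylinders_recover_truth_within_one_voxel(self, rng):
        radii = rng.uniform(2.0, 15.0, size=10)
        for r in radii:
            _, truth, _ = make_cylinder_mask(float(r), 30.0)
            mid = truth.data[truth.shape[0] // 2]
            cs = vm.measure_cross_sections(mid, 1.0, border_policy="include")
            assert len(cs) == 1
            assert abs(cs[0].equiv_diameter_um - 2 * r) <= 1.0

    def test_oblique_cylinder_bias_is_upward(self):
        # a cylinder tilted against the section normal cuts an elliptical
        # profile whose equivalent diameter can only exceed the true one
        r = 6.0
        p0 = np.array([5.0, 30.0, 10.0])
        tilt = math.radians(30.0)
        p1 = p0 + 60.0 * np.array([math.cos(tilt), 0.0, math.sin(tilt)])
        seg = vm.VesselSegment(p0=p0, p1=p1, radius_um=r)
        _, truth = vm.rasterize_tree(
            vm.VesselTree(segments=[seg]),
            1.0,
            volume_shape=(70, 60, 60),
            origin_um=(0.0, 0.0, 0.0),
        )
        mid = truth.data[truth.shape[0] // 2]
        cs = vm.measure_cross_sections(mid, 1.0, border_policy="include")
        assert len(cs) == 1
        assert cs[0].equiv_diameter_um >= 2 * r
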