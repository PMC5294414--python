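import math

import numpy as np
import pytest

import vascmorph as vm
from vascmorph.phantoms import generate_classification_counts


class TestTreeGeneration:
    def test_depth_zero_is_one_straight_root_segment(self):
        t = vm.generate_vessel_tree(root_radius_um=10.0, depth=0, seed=0)
        assert len(t.segments) == 1
        seg = t.segments[0]
        assert seg.radius_um == 10.0
        assert seg.parent == -1
        assert math.isclose(seg.length_um, seg.chord_um)

    def test_symmetric_murray_split_halves_cubed_radius(self):
        t = vm.generate_vessel_tree(root_radius_um=10.0, depth=1, seed=0)
        children = [t.segments[i] for i in t.children_of(0)]
        assert len(children) == 2
        for c in children:
            assert math.isclose(c.radius_um, 10.0 * 2 ** (-1 / 3), rel_tol=1e-12)

    @pytest.mark.parametrize("m", [2.0, 2.7, 3.0])
    @pytest.mark.parametrize("split", [0.5, 0.3])
    def test_murray_law_holds_exactly_at_every_bifurcation(self, m, split):
        t = vm.generate_vessel_tree(
            depth=4, murray_exponent=m, split_fraction=split, seed=3
        )
        res = vm.murray_residuals(t)
        assert len(res) == 2**4 - 1
        assert res.max() < 1e-9

    def test_same_seed_reproduces_tree_bitwise(self):
        kw = dict(depth=3, tortuosity_amplitude_um=3.0)
        a = vm.generate_vessel_tree(seed=5, **kw)
        b = vm.generate_vessel_tree(seed=5, **kw)
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.points, sb.points)
        c = vm.generate_vessel_tree(seed=6, **kw)
        assert any(
            not np.array_equal(sa.points, sc.points)
            for sa, sc in zip(a.segments, c.segments)
        )

    def test_tortuosity_lengthens_paths_but_keeps_connectivity(self):
        t = vm.generate_vessel_tree(depth=3, tortuosity_amplitude_um=4.0, seed=2)
        tortuosities = [s.length_um / s.chord_um for s in t.segments]
        assert max(tortuosities) > 1.01
        for i, s in enumerate(t.segments):
            if s.parent >= 0:
                np.testing.assert_allclose(s.points[0], t.segments[s.parent].points[-1])

    @pytest.mark.parametrize("kw", [{"root_radius_um": -1}, {"depth": -1}])
    def test_invalid_parameters_raise(self, kw):
        with pytest.raises(ValueError):
            vm.generate_vessel_tree(**kw)


class TestRasterization:
    def test_empty_tree_gives_background_only(self):
        t = vm.VesselTree(segments=[])
        vol, mask = vm.rasterize_tree(
            t, 1.0, volume_shape=(4, 4, 4), fg_intensity=200, bg_intensity=50
        )
        assert mask.count() == 0
        assert set(np.unique(vol.data)) == {50.0}

    def test_cylinder_mask_volume_matches_analytic_within_5pct(self):
        from conftest import make_cylinder_mask

        _, truth, t = make_cylinder_mask(radius_um=10.0, length_um=100.0)
        analytic = math.pi * 10.0**2 * 100.0
        assert truth.volume_um3() == pytest.approx(analytic, rel=0.05)

    def test_discretization_error_shrinks_with_voxel_size(self):
        from conftest import make_cylinder_mask

        analytic = math.pi * 6.0**2 * 60.0
        errs = []
        for vs in (2.0, 0.5):
            _, truth, _ = make_cylinder_mask(6.0, 60.0, voxel_size_um=vs)
            errs.append(abs(truth.volume_um3() - analytic) / analytic)
        assert errs[1] < errs[0]

    def test_zero_noise_volume_is_exactly_two_valued(self, tree):
        vol, _ = vm.rasterize_tree(tree, 2.0, noise_sigma=0.0)
        assert set(np.unique(vol.data)) <= {50.0, 200.0}

    def test_noise_is_seeded(self, tree):
        v1, _ = vm.rasterize_tree(tree, 2.0, noise_sigma=10.0, seed=9)
        v2, _ = vm.rasterize_tree(tree, 2.0, noise_sigma=10.0, seed=9)
        np.testing.assert_array_equal(v1.data, v2.data)


class TestHistologyScene:
    def test_zero_profile_gives_fibers_only(self):
        s = vm.generate_histology_scene((500, 500), 50, 0.0, seed=1)
        labels = set(s.points["label"])
        assert labels == {"fiber"}

    def test_mean_ratio_recovers_constant_profile(self):
        # Monte-Carlo oracle: capillaries per fiber are Poisson(c), so the
        # pooled capillary:fiber ratio estimates c; check within 3 SE.
        c = 1.8
        ratios = []
        for seed in range(100):
            s = vm.generate_histology_scene((600, 600), 50, c, seed=seed)
            n_cap = (s.points["label"] == "capillary").sum()
            n_fib = (s.points["label"] == "fiber").sum()
            ratios.append(n_cap / n_fib)
        se = np.std(ratios, ddof=1) / math.sqrt(len(ratios))
        assert abs(np.mean(ratios) - c) < 3 * se

    def test_two_band_profile_orders_band_ratios(self):
        def profile(x, y):
            return 3.0 if y < 500 else 1.0

        wins = 0
        n_seeds = 100
        for seed in range(n_seeds):
            s = vm.generate_histology_scene((600, 1000), 50, profile, seed=seed)
            df = s.points
            deep = df[df.y_um < 500]
            sup = df[df.y_um >= 500]
            r_deep = (deep.label == "capillary").sum() / (deep.label == "fiber").sum()
            r_sup = (sup.label == "capillary").sum() / (sup.label == "fiber").sum()
            wins += r_deep > r_sup
        assert wins >= 0.95 * n_seeds

    def test_pitch_exceeding_extent_raises(self):
        with pytest.raises(ValueError):
            vm.generate_histology_scene((100, 100), 200, 1.0, seed=0)


class TestClassificationCounts:
    def test_degenerate_proportions_give_all_double_positive(self):
        c = generate_classification_counts((1.0, 0.0, 0.0), seed=0)
        assert c.table["n_pm"].sum() == 0
        assert c.table["n_mp"].sum() == 0
        assert c.table["n_pp"].sum() == c.total() > 0

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            generate_classification_counts((0.9, 0.05, 0.02), seed=0)

    def test_same_seed_reproduces_counts(self):
        a = generate_classification_counts((0.91, 0.07, 0.02), seed=4)
        b = generate_classification_counts((0.91, 0.07, 0.02), seed=4)
        assert a.table.equals(b.table)

    def test_design_shape_matches_request(self):
        c = generate_classification_counts(
            (0.91, 0.07, 0.02), n_animals=2, sections_per_animal=3,
            fovs_per_section=4, seed=0
        )
        assert len(c.table) == 2 * 3 * 4
        assert set(c.table["animal"]) == {0, 1}
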