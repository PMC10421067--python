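"""Generator contracts: trees, rasterization, perfusion forward model,
Hertz curves, and warping."""

import numpy as np
import pytest

from vascmorph import mechanics
from vascmorph.core_io import ImageVolume, VoxelGrid
from vascmorph.synthsim import (
    CurveParams,
    PerfusionParams,
    Segment,
    TreeParams,
    VesselTree,
    generate_tree,
    rasterize,
    render_perfusion,
    simulate_scene,
    speckle_volume,
    synth_force_curve,
    warp,
)


class TestGenerateTree:
    def test_seed_contract(self):
        a = generate_tree(TreeParams(seed=1, max_segments=20))
        b = generate_tree(TreeParams(seed=1, max_segments=20))
        c = generate_tree(TreeParams(seed=2, max_segments=20))
        assert len(a.segments) == len(b.segments)
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.polyline, sb.polyline)
        first_a, first_c = a.segments[0].polyline, c.segments[0].polyline
        assert first_a.shape != first_c.shape or not np.allclose(first_a, first_c)

    def test_no_branching_gives_unbranched_paths(self):
        tree = generate_tree(
            TreeParams(seed=2, branching_prob=0.0, n_roots=2, max_segments=30)
        )
        children_per_node = {}
        for seg in tree.segments:
            children_per_node[seg.parent_node] = (
                children_per_node.get(seg.parent_node, 0) + 1
            )
        assert max(children_per_node.values()) == 1

    def test_mean_segment_length_matches_stated_distribution(self):
        # pooled over trees: mean within 5% of the 90 μm study morphology
        lengths = []
        seed = 42
        while len(lengths) < 2000:
            tree = generate_tree(TreeParams(seed=seed, max_segments=100))
            lengths.extend(s.length for s in tree.segments)
            seed += 1
        mean = np.mean(lengths)
        assert abs(mean - 90.0) / 90.0 < 0.05

    def test_radii_within_range(self):
        tree = generate_tree(TreeParams(seed=3, max_segments=60))
        lo, hi = 5.0 / 2, 150.0 / 2
        for seg in tree.segments:
            assert lo <= seg.radius_lateral <= hi
            assert seg.radius_transversal == pytest.approx(
                seg.radius_lateral * (30.0 / 44.0)
            )

    def test_polylines_inside_slab(self):
        params = TreeParams(seed=4, max_segments=80)
        tree = generate_tree(params)
        slab = np.asarray(params.slab_um)
        for seg in tree.segments:
            assert np.all(seg.polyline >= -1e-9)
            assert np.all(seg.polyline <= slab + 1e-9)

    def test_tiny_slab_rejected(self):
        with pytest.raises(ValueError, match="slab"):
            generate_tree(TreeParams(slab_um=(10.0, 10.0, 10.0)))


class TestRasterize:
    def test_circular_tube_cross_section_extents(self, straight_tube):
        # radius 20 μm at 1-pitch-2 voxels: extents 40 μm ± 2 voxels mid-tube
        mid = straight_tube["lumen"].voxels[:, :, 140]
        y_extent = mid.any(axis=0).sum() * 2.0
        z_extent = mid.any(axis=1).sum() * 2.0
        assert abs(y_extent - 40.0) <= 4.0
        assert abs(z_extent - 40.0) <= 4.0

    def test_anisotropic_tube_extent_ratio(self):
        start, end = np.array([60.0, 60.0, 20.0]), np.array([60.0, 60.0, 220.0])
        tree = VesselTree(
            nodes=[start, end],
            segments=[Segment(0, 1, np.vstack([start, end]), 22.0, 15.0)],
            roots=[0],
        )
        grid = VoxelGrid((120, 120, 120), (1.0, 1.0, 1.0))
        _, lumen, _ = rasterize(tree, grid)
        mid = lumen.voxels[:, :, 60]
        ratio = mid.any(axis=1).sum() / mid.any(axis=0).sum()
        assert ratio == pytest.approx(30.0 / 44.0, rel=0.1)

    def test_volume_fraction_converges_to_analytic(self):
        # tube volume / slab volume approaches pi r^2 L / V as voxels shrink
        start, end = np.array([40.0, 40.0, 10.0]), np.array([40.0, 40.0, 150.0])
        analytic = np.pi * 15.0**2 * 140.0
        errors = []
        for pitch in (8.0, 2.0):
            shape = tuple(int(round(s / pitch)) for s in (80, 80, 160))
            tree = VesselTree(
                nodes=[start, end],
                segments=[Segment(0, 1, np.vstack([start, end]), 15.0, 15.0)],
                roots=[0],
            )
            _, lumen, _ = rasterize(tree, VoxelGrid(shape, (pitch,) * 3))
            measured = lumen.volume_um3
            # subtract the two rounded end caps (two half-ellipsoids)
            caps = 4.0 / 3.0 * np.pi * 15.0**3
            errors.append(abs(measured - caps - analytic) / analytic)
        assert errors[1] < errors[0]
        assert errors[1] < 0.05

    def test_empty_tree_rejected(self):
        with pytest.raises(ValueError):
            rasterize(
                VesselTree(nodes=[], segments=[], roots=[]),
                VoxelGrid((4, 4, 4), (1, 1, 1)),
            )


class TestRenderPerfusion:
    def test_zero_permeability_leaves_timepoints_identical(self, branched_tree_scene):
        s = branched_tree_scene
        t1, t2 = render_perfusion(
            s["tree"], s["grid"], s["lumen"], s["labels"],
            PerfusionParams(permeability_cm_s=0.0, noise_sd=0.0),
        )
        np.testing.assert_array_equal(t1.channel("dextran"), t2.channel("dextran"))

    def test_interstitial_increment_matches_closed_form(self, branched_tree_scene):
        from vascmorph.synthsim import perfused_surface_area_um2

        s = branched_tree_scene
        p = PerfusionParams(permeability_cm_s=2e-7, noise_sd=0.0)
        t1, t2 = render_perfusion(s["tree"], s["grid"], s["lumen"], s["labels"], p)
        inter = ~s["lumen"].voxels
        measured = t2.channel("dextran")[inter].mean() - t1.channel("dextran")[inter].mean()
        s_cm2 = perfused_surface_area_um2(s["lumen"].voxels, s["grid"].spacing) * 1e-8
        v_cm3 = inter.sum() * s["grid"].voxel_volume * 1e-12
        expected = 2e-7 * 1200.0 * (s_cm2 / v_cm3) * (
            p.lumen_intensity - p.baseline_intensity
        )
        assert measured == pytest.approx(expected, rel=1e-12)

    def test_half_perfused_fills_exactly_one_branch(self, two_branch_tree):
        s = two_branch_tree
        t1, _ = render_perfusion(
            s["tree"], s["grid"], s["lumen"], s["labels"],
            PerfusionParams(perfused_fraction=0.5, permeability_cm_s=0.0),
        )
        dex = t1.channel("dextran")
        filled = {
            seg_id: (dex[s["labels"] == seg_id + 1] > 500).all()
            for seg_id in (0, 1)
        }
        assert sorted(filled.values()) == [False, True]

    def test_unconnected_perfusion_rejected(self, two_branch_tree):
        s = two_branch_tree
        orphan = VesselTree(nodes=s["tree"].nodes, segments=s["tree"].segments, roots=[])
        with pytest.raises(ValueError, match="root"):
            render_perfusion(
                orphan, s["grid"], s["lumen"], s["labels"],
                PerfusionParams(perfused_fraction=1.0),
            )


class TestSynthForceCurve:
    def test_hertz_value_at_one_micron(self):
        # E_app 1000 Pa, R 25 μm, δ 1 μm -> 6.67 nN
        assert mechanics.hertz_force(1.0, 1000.0, 25.0) == pytest.approx(6.6667, rel=1e-3)

    def test_noise_free_curve_reproduces_hertz_everywhere(self):
        p = CurveParams(apparent_modulus_pa=800.0, contact_offset_um=1.5)
        curve = synth_force_curve(p)
        delta = np.clip(curve.extension_um - 1.5, 0.0, None)
        np.testing.assert_allclose(
            curve.force_nn, mechanics.hertz_force(delta, 800.0, 25.0), atol=1e-12
        )
        assert curve.force_nn.max() <= 30.0 + 1e-9

    def test_force_linear_in_modulus(self):
        c1 = synth_force_curve(CurveParams(apparent_modulus_pa=500.0))
        c2 = synth_force_curve(CurveParams(apparent_modulus_pa=1000.0))
        n = min(c1.force_nn.size, c2.force_nn.size)
        np.testing.assert_allclose(c2.force_nn[:n], 2.0 * c1.force_nn[:n], atol=1e-9)

    def test_oversized_sampling_step_rejected(self):
        with pytest.raises(ValueError, match="step"):
            synth_force_curve(CurveParams(apparent_modulus_pa=5000.0, step_nm=5000.0))


class TestWarp:
    def test_zero_field_is_identity(self, speckle_pair_grid):
        grid, pre = speckle_pair_grid
        out = warp(pre, np.zeros((3,) + grid.shape))
        np.testing.assert_allclose(out.channel("matrix"), pre.channel("matrix"), atol=1e-12)

    def test_integer_shift_equals_roll_in_interior(self, speckle_pair_grid):
        grid, pre = speckle_pair_grid
        u = np.zeros((3,) + grid.shape)
        u[0], u[1], u[2] = 1 * 2.0, 2 * 2.0, 3 * 2.0  # (1,2,3) voxels in μm
        out = warp(pre, u)
        rolled = np.roll(pre.channel("matrix"), (1, 2, 3), axis=(0, 1, 2))
        core = (slice(4, -4),) * 3
        np.testing.assert_allclose(out.channel("matrix")[core], rolled[core], atol=1e-9)

    def test_mismatched_field_shape_rejected(self, speckle_pair_grid):
        grid, pre = speckle_pair_grid
        with pytest.raises(ValueError):
            warp(pre, np.zeros((3, 2, 2, 2)))


class TestScene:
    def test_scene_is_deterministic_and_complete(self):
        a = simulate_scene("default-day4", seed=5)
        b = simulate_scene("default-day4", seed=5)
        np.testing.assert_array_equal(
            a.volume.channel("ec"), b.volume.channel("ec")
        )
        np.testing.assert_array_equal(
            a.dextran_t2.channel("dextran"), b.dextran_t2.channel("dextran")
        )
        assert a.speckle_pre.grid.shape == (48, 48, 48)
        assert a.truth["max_displacement_um"] > 0
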