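"""Skeletonization, network length, diameters, and branching geometry."""

import numpy as np
import pytest

from vascmorph import morphometry as mm
from vascmorph.core_io import BinaryMask, VoxelGrid
from vascmorph.synthsim import TreeParams, generate_tree

from conftest import make_tube


@pytest.fixture(scope="module")
def tube_graph(straight_tube):
    return mm.skeletonize(straight_tube["lumen"], mode="3d")


class TestSkeletonize:
    def test_straight_tube_is_single_edge_with_true_length(self, straight_tube, tube_graph):
        g = tube_graph
        assert g.graph.number_of_edges() == 1
        pitch = max(straight_tube["grid"].spacing)
        assert mm.longest_network_length(g) == pytest.approx(
            straight_tube["length"], abs=pitch
        )

    def test_projected_mode_matches_tube_length(self, straight_tube):
        g2 = mm.skeletonize(straight_tube["lumen"], mode="2d-projected")
        assert g2.mode == "2d-projected"
        assert mm.longest_network_length(g2) == pytest.approx(500.0, abs=4.0)

    def test_anisotropic_spacing_resampled_before_thinning(self):
        _, _, _, lumen, _ = make_tube(
            (30, 50, 30), (30, 50, 530), 20.0, 20.0, (15, 50, 280), (4.0, 2.0, 2.0)
        )
        g = mm.skeletonize(lumen, mode="3d")
        assert mm.longest_network_length(g) == pytest.approx(500.0, abs=4.0)

    def test_y_junction_topology_recovered(self, y_junction):
        g = mm.skeletonize(y_junction["lumen"], mode="3d")
        kinds = [d["kind"] for _, d in g.graph.nodes(data=True)]
        assert kinds.count("junction") == 1
        assert kinds.count("endpoint") == 3
        assert g.graph.number_of_edges() == 3

    def test_solid_sphere_leaves_no_elongated_structure(self):
        grid = VoxelGrid((40, 40, 40), (2.0, 2.0, 2.0))
        zz, yy, xx = np.indices(grid.shape, dtype=float) * 2.0
        ball = (zz - 40) ** 2 + (yy - 40) ** 2 + (xx - 40) ** 2 <= 30.0**2
        g = mm.skeletonize(BinaryMask(grid=grid, voxels=ball), mode="3d")
        assert g.total_length() == 0.0

    def test_empty_mask_gives_empty_graph(self):
        grid = VoxelGrid((4, 4, 4), (1, 1, 1))
        g = mm.skeletonize(BinaryMask(grid=grid, voxels=np.zeros(grid.shape, bool)))
        assert g.graph.number_of_nodes() == 0

    def test_total_length_invariant_under_quarter_turns(self, straight_tube):
        base = mm.skeletonize(straight_tube["lumen"], mode="3d").total_length()
        rotated = np.rot90(straight_tube["lumen"].voxels, k=1, axes=(1, 2))
        grid = VoxelGrid(rotated.shape, straight_tube["grid"].spacing)
        turned = mm.skeletonize(BinaryMask(grid=grid, voxels=rotated), mode="3d")
        assert turned.total_length() == pytest.approx(base, abs=2 * 2.0)


class TestNetworkLength:
    def test_longest_component_wins(self):
        # two disjoint tubes, 300 and 500 μm
        _, _, _, lum_a, _ = make_tube(
            (20, 30, 20), (20, 30, 320), 12.0, 12.0, (20, 60, 280), (2.0, 2.0, 2.0)
        )
        _, _, _, lum_b, _ = make_tube(
            (20, 90, 30), (20, 90, 530), 12.0, 12.0, (20, 60, 280), (2.0, 2.0, 2.0)
        )
        grid = VoxelGrid((20, 60, 280), (2.0, 2.0, 2.0))
        both = BinaryMask(grid=grid, voxels=lum_a.voxels | lum_b.voxels)
        g = mm.skeletonize(both, mode="3d")
        assert len(g.components()) == 2
        assert mm.longest_network_length(g) == pytest.approx(500.0, abs=4.0)

    def test_empty_graph_has_zero_length(self):
        assert mm.longest_network_length(mm.SkeletonGraph()) == 0.0

    def test_longest_never_exceeds_total(self, y_junction):
        g = mm.skeletonize(y_junction["lumen"], mode="3d")
        assert mm.longest_network_length(g) <= g.total_length() + 1e-9
        assert mm.longest_network_length(g) == pytest.approx(g.total_length())


class TestMeasureDiameters:
    def test_circular_tube_diameters(self, straight_tube, tube_graph):
        d = mm.measure_diameters(tube_graph, straight_tube["lumen"])
        assert d.shape[0] > 20
        pitch = 2.0
        assert abs(d[:, 0].mean() - 40.0) <= 2 * pitch
        assert abs(d[:, 1].mean() - 40.0) <= 2 * pitch

    def test_elliptical_tube_anisotropy(self, elliptical_tube):
        lumen = elliptical_tube["lumen"]
        g = mm.skeletonize(lumen, mode="3d")
        d = mm.measure_diameters(g, lumen)
        lat, trans = d[:, 0].mean(), d[:, 1].mean()
        assert lat == pytest.approx(44.0, abs=4.0)
        assert trans == pytest.approx(30.0, abs=4.0)
        assert trans / lat == pytest.approx(30.0 / 44.0, rel=0.1)

    def test_diameter_recovery_across_radii(self):
        # ground-truth 2a recovered within 2 voxel pitches for r >= 3 voxels
        for seed, radius in [(0, 8.0), (1, 12.0), (2, 16.0)]:
            rng = np.random.default_rng(seed)
            y = float(rng.uniform(40, 60))
            _, _, _, lumen, _ = make_tube(
                (30, y, 30), (30, y, 330), radius, radius, (30, 50, 180), (2.0, 2.0, 2.0)
            )
            g = mm.skeletonize(lumen, mode="3d")
            d = mm.measure_diameters(g, lumen)
            assert abs(d[:, 0].mean() - 2 * radius) <= 4.0

    def test_single_voxel_blob_has_no_valid_samples(self):
        grid = VoxelGrid((9, 9, 9), (2.0, 2.0, 2.0))
        vox = np.zeros(grid.shape, bool)
        vox[4, 4, 4] = True
        g = mm.SkeletonGraph()
        g.graph.add_node(0, pos=np.array([8.0, 8.0, 8.0]), kind="endpoint")
        d = mm.measure_diameters(g, BinaryMask(grid=grid, voxels=vox))
        assert d.size == 0


class TestHydraulicDiameter:
    def test_circle_identity(self):
        assert mm.hydraulic_diameter(40.0, 40.0) == pytest.approx(40.0)

    def test_day7_axes_give_ellipse_value(self):
        # numeric ellipse-perimeter oracle for axes (44, 30):
        # A = pi*22*15, Ramanujan-II perimeter, D_h = 4A/P = 35.36 μm
        assert mm.hydraulic_diameter(44.0, 30.0) == pytest.approx(35.36, abs=0.05)

    def test_vanishing_axis_limit(self):
        assert mm.hydraulic_diameter(40.0, 1e-6) < 1e-5

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            mm.hydraulic_diameter(0.0, 10.0)


class TestDensityAndVolumeFraction:
    def test_edge_count_per_area(self, tube_graph, straight_tube):
        density, _ = mm.density_and_volume_fraction(
            straight_tube["lumen"], tube_graph, roi_area_mm2=0.5
        )
        assert density == pytest.approx(1 / 0.5)

    def test_volume_fraction_is_mask_fraction(self, straight_tube):
        _, frac = mm.density_and_volume_fraction(
            straight_tube["lumen"], mm.SkeletonGraph(), roi_area_mm2=1.0
        )
        assert frac == pytest.approx(100.0 * straight_tube["lumen"].voxels.mean())

    def test_zero_area_rejected(self, straight_tube):
        with pytest.raises(ValueError):
            mm.density_and_volume_fraction(straight_tube["lumen"], mm.SkeletonGraph(), 0.0)


class TestBranchingGeometry:
    def test_constructed_y_angle_recovered(self, y_junction):
        g = mm.skeletonize(y_junction["lumen"], mode="3d")
        geom = mm.branching_geometry(g)
        assert geom.angles_deg.size == 1
        assert geom.angles_deg[0] == pytest.approx(90.0, abs=5.0)

    def test_unbranched_tube_has_no_angles(self, tube_graph):
        assert mm.branching_geometry(tube_graph).angles_deg.size == 0

    def test_generator_angle_distribution_recovered(self):
        # stated opening-angle distribution N(70°, 10°) recovered within 3°
        angles = []
        seed = 100
        while len(angles) < 500:
            tree = generate_tree(
                TreeParams(seed=seed, max_segments=120, branching_prob=0.5)
            )
            g = mm.skeleton_from_tree(tree)
            angles.extend(mm.branching_geometry(g).angles_deg)
            seed += 1
        assert abs(np.mean(angles) - 70.0) <= 3.0

    def test_interbranch_distance_from_ground_truth_graph(self):
        tree = generate_tree(TreeParams(seed=7, max_segments=60, branching_prob=0.6))
        g = mm.skeleton_from_tree(tree)
        geom = mm.branching_geometry(g)
        if geom.interbranch_distances_um.size:
            assert np.all(geom.interbranch_distances_um > 0)
        assert geom.segment_radii_um.size == len(tree.segments)
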