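"""Displacement recovery, histograms, strain tensors, near-vessel stats."""

import numpy as np
import pytest
from scipy import ndimage

from vascmorph import dvc_strain as dv
from vascmorph.core_io import BinaryMask, ImageVolume, VoxelGrid
from vascmorph.synthsim import radial_field, speckle_volume, warp

INTERIOR = (slice(1, -1),) * 3


def _field(grid_shape, spacing, u, quality=None):
    grid = VoxelGrid(grid_shape, spacing)
    q = np.ones(grid_shape) if quality is None else quality
    return dv.DisplacementField(grid=grid, u=u, quality=q, source_spacing=(2, 2, 2))


class TestDvc:
    def test_integer_translation_recovered_exactly(self, speckle_pair_grid):
        grid, pre = speckle_pair_grid
        rolled = np.roll(pre.channel("matrix"), (3, 2, 1), axis=(0, 1, 2))
        post = ImageVolume(grid=grid, channels={"matrix": rolled})
        field = dv.dvc(pre, post, window=16, overlap=0.5)
        u_vox = field.u[(slice(None),) + INTERIOR] / 2.0
        expected = np.array([3.0, 2.0, 1.0])[:, None, None, None]
        np.testing.assert_array_equal(u_vox, np.broadcast_to(expected, u_vox.shape))
        assert field.quality[INTERIOR].min() == pytest.approx(1.0)

    def test_self_correlation_gives_zero_field(self, speckle_pair_grid):
        _, pre = speckle_pair_grid
        field = dv.dvc(pre, pre, window=16)
        assert field.magnitude().max() == 0.0
        assert field.quality.min() == pytest.approx(1.0)

    def test_half_voxel_shift_within_tenth_voxel(self, speckle_pair_grid):
        grid, pre = speckle_pair_grid
        u = np.zeros((3,) + grid.shape)
        u[2] = 0.5 * grid.spacing[2]
        post = warp(pre, u)
        field = dv.dvc(pre, post, window=16)
        ux_vox = field.u[2][INTERIOR] / grid.spacing[2]
        assert np.abs(ux_vox - 0.5).max() <= 0.1

    def test_featureless_window_flagged_not_fatal(self):
        grid = VoxelGrid((32, 32, 32), (1.0, 1.0, 1.0))
        flat = ImageVolume(grid=grid, channels={"matrix": np.zeros(grid.shape)})
        field = dv.dvc(flat, flat, window=16)
        assert np.all(field.quality == 0.0)
        assert field.magnitude().max() == 0.0

    def test_mismatched_grids_rejected(self, speckle_pair_grid):
        _, pre = speckle_pair_grid
        other = speckle_volume(VoxelGrid((32, 32, 32), (1.0, 1.0, 1.0)), seed=2)
        with pytest.raises(ValueError):
            dv.dvc(pre, other)

    def test_radial_relaxation_field_recovered(self, speckle_pair_grid):
        grid, pre = speckle_pair_grid
        true_field = radial_field(grid, 0.5 * np.asarray(grid.extent), 6.0)
        post = warp(pre, true_field)
        field = dv.dvc(pre, post, window=16, overlap=0.5)
        axes = [
            (field.grid.origin[d] + np.arange(field.grid.shape[d]) * field.grid.spacing[d])
            / grid.spacing[d]
            for d in range(3)
        ]
        idx = np.stack(np.meshgrid(*axes, indexing="ij"))
        truth = np.stack(
            [ndimage.map_coordinates(true_field[c], idx, order=1) for c in range(3)]
        )
        err = np.linalg.norm(field.u - truth, axis=0)
        assert np.median(err) < 1.0  # μm; window-scale averaging of a smooth field
        assert field.magnitude().max() > 5.0


class TestDisplacementHistogram:
    def test_uniform_field_single_bin(self):
        u = np.zeros((3, 4, 4, 4))
        u[2] = 5.0
        hist = dv.displacement_histogram(_field((4, 4, 4), (8, 8, 8), u), bins=5)
        assert hist.frequencies.sum() == pytest.approx(1.0)
        assert (hist.frequencies > 0).sum() >= 1
        assert hist.frequencies.max() == pytest.approx(1.0)

    def test_zero_field_empty_histogram(self):
        hist = dv.displacement_histogram(_field((4, 4, 4), (8, 8, 8), np.zeros((3, 4, 4, 4))))
        assert hist.empty
        assert hist.frequencies.size == 0

    def test_low_quality_nodes_excluded(self):
        u = np.zeros((3, 4, 4, 4))
        u[2] = 5.0
        q = np.zeros((4, 4, 4))
        hist = dv.displacement_histogram(_field((4, 4, 4), (8, 8, 8), u, quality=q))
        assert hist.empty

    def test_support_reaches_field_maximum(self, speckle_pair_grid):
        grid, pre = speckle_pair_grid
        true_field = radial_field(grid, 0.5 * np.asarray(grid.extent), 6.5)
        post = warp(pre, true_field)
        field = dv.dvc(pre, post, window=16, overlap=0.5)
        hist = dv.displacement_histogram(field)
        assert not hist.empty
        assert hist.bin_edges_um[-1] > 5.5


class TestStrainField:
    def test_uniaxial_gradient(self):
        shape = (5, 6, 7)
        zz, yy, xx = np.indices(shape, dtype=float) * 4.0
        u = np.zeros((3,) + shape)
        u[2] = 0.01 * xx
        strain = dv.strain_field(_field(shape, (4, 4, 4), u))
        np.testing.assert_allclose(strain.tensor[..., 2, 2], 0.01, atol=1e-12)
        assert np.abs(strain.tensor[..., 0, 0]).max() < 1e-12
        assert np.abs(strain.tensor[..., 1, 2]).max() < 1e-12

    def test_rigid_translation_strain_free(self):
        u = np.full((3, 4, 4, 4), 3.0)
        strain = dv.strain_field(_field((4, 4, 4), (4, 4, 4), u))
        np.testing.assert_allclose(strain.tensor, 0.0, atol=1e-12)

    def test_small_rotation_strain_free(self):
        shape = (5, 6, 7)
        zz, yy, xx = np.indices(shape, dtype=float) * 4.0
        theta = 1e-3
        u = np.zeros((3,) + shape)
        u[1] = -theta * xx
        u[2] = theta * yy
        strain = dv.strain_field(_field(shape, (4, 4, 4), u))
        assert np.abs(strain.tensor).max() < 1e-6

    def test_affine_field_symmetric_gradient_machine_precision(self):
        shape = (5, 5, 5)
        rng = np.random.default_rng(0)
        A = rng.normal(scale=0.01, size=(3, 3))
        coords = np.indices(shape, dtype=float) * 4.0
        u = np.einsum("ij,j...->i...", A, coords)
        strain = dv.strain_field(_field(shape, (4, 4, 4), u))
        expected = 0.5 * (A + A.T)
        np.testing.assert_allclose(
            strain.tensor, np.broadcast_to(expected, shape + (3, 3)), atol=1e-13
        )
        assert np.all(np.isreal(strain.principal))

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            dv.strain_field(_field((2, 4, 4), (4, 4, 4), np.zeros((3, 2, 4, 4))))


class TestNearVesselStatistics:
    def _lumen(self):
        grid = VoxelGrid((24, 24, 24), (4.0, 4.0, 4.0))
        vox = np.zeros(grid.shape, bool)
        vox[10:14, 10:14, :] = True  # x-aligned square channel
        return BinaryMask(grid=grid, voxels=vox)

    def test_decaying_field_concentrates_near_vessel(self):
        lumen = self._lumen()
        shape = (12, 12, 12)
        grid = VoxelGrid(shape, (8.0, 8.0, 8.0))
        dist = ndimage.distance_transform_edt(~lumen.voxels, sampling=lumen.grid.spacing)
        node_idx = np.stack(np.meshgrid(*[np.arange(s) * 2 for s in shape], indexing="ij"))
        node_dist = dist[tuple(node_idx)]
        u = np.zeros((3,) + shape)
        u[1] = 5.0 * np.exp(-node_dist / 20.0)
        field = dv.DisplacementField(
            grid=grid, u=u, quality=np.ones(shape), source_spacing=(4, 4, 4)
        )
        stats = dv.near_vessel_statistics(field, lumen, shell_um=20.0)
        assert stats["shell_mean"] > stats["far_mean"]

    def test_uniform_field_shell_equals_far(self):
        lumen = self._lumen()
        shape = (12, 12, 12)
        u = np.full((3,) + shape, 2.0)
        field = dv.DisplacementField(
            grid=VoxelGrid(shape, (8.0, 8.0, 8.0)),
            u=u,
            quality=np.ones(shape),
            source_spacing=(4, 4, 4),
        )
        stats = dv.near_vessel_statistics(field, lumen, shell_um=20.0)
        assert stats["shell_mean"] == pytest.approx(stats["far_mean"])

    def test_empty_mask_rejected(self):
        grid = VoxelGrid((8, 8, 8), (4.0, 4.0, 4.0))
        empty = BinaryMask(grid=grid, voxels=np.zeros(grid.shape, bool))
        field = _field((4, 4, 4), (8, 8, 8), np.zeros((3, 4, 4, 4)))
        with pytest.raises(ValueError):
            dv.near_vessel_statistics(field, empty)


class TestDriftRemoval:
    def test_uniform_drift_subtracted(self):
        u = np.full((3, 4, 4, 4), 1.5)
        out = dv.remove_rigid_drift(_field((4, 4, 4), (8, 8, 8), u))
        assert out.magnitude().max() == pytest.approx(0.0, abs=1e-12)
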