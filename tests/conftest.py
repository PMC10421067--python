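"""Shared synthetic fixtures: rasterized tubes, trees, and speckle pairs."""

import numpy as np
import pytest

from vascmorph.core_io import ImageVolume, VoxelGrid
from vascmorph.synthsim import Segment, VesselTree, rasterize, speckle_volume


def make_tube(start, end, radius_lateral, radius_transversal, shape, spacing):
    """Rasterize a single straight tube; returns (tree, grid, volume, lumen, labels)."""
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    tree = VesselTree(
        nodes=[start, end],
        segments=[
            Segment(0, 1, np.vstack([start, end]), radius_lateral, radius_transversal)
        ],
        roots=[0],
    )
    grid = VoxelGrid(shape, spacing)
    volume, lumen, labels = rasterize(tree, grid)
    return tree, grid, volume, lumen, labels


@pytest.fixture(scope="session")
def straight_tube():
    """x-aligned circular tube: radius 20 μm, length 500 μm, 2 μm voxels."""
    tree, grid, volume, lumen, labels = make_tube(
        (30, 50, 30), (30, 50, 530), 20.0, 20.0, (30, 50, 280), (2.0, 2.0, 2.0)
    )
    return {
        "tree": tree,
        "grid": grid,
        "volume": volume,
        "lumen": lumen,
        "labels": labels,
        "length": 500.0,
        "radius": 20.0,
    }


@pytest.fixture(scope="session")
def elliptical_tube():
    """Tube with the lateral/transversal half-axes 22/15 μm (44/30 diameters)."""
    tree, grid, volume, lumen, labels = make_tube(
        (30, 50, 30), (30, 50, 530), 22.0, 15.0, (30, 50, 280), (2.0, 2.0, 2.0)
    )
    return {"lumen": lumen, "a": 22.0, "b": 15.0}


@pytest.fixture(scope="session")
def y_junction():
    """Symmetric Y: three arms meeting at one junction, 90° between daughters."""
    c = np.array([40.0, 150.0, 80.0])
    dirs = [
        np.array([0.0, 0.0, -1.0]),
        np.array([0.0, np.sin(np.pi / 4), np.cos(np.pi / 4)]),
        np.array([0.0, -np.sin(np.pi / 4), np.cos(np.pi / 4)]),
    ]
    arm_lengths = [70.0, 180.0, 180.0]
    nodes = [c]
    segs = []
    for i, (d, length) in enumerate(zip(dirs, arm_lengths)):
        end = c + length * d
        nodes.append(end)
        segs.append(Segment(0, i + 1, np.vstack([c, end]), 15.0, 15.0))
    tree = VesselTree(nodes=nodes, segments=segs, roots=[0])
    grid = VoxelGrid((40, 150, 150), (2.0, 2.0, 2.0))
    _, lumen, labels = rasterize(tree, grid)
    return {"tree": tree, "grid": grid, "lumen": lumen, "daughter_angle": 90.0}


@pytest.fixture(scope="session")
def branched_tree_scene():
    """Small root-connected branched tree for perfusion rendering."""
    root = np.array([40.0, 100.0, 10.0])
    j = np.array([40.0, 100.0, 60.0])
    b1 = np.array([40.0, 40.0, 160.0])
    b2 = np.array([40.0, 160.0, 160.0])
    tree = VesselTree(
        nodes=[root, j, b1, b2],
        segments=[
            Segment(0, 1, np.vstack([root, j]), 15.0, 15.0),
            Segment(1, 2, np.vstack([j, b1]), 15.0, 15.0),
            Segment(1, 3, np.vstack([j, b2]), 15.0, 15.0),
        ],
        roots=[0],
    )
    grid = VoxelGrid((40, 100, 100), (2.0, 2.0, 2.0))
    volume, lumen, labels = rasterize(tree, grid)
    return {"tree": tree, "grid": grid, "volume": volume, "lumen": lumen, "labels": labels}


@pytest.fixture(scope="session")
def two_branch_tree():
    """Two equal branches from one root node (for half-perfusion tests)."""
    j = np.array([40.0, 100.0, 60.0])
    b1 = np.array([40.0, 40.0, 160.0])
    b2 = np.array([40.0, 160.0, 160.0])
    tree = VesselTree(
        nodes=[j, b1, b2],
        segments=[
            Segment(0, 1, np.vstack([j, b1]), 15.0, 15.0),
            Segment(0, 2, np.vstack([j, b2]), 15.0, 15.0),
        ],
        roots=[0],
    )
    grid = VoxelGrid((40, 100, 100), (2.0, 2.0, 2.0))
    _, lumen, labels = rasterize(tree, grid)
    return {"tree": tree, "grid": grid, "lumen": lumen, "labels": labels}


@pytest.fixture(scope="session")
def speckle_pair_grid():
    """Isotropic speckle volume for displacement-recovery fixtures."""
    grid = VoxelGrid((64, 64, 64), (2.0, 2.0, 2.0))
    pre = speckle_volume(grid, seed=1)
    return grid, pre


@pytest.fixture()
def uniform_volume():
    grid = VoxelGrid((4, 8, 8), (10.0, 1.24, 1.24))
    return ImageVolume(grid=grid, channels={"dextran": np.full(grid.shape, 0.5)})
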