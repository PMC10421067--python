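"""Ground-truth generators for testing every analysis stage without real data.

The module emulates the measured modalities of a microfluidic vascular
morphogenesis experiment:

* stochastic branching vessel trees inside a tissue slab, with sampled
  segment lengths, bifurcation angles, elliptical lumen cross sections
  (lateral axis in-plane, transversal axis along z) and smooth tortuosity;
* rasterized two-channel image stacks plus a forward perfusion model in
  which a tracer fills the root-connected lumens at t1 and leaks into the
  interstitium by t2 at a prescribed permeability;
* spherical-indenter force-distance curves following Hertz contact;
* smoothly warped speckle volumes for displacement-recovery fixtures.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core_io import BinaryMask, ImageVolume, VoxelGrid

logger = logging.getLogger("vascmorph")

# default imaging geometry: 21 slices at 10-um z-step over a
# 1.27 mm x 1.27 mm field of view at 1.24 um in-plane pitch
DEFAULT_SLAB_UM = (210.0, 1270.0, 1270.0)
DEFAULT_SPACING_UM = (10.0, 1.24, 1.24)


# ---------------------------------------------------------------------------
# vessel trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """One vessel segment between two tree nodes.

    ``polyline`` is an (N, 3) array of (z, y, x) centre points in μm;
    ``radius_lateral`` / ``radius_transversal`` are the in-plane and
    z-axis semi-axes of the elliptical lumen cross section.
    """

    parent_node: int
    child_node: int
    polyline: np.ndarray
    radius_lateral: float
    radius_transversal: float

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.polyline, axis=0), axis=1).sum())


@dataclass
class VesselTree:
    """A forest of vessel segments grown from root nodes."""

    nodes: list[np.ndarray]
    segments: list[Segment]
    roots: list[int]

    def children(self) -> dict[int, list[int]]:
        """Map node index -> indices of segments leaving that node."""
        out: dict[int, list[int]] = {}
        for i, seg in enumerate(self.segments):
            out.setdefault(seg.parent_node, []).append(i)
        return out

    def root_connected_segments(self, roots: Sequence[int] | None = None) -> list[int]:
        """Segment indices reachable from the given (default: all) roots."""
        roots = list(self.roots if roots is None else roots)
        child_map = self.children()
        seen: list[int] = []
        stack = list(roots)
        visited_nodes = set()
        while stack:
            node = stack.pop()
            if node in visited_nodes:
                continue
            visited_nodes.add(node)
            for seg_idx in child_map.get(node, []):
                seen.append(seg_idx)
                stack.append(self.segments[seg_idx].child_node)
        return sorted(seen)

    def total_length(self) -> float:
        return sum(seg.length for seg in self.segments)


@dataclass(frozen=True)
class TreeParams:
    """Growth parameters for the stochastic vessel-tree generator.

    Defaults mirror the day-7 morphology of the microvascular networks
    the generator emulates: mean segment length 90 μm within a 50–900 μm
    range, lumen diameters within 5–150 μm averaging 44 μm laterally,
    transversal-to-lateral anisotropy 30/44, and a ~70° bifurcation
    opening angle.
    """

    slab_um: tuple[float, float, float] = DEFAULT_SLAB_UM
    mean_segment_length_um: float = 90.0
    segment_length_range_um: tuple[float, float] = (50.0, 900.0)
    branching_prob: float = 0.35
    branch_angle_deg: tuple[float, float] = (70.0, 10.0)
    diameter_range_um: tuple[float, float] = (5.0, 150.0)
    mean_lateral_diameter_um: float = 44.0
    diameter_sigma: float = 0.35  # lognormal shape parameter
    tortuosity_amplitude_um: float = 6.0
    anisotropy: float = 30.0 / 44.0
    #: vertical damping of the bifurcation plane (1 = isotropic branching);
    #: thin slabs favour in-plane branching
    branch_plane_z_damping: float = 0.25
    n_roots: int = 3
    max_segments: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.segment_length_range_um
        if not (0 < lo < hi):
            raise ValueError("segment length range must be ordered and positive")
        lo, hi = self.diameter_range_um
        if not (0 < lo < hi):
            raise ValueError("diameter range must be ordered and positive")
        if not 0.0 <= self.branching_prob <= 1.0:
            raise ValueError("branching probability must lie in [0, 1]")


def _sample_length(params: TreeParams, rng: np.random.Generator) -> float:
    """Shifted-exponential segment length: mean at the stated 90 μm."""
    lo, hi = params.segment_length_range_um
    scale = params.mean_segment_length_um - lo
    for _ in range(1000):
        val = lo + rng.exponential(scale)
        if val <= hi:
            return float(val)
    return float(hi)


def _sample_diameter(params: TreeParams, rng: np.random.Generator) -> float:
    lo, hi = params.diameter_range_um
    sigma = params.diameter_sigma
    mu = np.log(params.mean_lateral_diameter_um) - 0.5 * sigma**2
    for _ in range(1000):
        val = rng.lognormal(mu, sigma)
        if lo <= val <= hi:
            return float(val)
    return float(np.clip(params.mean_lateral_diameter_um, lo, hi))


def _perpendicular(direction: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random unit vector perpendicular to ``direction``."""
    while True:
        v = rng.normal(size=3)
        v -= v @ direction * direction
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            return v / norm


def _rotate_towards(direction: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotate ``direction`` by ``angle`` (rad) towards the perpendicular ``axis``."""
    out = np.cos(angle) * direction + np.sin(angle) * axis
    return out / np.linalg.norm(out)


def _segment_polyline(
    start: np.ndarray,
    end: np.ndarray,
    amplitude: float,
    rng: np.random.Generator,
    step_um: float = 10.0,
) -> np.ndarray:
    """Centre line with a smooth tortuosity bow.

    The perturbation is ``A sin²(πs/L)`` along a random normal, which
    keeps both endpoints and both end tangents fixed, so junction angles
    are unaffected by tortuosity.
    """
    chord = end - start
    length = np.linalg.norm(chord)
    n_pts = max(int(np.ceil(length / step_um)) + 1, 5)
    s = np.linspace(0.0, 1.0, n_pts)
    line = start[None] + s[:, None] * chord[None]
    if amplitude > 0 and length > 0:
        normal = _perpendicular(chord / length, rng)
        line = line + (amplitude * np.sin(np.pi * s) ** 2)[:, None] * normal[None]
    return line


def generate_tree(params: TreeParams) -> VesselTree:
    """Grow a stochastic branching vessel forest inside the slab.

    Roots sit on the x = 0 face (the upstream side of the device) and
    tips extend segment by segment; each completed segment bifurcates
    with ``branching_prob`` at an opening angle drawn from the branch
    angle distribution, otherwise continues with a gently jittered
    heading.  Tips die when they would leave the slab.  Identical seed
    gives an identical tree.
    """
    slab = np.asarray(params.slab_um, dtype=float)
    if np.any(slab < params.segment_length_range_um[0]):
        raise ValueError(
            f"slab {tuple(slab)} μm too small to host one minimum-length segment"
        )
    rng = np.random.default_rng(params.seed)
    margin = 0.02 * slab

    nodes: list[np.ndarray] = []
    segments: list[Segment] = []
    roots: list[int] = []
    tips: list[tuple[int, np.ndarray]] = []  # (node index, direction)

    for r in range(params.n_roots):
        pos = np.array(
            [
                rng.uniform(0.25, 0.75) * slab[0],
                (r + 0.5) / params.n_roots * slab[1],
                0.0,
            ]
        )
        direction = np.array([0.0, 0.0, 1.0])  # grow along +x
        direction = _rotate_towards(direction, _perpendicular(direction, rng),
                                    rng.normal(0.0, np.radians(8.0)))
        nodes.append(pos)
        roots.append(len(nodes) - 1)
        tips.append((len(nodes) - 1, direction))

    while tips and len(segments) < params.max_segments:
        node_idx, direction = tips.pop(0)
        start = nodes[node_idx]
        # keep the segment inside the slab: reflect the heading at the
        # faces (preserves the sampled length), fall back to re-sampling
        # a shorter length, else kill the tip
        length = _sample_length(params, rng)
        end = None
        candidate = start + length * direction
        for _ in range(4):
            out_lo = candidate < margin
            out_hi = candidate > slab - margin
            if not (out_lo.any() or out_hi.any()):
                end = candidate
                break
            direction = direction.copy()
            direction[out_lo | out_hi] *= -1.0
            candidate = start + length * direction
        if end is None:
            for _ in range(8):
                length = _sample_length(params, rng)
                candidate = start + length * direction
                if np.all(candidate > margin) and np.all(candidate < slab - margin):
                    end = candidate
                    break
            else:
                continue
        poly = _segment_polyline(start, end, params.tortuosity_amplitude_um, rng)
        poly = np.clip(poly, 0.0, slab[None])
        diameter = _sample_diameter(params, rng)
        a = diameter / 2.0
        nodes.append(end)
        child_idx = len(nodes) - 1
        segments.append(
            Segment(
                parent_node=node_idx,
                child_node=child_idx,
                polyline=poly,
                radius_lateral=a,
                radius_transversal=a * params.anisotropy,
            )
        )
        if rng.uniform() < params.branching_prob:
            mean_deg, sd_deg = params.branch_angle_deg
            opening = np.radians(rng.normal(mean_deg, sd_deg))
            # choose a bifurcation plane that keeps both daughters in the
            # slab, so the sampled opening angle is actually realized
            # (vessel beds in a thin slab branch preferentially in-plane)
            probe = params.mean_segment_length_um
            for _ in range(30):
                axis = _perpendicular(direction, rng)
                # thin-slab beds branch quasi-in-plane: damp the vertical
                # component of the bifurcation plane
                axis[0] *= params.branch_plane_z_damping
                axis -= (axis @ direction) * direction
                norm = np.linalg.norm(axis)
                if norm < 1e-8:
                    continue
                axis /= norm
                d1 = _rotate_towards(direction, axis, opening / 2.0)
                d2 = _rotate_towards(direction, -axis, opening / 2.0)
                ok = all(
                    np.all(end + probe * d > margin)
                    and np.all(end + probe * d < slab - margin)
                    for d in (d1, d2)
                )
                if ok:
                    break
            tips.append((child_idx, d1))
            tips.append((child_idx, d2))
        else:
            jitter = rng.normal(0.0, np.radians(5.0))
            axis = _perpendicular(direction, rng)
            tips.append((child_idx, _rotate_towards(direction, axis, jitter)))

    return VesselTree(nodes=nodes, segments=segments, roots=roots)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def rasterize(
    tree: VesselTree,
    grid: VoxelGrid,
    foreground: float = 1000.0,
) -> tuple[ImageVolume, BinaryMask, np.ndarray]:
    """Voxelize a tree into an endothelial channel, lumen mask and labels.

    A voxel belongs to the lumen iff it lies inside the elliptical tube of
    some segment: offsets from the local centre line (perpendicular to the
    tangent) satisfy ``(d_xy/a)² + (d_z/b)² <= 1`` with the lateral
    semi-axis ``a`` in-plane and the transversal semi-axis ``b`` along z.
    Segment ends are rounded (ellipsoidal caps).  Returns the intensity
    volume (channel ``ec``), the lumen mask, and an int32 label array with
    the 1-based segment index per lumen voxel.
    """
    if not tree.segments:
        raise ValueError("cannot rasterize an empty tree")
    spacing = np.asarray(grid.spacing)
    min_radius = min(
        min(s.radius_lateral, s.radius_transversal) for s in tree.segments
    )
    if np.max(spacing) > min_radius:
        logger.warning(
            "voxel spacing %s μm exceeds the smallest segment radius %.2f μm; "
            "thin vessels will rasterize poorly",
            tuple(spacing),
            min_radius,
        )
    origin = np.asarray(grid.origin)
    shape = np.asarray(grid.shape)
    labels = np.zeros(grid.shape, dtype=np.int32)

    for seg_idx, seg in enumerate(tree.segments, start=1):
        a, b = seg.radius_lateral, seg.radius_transversal
        pad = np.array([b, a, a]) + spacing
        lo_idx = np.maximum(
            np.floor((seg.polyline.min(axis=0) - pad - origin) / spacing), 0
        ).astype(int)
        hi_idx = np.minimum(
            np.ceil((seg.polyline.max(axis=0) + pad - origin) / spacing) + 1, shape
        ).astype(int)
        if np.any(hi_idx <= lo_idx):
            continue
        zz, yy, xx = np.meshgrid(
            *(np.arange(lo, hi) for lo, hi in zip(lo_idx, hi_idx)), indexing="ij"
        )
        pts = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3) * spacing + origin
        p0 = seg.polyline[:-1]
        p1 = seg.polyline[1:]
        w = p1 - p0
        wlen2 = np.einsum("ij,ij->i", w, w)
        wlen2[wlen2 == 0] = 1e-12
        inside = np.zeros(len(pts), dtype=bool)
        for j in range(len(p0)):
            v = pts - p0[j]
            t = np.clip((v @ w[j]) / wlen2[j], 0.0, 1.0)
            # offset from the nearest centre-line point: perpendicular in
            # the interior, radial at the clamped ends (rounded caps)
            d = v - t[:, None] * w[j]
            inside |= (d[:, 1] ** 2 + d[:, 2] ** 2) / a**2 + d[:, 0] ** 2 / b**2 <= 1.0
        box = labels[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]]
        box_flat = box.reshape(-1)
        box_flat[inside] = seg_idx
        box[...] = box_flat.reshape(box.shape)

    lumen = labels > 0
    if not lumen.any():
        raise ValueError("tree has zero rasterized extent on this grid")
    ec = np.where(lumen, float(foreground), 0.0)
    volume = ImageVolume(grid=grid, channels={"ec": ec})
    return volume, BinaryMask(grid=grid, voxels=lumen), labels


# ---------------------------------------------------------------------------
# perfusion forward model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerfusionParams:
    """Forward-model parameters for the two-timepoint tracer assay."""

    perfused_fraction: float = 1.0
    lumen_intensity: float = 1000.0
    baseline_intensity: float = 5.0
    permeability_cm_s: float = 2e-7
    t1_s: float = 0.0
    t2_s: float = 1200.0  # imaged again after 20 min
    noise_sd: float = 0.0
    halo_decay_um: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t2_s <= self.t1_s:
            raise ValueError("t2 must exceed t1")
        if self.permeability_cm_s < 0:
            raise ValueError("permeability must be non-negative")
        if not 0.0 <= self.perfused_fraction <= 1.0:
            raise ValueError("perfused fraction must lie in [0, 1]")


def perfused_surface_area_um2(mask: np.ndarray, spacing) -> float:
    """Surface area of a voxel mask via a marching-cubes mesh, in μm²."""
    from skimage.measure import marching_cubes, mesh_surface_area

    padded = np.pad(mask.astype(np.float32), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    return float(mesh_surface_area(verts, faces))


def _select_perfused_segments(
    tree: VesselTree, labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> list[int]:
    """Root-connected segments, trimmed subtree-by-subtree to the target
    perfused volume fraction."""
    connected = tree.root_connected_segments()
    if fraction >= 1.0:
        return connected
    counts = {i: int((labels == i + 1).sum()) for i in connected}
    total = sum(counts.values())
    child_map = tree.children()

    def subtree(seg_idx: int) -> list[int]:
        out, stack = [], [seg_idx]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(child_map.get(tree.segments[i].child_node, []))
        return out

    top = [i for i in connected if tree.segments[i].parent_node in tree.roots]
    order = list(rng.permutation(len(top)))
    chosen: list[int] = []
    vol = 0
    for k in order:
        branch = subtree(top[k])
        branch_vol = sum(counts.get(i, 0) for i in branch)
        if vol + branch_vol <= fraction * total + 0.5 * branch_vol:
            chosen.extend(branch)
            vol += branch_vol
        if vol >= fraction * total:
            break
    return sorted(chosen)


def render_perfusion(
    tree: VesselTree,
    grid: VoxelGrid,
    lumen: BinaryMask,
    labels: np.ndarray,
    params: PerfusionParams,
) -> tuple[ImageVolume, ImageVolume]:
    """Render tracer volumes at t1 and t2 for the two-timepoint leak assay.

    At t1 the tracer fills the perfused (root-connected) lumens at
    ``lumen_intensity`` over a small interstitial baseline.  By t2 the
    interstitial mean has risen by exactly

        ΔI = P · Δt · (S / V_int) · (I_v − I_i(t1)),

    with S the perfused-lumen surface area and V_int the interstitial
    volume, both computed from the rasterization.  The leaked intensity is
    deposited as a smooth exponential halo (decay ``halo_decay_um``)
    around the perfused vessels and rescaled so the interstitial mean
    matches the closed form to machine precision; noise is added last.
    """
    rng = np.random.default_rng(params.seed)
    perfused_ids = _select_perfused_segments(tree, labels, params.perfused_fraction, rng)
    if params.perfused_fraction > 0 and not perfused_ids:
        raise ValueError("perfused fraction > 0 but no lumen is connected to a root")
    perfused = np.isin(labels, [i + 1 for i in perfused_ids])
    interstitial = ~lumen.voxels

    t1 = np.full(grid.shape, params.baseline_intensity, dtype=np.float64)
    t1[perfused] = params.lumen_intensity
    t2 = t1.copy()

    if params.permeability_cm_s > 0 and perfused.any():
        s_cm2 = perfused_surface_area_um2(perfused, grid.spacing) * 1e-8
        v_int_cm3 = interstitial.sum() * grid.voxel_volume * 1e-12
        delta_i = (
            params.permeability_cm_s
            * (params.t2_s - params.t1_s)
            * (s_cm2 / v_int_cm3)
            * (params.lumen_intensity - params.baseline_intensity)
        )
        dist = ndimage.distance_transform_edt(~perfused, sampling=grid.spacing)
        weight = np.exp(-dist / params.halo_decay_um) * interstitial
        weight_sum = weight.sum()
        if weight_sum > 0:
            t2 += delta_i * interstitial.sum() / weight_sum * weight

    if params.noise_sd > 0:
        t1 = t1 + rng.normal(0.0, params.noise_sd, size=t1.shape)
        t2 = t2 + rng.normal(0.0, params.noise_sd, size=t2.shape)

    return (
        ImageVolume(grid=grid, channels={"dextran": t1}),
        ImageVolume(grid=grid, channels={"dextran": t2}),
    )


# ---------------------------------------------------------------------------
# AFM force curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CurveParams:
    """Parameters of a synthetic spherical-indenter approach curve."""

    apparent_modulus_pa: float = 900.0  # E / (1 - nu^2)
    probe_radius_um: float = 25.0  # 50-μm glass microsphere
    contact_offset_um: float = 2.0
    max_force_nn: float = 30.0  # instrument set force
    step_nm: float = 10.0
    noise_sd_nn: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.apparent_modulus_pa <= 0 or self.probe_radius_um <= 0:
            raise ValueError("modulus and probe radius must be positive")


def synth_force_curve(params: CurveParams):
    """Generate one approach force-distance curve following Hertz contact.

    The curve is flat (zero force) until the contact offset, then follows
    F = (4/3)·E_app·√R·δ^{3/2} until the set force is reached; Gaussian
    force noise of the stated sd is added last.
    """
    from .mechanics import ForceCurve, hertz_force

    e, r = params.apparent_modulus_pa, params.probe_radius_um
    # indentation at which the set force is reached
    delta_end_m = (
        3.0 * params.max_force_nn * 1e-9 / (4.0 * e * np.sqrt(r * 1e-6))
    ) ** (2.0 / 3.0)
    delta_end_um = delta_end_m * 1e6
    step_um = params.step_nm * 1e-3
    if step_um >= delta_end_um:
        raise ValueError(
            f"sampling step {step_um} μm is larger than the {delta_end_um:.3f} μm "
            "contact region"
        )
    span = params.contact_offset_um + delta_end_um
    n = int(np.floor(span / step_um)) + 1  # last sample stays at/below set force
    extension = np.arange(n) * step_um
    delta = np.clip(extension - params.contact_offset_um, 0.0, None)
    force = hertz_force(delta, e, r)
    if params.noise_sd_nn > 0:
        rng = np.random.default_rng(params.seed)
        force = force + rng.normal(0.0, params.noise_sd_nn, size=force.shape)
    return ForceCurve(
        extension_um=extension,
        force_nn=force,
        probe_radius_um=r,
        metadata={"true_modulus_pa": e, "true_contact_um": params.contact_offset_um},
    )


# ---------------------------------------------------------------------------
# speckle volumes and warping
# ---------------------------------------------------------------------------


def speckle_volume(
    grid: VoxelGrid, seed: int = 0, smoothing_vox: float = 1.5, mean: float = 100.0
) -> ImageVolume:
    """Random smooth speckle pattern emulating a fluorescently labeled gel."""
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=grid.shape)
    matrix = ndimage.gaussian_filter(noise, smoothing_vox)
    matrix = mean * (1.0 + matrix / np.abs(matrix).max())
    return ImageVolume(grid=grid, channels={"matrix": matrix})


def radial_field(
    grid: VoxelGrid,
    center_um: Sequence[float],
    max_displacement_um: float = 6.0,
    decay_um: float = 40.0,
) -> np.ndarray:
    """Smooth inward radial displacement field (3, nz, ny, nx) in μm.

    Emulates matrix relaxation toward a contractile structure: magnitude
    peaks at ``max_displacement_um`` near the centre and decays smoothly
    with distance.
    """
    idx = np.indices(grid.shape, dtype=float)
    coords = idx * np.asarray(grid.spacing)[:, None, None, None]
    rel = coords - np.asarray(center_um, dtype=float)[:, None, None, None]
    dist = np.sqrt((rel**2).sum(axis=0))
    mag = max_displacement_um * (dist / decay_um) * np.exp(1.0 - dist / decay_um)
    mag = np.minimum(mag, max_displacement_um)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(dist > 0, rel / dist, 0.0)
    return -mag * unit


def warp(volume: ImageVolume, displacement) -> ImageVolume:
    """Resample each channel at ``x − u(x)`` by trilinear interpolation.

    ``displacement`` is either a (3, nz, ny, nx) array of μm vectors on
    the volume grid, or a :class:`~vascmorph.dvc_strain.DisplacementField`
    (interpolated to the volume grid first).  A zero field is the
    identity.
    """
    grid = volume.grid
    u = _field_on_grid(displacement, grid)
    u_vox = u / np.asarray(grid.spacing)[:, None, None, None]
    idx = np.indices(grid.shape, dtype=float)
    sample_at = idx - u_vox
    channels = {
        name: ndimage.map_coordinates(arr, sample_at, order=1, mode="nearest")
        for name, arr in volume.channels.items()
    }
    return ImageVolume(grid=grid, channels=channels)


def _field_on_grid(displacement, grid: VoxelGrid) -> np.ndarray:
    if isinstance(displacement, np.ndarray):
        if displacement.shape != (3,) + grid.shape:
            raise ValueError(
                f"displacement array shape {displacement.shape} does not match "
                f"(3,) + grid shape {grid.shape}"
            )
        return displacement
    # DisplacementField on a coarse grid: interpolate each component
    from scipy.interpolate import RegularGridInterpolator

    fgrid = displacement.grid
    axes = [
        fgrid.origin[d] + np.arange(fgrid.shape[d]) * fgrid.spacing[d] for d in range(3)
    ]
    targets = [
        grid.origin[d] + np.arange(grid.shape[d]) * grid.spacing[d] for d in range(3)
    ]
    for d in range(3):
        if targets[d][-1] < axes[d][0] or targets[d][0] > axes[d][-1]:
            raise ValueError("displacement-field grid is disjoint from the volume grid")
    pts = np.stack(np.meshgrid(*targets, indexing="ij"), axis=-1)
    out = np.empty((3,) + grid.shape)
    for c in range(3):
        interp = RegularGridInterpolator(
            axes, displacement.u[c], bounds_error=False, fill_value=None
        )
        out[c] = interp(pts)
    return out


# ---------------------------------------------------------------------------
# complete synthetic scenes
# ---------------------------------------------------------------------------


@dataclass
class Scene:
    """One synthetic imaging region with all modalities and ground truth."""

    tree: VesselTree
    volume: ImageVolume  # channel "ec"
    lumen_mask: BinaryMask
    labels: np.ndarray
    dextran_t1: ImageVolume
    dextran_t2: ImageVolume
    speckle_pre: ImageVolume
    speckle_post: ImageVolume
    truth: dict = field(default_factory=dict)


SCENARIOS: dict[str, dict] = {
    # a down-scaled imaging region that keeps the day-7 morphology
    # (diameter distribution, anisotropy, branching) on a tractable grid
    "default-day7": {
        "slab_um": (120.0, 400.0, 400.0),
        "spacing_um": (8.0, 2.0, 2.0),
        "tree": {"n_roots": 2, "max_segments": 14, "branching_prob": 0.4,
                 "mean_lateral_diameter_um": 44.0, "diameter_range_um": (20.0, 100.0),
                 "mean_segment_length_um": 90.0, "segment_length_range_um": (50.0, 300.0),
                 "tortuosity_amplitude_um": 4.0},
        "perfusion": {"permeability_cm_s": 2e-7, "noise_sd": 5.0},
        "speckle_shape": (48, 48, 48),
        "speckle_spacing": (2.0, 2.0, 2.0),
        "max_displacement_um": 6.5,
    },
    "default-day4": {
        "slab_um": (120.0, 400.0, 400.0),
        "spacing_um": (8.0, 2.0, 2.0),
        "tree": {"n_roots": 2, "max_segments": 10, "branching_prob": 0.25,
                 "mean_lateral_diameter_um": 36.0, "diameter_range_um": (16.0, 90.0),
                 "mean_segment_length_um": 90.0, "segment_length_range_um": (50.0, 300.0),
                 "tortuosity_amplitude_um": 4.0},
        "perfusion": {"permeability_cm_s": 4e-7, "noise_sd": 5.0, "perfused_fraction": 0.8},
        "speckle_shape": (48, 48, 48),
        "speckle_spacing": (2.0, 2.0, 2.0),
        "max_displacement_um": 3.0,
    },
}


def simulate_scene(scenario: str | dict, seed: int = 0) -> Scene:
    """Build a full synthetic imaging region for one scenario.

    The scene contains the ground-truth tree, the rasterized endothelial
    stack, tracer volumes at both timepoints, and a pre/post speckle pair
    warped by a smooth radial relaxation field.
    """
    cfg = SCENARIOS[scenario] if isinstance(scenario, str) else dict(scenario)
    spacing = tuple(cfg["spacing_um"])
    slab = tuple(cfg["slab_um"])
    shape = tuple(int(round(s / p)) for s, p in zip(slab, spacing))
    grid = VoxelGrid(shape=shape, spacing=spacing)

    tree_params = TreeParams(slab_um=slab, seed=seed, **cfg.get("tree", {}))
    tree = generate_tree(tree_params)
    volume, lumen, labels = rasterize(tree, grid)

    perf_params = PerfusionParams(seed=seed + 1, **cfg.get("perfusion", {}))
    t1, t2 = render_perfusion(tree, grid, lumen, labels, perf_params)

    sgrid = VoxelGrid(shape=cfg["speckle_shape"], spacing=cfg["speckle_spacing"])
    pre = speckle_volume(sgrid, seed=seed + 2)
    center = 0.5 * np.asarray(sgrid.extent)
    field_true = radial_field(sgrid, center, cfg["max_displacement_um"])
    post = warp(pre, field_true)

    truth = {
        "tree_total_length_um": tree.total_length(),
        "lumen_volume_fraction_pct": 100.0 * lumen.voxels.mean(),
        "permeability_cm_s": perf_params.permeability_cm_s,
        "max_displacement_um": float(np.linalg.norm(field_true, axis=0).max()),
        "displacement_field": field_true,
    }
    return Scene(
        tree=tree,
        volume=volume,
        lumen_mask=lumen,
        labels=labels,
        dextran_t1=t1,
        dextran_t2=t2,
        speckle_pre=pre,
        speckle_post=post,
        truth=truth,
    )
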