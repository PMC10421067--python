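"""Functional metrics of a tracer-perfused vascular network.

Three metrics characterize vessel function in the dextran assay:

* perfusability — the percentage of the vascular volume reachable by a
  luminally introduced tracer, scored cross section by cross section;
* permeability — the two-timepoint rate constant P (cm/s) for tracer
  flux across the vessel wall,

      P = [ΔĪ_i / Δt] · [1 / (Ī_v(t1) − Ī_i(t1))] · (V_int / S),

  with Ī_v / Ī_i the mean vascular / interstitial tracer intensities,
  S the perfused-lumen surface area and V_int the interstitial volume;
* barrier function — the inverse mean interstitial tracer intensity
  (higher = tighter vessels).

The assay's hydrostatic driving pressure from the port head difference
is also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as _label

from .core_io import BinaryMask, ImageVolume, VoxelGrid
from .synthsim import perfused_surface_area_um2

logger = logging.getLogger("vascmorph")

WATER_DENSITY_KG_M3 = 1000.0
GRAVITY_M_S2 = 9.81


@dataclass(frozen=True)
class PerfusionMetrics:
    """Bundle of the three functional metrics with their raw inputs."""

    perfusability_pct: float
    permeability_cm_s: float
    barrier_function_inv_au: float
    i_vascular_t1: float
    i_interstitial_t1: float
    i_interstitial_t2: float
    dt_s: float
    surface_area_cm2: float
    interstitial_volume_cm3: float


def _dextran_array(dextran: ImageVolume | np.ndarray) -> np.ndarray:
    if isinstance(dextran, ImageVolume):
        return dextran.channel("dextran")
    return np.asarray(dextran, dtype=float)


def _dextran_threshold(data: np.ndarray) -> float:
    """Otsu threshold on the tracer volume; a constant volume means no
    tracer contrast anywhere, so the threshold is set above the data."""
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        return np.inf
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(data, nbins=256))


def perfused_vessel_mask(
    ec_mask: BinaryMask,
    dextran: ImageVolume | np.ndarray,
    dextran_threshold: float | None = None,
) -> BinaryMask:
    """Vessel voxels belonging to tracer-containing cross sections.

    The stack is resliced into x-z cross sections (one per y position);
    within each cross section every connected vessel component that
    contains at least one suprathreshold tracer voxel is scored perfused
    in full.
    """
    data = _dextran_array(dextran)
    if data.shape != ec_mask.voxels.shape:
        raise ValueError("dextran volume and EC mask must share a grid")
    if dextran_threshold is None:
        dextran_threshold = _dextran_threshold(data)
    perfused = np.zeros_like(ec_mask.voxels)
    for y in range(ec_mask.voxels.shape[1]):
        section = ec_mask.voxels[:, y, :]
        if not section.any():
            continue
        labels = _label(section, connectivity=2)
        hot = np.unique(labels[(data[:, y, :] >= dextran_threshold) & (labels > 0)])
        if hot.size:
            perfused[:, y, :] = np.isin(labels, hot)
    return BinaryMask(grid=ec_mask.grid, voxels=perfused)


def perfusability(
    ec_mask: BinaryMask,
    dextran: ImageVolume | np.ndarray,
    dextran_threshold: float | None = None,
) -> float:
    """Percentage of the vascular volume that is perfused by the tracer."""
    if not ec_mask.voxels.any():
        raise ValueError("empty vascular mask")
    perfused = perfused_vessel_mask(ec_mask, dextran, dextran_threshold)
    return 100.0 * float(perfused.voxels.sum()) / float(ec_mask.voxels.sum())


def interstitial_mask(ec_mask: BinaryMask, dilation_vox: int = 1) -> np.ndarray:
    """Interstitial region: complement of the EC mask dilated by
    ``dilation_vox`` voxels (avoids vessel-wall bleed-through)."""
    if dilation_vox > 0:
        dilated = ndimage.binary_dilation(ec_mask.voxels, iterations=dilation_vox)
    else:
        dilated = ec_mask.voxels
    return ~dilated


def barrier_function(
    dextran: ImageVolume | np.ndarray,
    ec_mask: BinaryMask,
    dilation_vox: int = 1,
) -> float:
    """Inverse mean interstitial tracer intensity of the z-projected stack.

    The stack is mean-projected along z and the EC mask projected and
    dilated by ``dilation_vox`` pixels to define the interstitial plane
    region.  A zero interstitial mean is reported as infinity.
    """
    data = _dextran_array(dextran)
    proj = data.mean(axis=0)
    ec_proj = ec_mask.voxels.any(axis=0)
    if dilation_vox > 0:
        ec_proj = ndimage.binary_dilation(ec_proj, iterations=dilation_vox)
    interstitial = ~ec_proj
    if not interstitial.any():
        raise ValueError("interstitial region is empty after dilation")
    mean_i = float(proj[interstitial].mean())
    if mean_i == 0:
        logger.warning("zero interstitial intensity; barrier function is infinite")
        return float("inf")
    return 1.0 / mean_i


def permeability(
    dextran_t1: ImageVolume | np.ndarray,
    dextran_t2: ImageVolume | np.ndarray,
    ec_mask: BinaryMask,
    dt: float = 1200.0,
    dextran_threshold: float | None = None,
    dilation_vox: int = 1,
    projected: bool = False,
    surface_to_volume_per_cm: float | None = None,
) -> float:
    """Two-timepoint permeability coefficient P in cm/s.

    Interstitial means are volumetric by default (``projected=True``
    averages the z-projection instead).  ``surface_to_volume_per_cm``
    overrides the measured S/V_int ratio, e.g. with the single-vessel
    4/d convention.  Raises when the vasculature shows no tracer
    contrast over the interstitium.
    """
    t1 = _dextran_array(dextran_t1)
    t2 = _dextran_array(dextran_t2)
    if t1.shape != t2.shape or t1.shape != ec_mask.voxels.shape:
        raise ValueError("both tracer volumes and the EC mask must share a grid")
    if dt <= 0:
        raise ValueError("Δt must be positive")

    perfused = perfused_vessel_mask(ec_mask, t1, dextran_threshold)
    if not perfused.voxels.any():
        raise ValueError("no perfused vessels detected at t1")
    interstitial = interstitial_mask(ec_mask, dilation_vox)
    if not interstitial.any():
        raise ValueError("interstitial region is empty")

    i_v1 = float(t1[perfused.voxels].mean())
    if projected:
        region2d = interstitial.all(axis=0)
        i_i1 = float(t1.mean(axis=0)[region2d].mean())
        i_i2 = float(t2.mean(axis=0)[region2d].mean())
    else:
        i_i1 = float(t1[interstitial].mean())
        i_i2 = float(t2[interstitial].mean())
    if i_v1 <= i_i1:
        raise ValueError(
            f"no vascular tracer contrast: Ī_v(t1)={i_v1:.3g} <= Ī_i(t1)={i_i1:.3g}"
        )

    if surface_to_volume_per_cm is None:
        grid = ec_mask.grid
        s_cm2 = perfused_surface_area_um2(perfused.voxels, grid.spacing) * 1e-8
        v_int_cm3 = float(interstitial.sum()) * grid.voxel_volume * 1e-12
        v_over_s = v_int_cm3 / s_cm2
    else:
        v_over_s = 1.0 / surface_to_volume_per_cm
    return ((i_i2 - i_i1) / dt) * (1.0 / (i_v1 - i_i1)) * v_over_s


def perfusion_metrics(
    dextran_t1: ImageVolume,
    dextran_t2: ImageVolume,
    ec_mask: BinaryMask,
    dt: float = 1200.0,
    dextran_threshold: float | None = None,
) -> PerfusionMetrics:
    """All three functional metrics plus their recorded inputs."""
    t1 = _dextran_array(dextran_t1)
    t2 = _dextran_array(dextran_t2)
    perfused = perfused_vessel_mask(ec_mask, t1, dextran_threshold)
    interstitial = interstitial_mask(ec_mask)
    grid = ec_mask.grid
    s_cm2 = perfused_surface_area_um2(perfused.voxels, grid.spacing) * 1e-8
    v_int_cm3 = float(interstitial.sum()) * grid.voxel_volume * 1e-12
    return PerfusionMetrics(
        perfusability_pct=perfusability(ec_mask, t1, dextran_threshold),
        permeability_cm_s=permeability(t1, t2, ec_mask, dt, dextran_threshold),
        barrier_function_inv_au=barrier_function(t1, ec_mask),
        i_vascular_t1=float(t1[perfused.voxels].mean()) if perfused.voxels.any() else float("nan"),
        i_interstitial_t1=float(t1[interstitial].mean()),
        i_interstitial_t2=float(t2[interstitial].mean()),
        dt_s=float(dt),
        surface_area_cm2=s_cm2,
        interstitial_volume_cm3=v_int_cm3,
    )


def hydrostatic_pressure(h_upstream_mm: float, h_downstream_mm: float) -> float:
    """Hydrostatic driving pressure ΔP = ρ g Δh in Pa for water columns."""
    if h_upstream_mm < 0 or h_downstream_mm < 0:
        raise ValueError("column heights must be non-negative")
    dh_m = (h_upstream_mm - h_downstream_mm) * 1e-3
    return WATER_DENSITY_KG_M3 * GRAVITY_M_S2 * dh_m
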