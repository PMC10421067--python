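"""Voxel-grid data model, TIFF stack I/O, and the end-to-end pipeline driver.

Conventions used throughout the package:

* axis order is ``(z, y, x)``; the z axis is perpendicular to the glass
  substrate ("transversal" direction), x/y are in-plane ("lateral");
* all physical lengths are in micrometres, pressures in Pa, forces in nN,
  permeabilities in cm/s;
* image intensities are arbitrary units and are never rescaled on read.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("vascmorph")

CHANNEL_NAMES = ("ec", "dextran", "matrix")

#: registry of metric names that may appear in a MetricsReport
METRIC_REGISTRY = frozenset(
    {
        "longest_network_length_um",
        "total_network_length_um",
        "mean_lateral_diameter_um",
        "mean_transversal_diameter_um",
        "mean_hydraulic_diameter_um",
        "vessel_density_per_mm2",
        "vascular_volume_fraction_pct",
        "mean_branching_angle_deg",
        "mean_segment_length_um",
        "perfusability_pct",
        "permeability_cm_per_s",
        "barrier_function_inv_au",
        "hydrostatic_pressure_pa",
        "apparent_modulus_mean_pa",
        "apparent_modulus_median_pa",
        "apparent_modulus_sem_pa",
        "stiffness_fold_change",
        "contribution_base_fibrin_pct",
        "contribution_ecm_remodeling_pct",
        "contribution_cell_material_pct",
        "contribution_active_force_pct",
        "max_displacement_um",
        "mean_nonzero_displacement_um",
        "max_principal_strain",
        "near_vessel_mean_displacement_um",
        "far_field_mean_displacement_um",
    }
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3D voxel lattice with anisotropic physical spacing.

    Parameters
    ----------
    shape : tuple of int
        ``(nz, ny, nx)`` voxel counts, each >= 1.
    spacing : tuple of float
        ``(dz, dy, dx)`` voxel pitch in micrometres, each > 0.
    origin : tuple of float
        Physical position of voxel ``(0, 0, 0)`` in micrometres.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be three integers >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (z, y, x) of the grid in micrometres."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cubic micrometres."""
        return float(np.prod(self.spacing))

    def coords(self, indices: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (…, 3) to physical μm coordinates."""
        idx = np.asarray(indices, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)


@dataclass
class ImageVolume:
    """A multi-channel intensity volume on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, arr in self.channels.items():
            arr = np.asarray(arr, dtype=np.float64)
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"channel {name!r} shape {arr.shape} != grid shape {self.grid.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite intensities")
            self.channels[name] = arr

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            )
        return self.channels[name]


@dataclass
class BinaryMask:
    """A boolean segmentation on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.voxels.shape} != grid shape {self.grid.shape}"
            )

    @property
    def volume_um3(self) -> float:
        """Total physical volume of the foreground in μm³."""
        return float(self.voxels.sum()) * self.grid.voxel_volume


REPORT_COLUMNS = ["region", "timepoint", "metric", "value", "dispersion", "units", "n"]


@dataclass
class MetricsReport:
    """Long/tidy table of per-region, per-timepoint metric values."""

    rows: list[dict] = field(default_factory=list)

    def add(
        self,
        region: str,
        timepoint: str,
        metric: str,
        value: float,
        dispersion: float = float("nan"),
        units: str = "a.u.",
        n: int = 1,
    ) -> None:
        if metric not in METRIC_REGISTRY:
            raise ValueError(f"unknown metric {metric!r}; not in registry")
        if not units:
            raise ValueError("units must be non-empty")
        self.rows.append(
            {
                "region": region,
                "timepoint": timepoint,
                "metric": metric,
                "value": float(value),
                "dispersion": float(dispersion),
                "units": units,
                "n": int(n),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=REPORT_COLUMNS)

    def device_summary(self) -> pd.DataFrame:
        """Average region values to one value per metric (per timepoint).

        Regions imaged within one device are averaged before any
        cross-device statistics, so each device contributes a single
        sample value per metric.
        """
        df = self.to_frame()
        return (
            df.groupby(["timepoint", "metric", "units"], as_index=False)
            .agg(value=("value", "mean"), n=("value", "size"))
        )

    def write_csv(self, path: str | Path) -> None:
        # fixed float formatting keeps repeated runs byte-identical
        self.to_frame().to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


# ---------------------------------------------------------------------------
# stack I/O
# ---------------------------------------------------------------------------


def read_stack(
    path: str | Path,
    channel_map: Mapping[str, int],
    spacing: tuple[float, float, float],
) -> ImageVolume:
    """Read a multi-page grayscale TIFF into an :class:`ImageVolume`.

    ``channel_map`` maps channel names to page offsets within each
    interleave group: with ``{"ec": 0, "dextran": 1}`` pages 0, 2, 4, …
    are ``ec`` and 1, 3, 5, … are ``dextran``.  Intensities are cast to
    float64 without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_pages = pages.shape[0]
    period = max(channel_map.values()) + 1
    if period > n_pages:
        raise IndexError(
            f"channel page offset {period - 1} out of range for {n_pages}-page stack"
        )
    if n_pages % period:
        raise ValueError(
            f"page count {n_pages} is not a multiple of the interleave period {period}"
        )
    channels = {
        name: pages[offset::period].astype(np.float64)
        for name, offset in channel_map.items()
    }
    nz = n_pages // period
    grid = VoxelGrid(shape=(nz,) + pages.shape[1:], spacing=spacing)
    return ImageVolume(grid=grid, channels=channels)


def write_stack(
    volume: ImageVolume,
    path: str | Path,
    channel_order: Iterable[str] | None = None,
) -> dict[str, int]:
    """Write an :class:`ImageVolume` as an interleaved multi-page TIFF.

    Returns the channel map that :func:`read_stack` needs to invert the
    interleave.  Intensities are written as float32 pages.
    """
    order = list(channel_order) if channel_order is not None else sorted(volume.channels)
    nz = volume.grid.shape[0]
    pages = np.empty((nz * len(order),) + volume.grid.shape[1:], dtype=np.float32)
    for off, name in enumerate(order):
        pages[off :: len(order)] = volume.channel(name)
    tifffile.imwrite(path, pages, photometric="minisblack")
    return {name: off for off, name in enumerate(order)}


# ---------------------------------------------------------------------------
# basic image operations
# ---------------------------------------------------------------------------


def binarize(
    volume: ImageVolume,
    channel: str,
    method: str = "otsu",
    threshold: float | None = None,
) -> BinaryMask:
    """Threshold a channel into a :class:`BinaryMask`.

    ``method="fixed"`` marks voxels with intensity >= ``threshold``;
    ``method="otsu"`` selects a global threshold from a 256-bin histogram
    of the channel's own intensity range.
    """
    data = volume.channel(channel)
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed binarization requires a threshold")
        mask = data >= threshold
    elif method == "otsu":
        lo, hi = float(data.min()), float(data.max())
        if lo == hi:
            raise ValueError(
                f"cannot apply Otsu thresholding to channel {channel!r}: "
                f"degenerate single-bin histogram (constant intensity {lo})"
            )
        from skimage.filters import threshold_otsu

        t = threshold_otsu(data, nbins=256)
        mask = data >= t
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return BinaryMask(grid=volume.grid, voxels=mask)


def z_projection(volume: ImageVolume, channel: str, mode: str = "max") -> np.ndarray:
    """Project a channel along z by pixelwise maximum, sum, or mean."""
    data = volume.channel(channel)
    if mode == "max":
        return data.max(axis=0)
    if mode == "sum":
        return data.sum(axis=0)
    if mode == "mean":
        return data.mean(axis=0)
    raise ValueError(f"unknown projection mode {mode!r}")


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "scenario": "default-day7",
    "seed": 0,
    "region_count": 3,
    "timepoint": "day7",
    "stages": ["morphometry", "perfusion", "afm", "dvc"],
    "channels": ["ec", "dextran", "matrix"],
    "morphometry": {"mode": "2d-projected"},
    "perfusion": {"heights_mm": [6.0, 3.0], "dt_s": 1200.0},
    "afm": {
        "n_curves": 50,
        "modulus_pa": 900.0,
        "force_noise_nn": 0.3,
        "reference_modulus_pa": 100.0,
        "decomposition_moduli_pa": {
            "fibrin": 50.0,
            "decellular": 270.0,
            "cytod": 470.0,
            "cnt": 900.0,
        },
    },
    "dvc": {"window": 16, "overlap": 0.5},
}


def load_config(source: str | Path | Mapping) -> dict:
    """Load a pipeline config from a YAML file or mapping, applying defaults."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: Mapping | str | Path, outdir: str | Path | None = None) -> MetricsReport:
    """Run the requested analysis stages on synthetic scenes and collect metrics.

    The config selects a synthetic scenario, a seed, the imaged region
    count, and the stages to run.  Identical config + seed produces an
    identical report.  When ``outdir`` is given, a tidy CSV, a JSON
    sidecar (config hash + seed) and a log file are written there; on a
    stage failure the rows collected so far are flushed before the error
    propagates.
    """
    from . import dvc_strain, mechanics, morphometry, perfusion, synthsim

    cfg = load_config(config)
    seed = int(cfg["seed"])
    stages = list(cfg["stages"])
    channels = list(cfg["channels"])
    timepoint = str(cfg["timepoint"])
    report = MetricsReport()

    out = Path(outdir) if outdir is not None else None
    log_handler = None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        log_handler = logging.FileHandler(out / "pipeline.log")
        log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(log_handler)
        logger.setLevel(logging.INFO)

    if "perfusion" in stages and "dextran" not in channels:
        raise ValueError(
            "stage 'perfusion' requires channel 'dextran', which the config omits"
        )
    if "dvc" in stages and "matrix" not in channels:
        raise ValueError("stage 'dvc' requires channel 'matrix', which the config omits")

    current_stage = "setup"
    try:
        for region_idx in range(int(cfg["region_count"])):
            region = f"region{region_idx:02d}"
            region_seed = (seed * 1000 + region_idx) % (2**31 - 1)
            scene = synthsim.simulate_scene(cfg["scenario"], seed=region_seed)
            logger.info("simulated scene %s for %s", cfg["scenario"], region)

            if "morphometry" in stages:
                current_stage = "morphometry"
                mcfg = cfg["morphometry"]
                mask = binarize(scene.volume, "ec", method="otsu")
                graph = morphometry.skeletonize(mask, mode=mcfg.get("mode", "2d-projected"))
                report.add(region, timepoint, "longest_network_length_um",
                           morphometry.longest_network_length(graph), units="um")
                graph3d = morphometry.skeletonize(mask, mode="3d")
                diam = morphometry.measure_diameters(graph3d, mask)
                if diam.size:
                    lat, trans = diam[:, 0], diam[:, 1]
                    report.add(region, timepoint, "mean_lateral_diameter_um",
                               lat.mean(), lat.std(), "um", lat.size)
                    report.add(region, timepoint, "mean_transversal_diameter_um",
                               trans.mean(), trans.std(), "um", trans.size)
                    dh = np.array([morphometry.hydraulic_diameter(a, b) for a, b in diam])
                    report.add(region, timepoint, "mean_hydraulic_diameter_um",
                               dh.mean(), dh.std(), "um", dh.size)
                ext = mask.grid.extent
                roi_mm2 = ext[1] * ext[2] / 1e6
                dens, vfrac = morphometry.density_and_volume_fraction(mask, graph3d, roi_mm2)
                report.add(region, timepoint, "vessel_density_per_mm2", dens, units="1/mm^2")
                report.add(region, timepoint, "vascular_volume_fraction_pct", vfrac, units="%")

            if "perfusion" in stages:
                current_stage = "perfusion"
                pcfg = cfg["perfusion"]
                mask = scene.lumen_mask
                perf = perfusion.perfusability(mask, scene.dextran_t1)
                report.add(region, timepoint, "perfusability_pct", perf, units="%")
                bf = perfusion.barrier_function(scene.dextran_t1, mask)
                report.add(region, timepoint, "barrier_function_inv_au", bf, units="1/a.u.")
                perm = perfusion.permeability(
                    scene.dextran_t1, scene.dextran_t2, mask, dt=pcfg["dt_s"]
                )
                report.add(region, timepoint, "permeability_cm_per_s", perm, units="cm/s")
                h_up, h_down = pcfg["heights_mm"]
                report.add(region, timepoint, "hydrostatic_pressure_pa",
                           perfusion.hydrostatic_pressure(h_up, h_down), units="Pa")

            if "afm" in stages:
                current_stage = "afm"
                acfg = cfg["afm"]
                rng_seed = (region_seed + 7919) % (2**31 - 1)
                curves = [
                    synthsim.synth_force_curve(
                        synthsim.CurveParams(
                            apparent_modulus_pa=float(acfg["modulus_pa"]),
                            noise_sd_nn=float(acfg.get("force_noise_nn", 0.0)),
                            seed=rng_seed + i,
                        )
                    )
                    for i in range(int(acfg["n_curves"]))
                ]
                fits = [mechanics.fit_hertz(c) for c in curves]
                summary = mechanics.aggregate_modulus(fits, min_n=len(curves))
                report.add(region, timepoint, "apparent_modulus_mean_pa",
                           summary.mean, summary.sem, "Pa", summary.n)
                report.add(region, timepoint, "apparent_modulus_median_pa",
                           summary.median, units="Pa", n=summary.n)
                report.add(region, timepoint, "stiffness_fold_change",
                           mechanics.fold_change(summary.mean, acfg["reference_modulus_pa"]),
                           units="fold")
                dm = acfg["decomposition_moduli_pa"]
                dec = mechanics.decompose_stiffness(
                    dm["fibrin"], dm["decellular"], dm["cytod"], dm["cnt"]
                )
                report.add(region, timepoint, "contribution_base_fibrin_pct",
                           dec.base_fibrin_pct, units="%")
                report.add(region, timepoint, "contribution_ecm_remodeling_pct",
                           dec.ecm_remodeling_pct, units="%")
                report.add(region, timepoint, "contribution_cell_material_pct",
                           dec.cell_material_pct, units="%")
                report.add(region, timepoint, "contribution_active_force_pct",
                           dec.active_force_pct, units="%")

            if "dvc" in stages:
                current_stage = "dvc"
                dcfg = cfg["dvc"]
                field_est = dvc_strain.dvc(
                    scene.speckle_pre, scene.speckle_post,
                    window=int(dcfg["window"]), overlap=float(dcfg["overlap"]),
                )
                mag = field_est.magnitude()
                ok = field_est.quality >= dvc_strain.DEFAULT_QUALITY_THRESHOLD
                report.add(region, timepoint, "max_displacement_um",
                           float(mag[ok].max()) if ok.any() else 0.0, units="um")
                hist = dvc_strain.displacement_histogram(field_est)
                if hist.frequencies.size:
                    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
                    report.add(region, timepoint, "mean_nonzero_displacement_um",
                               float((centers * hist.frequencies).sum()), units="um")
                strain = dvc_strain.strain_field(field_est)
                report.add(region, timepoint, "max_principal_strain",
                           float(np.nanmax(np.abs(strain.principal))), units="strain")
    except Exception:
        logger.exception("pipeline stage %r failed", current_stage)
        if out is not None:
            report.write_csv(out / "metrics_partial.csv")
        raise
    finally:
        if log_handler is not None:
            logger.removeHandler(log_handler)
            log_handler.close()

    if out is not None:
        report.write_csv(out / "metrics.csv")
        sidecar = {"config_hash": _config_hash(cfg), "seed": seed, "config": cfg}
        with open(out / "metrics.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
    return report
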