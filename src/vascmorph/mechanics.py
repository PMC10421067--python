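"""AFM force-curve analysis: Hertz contact fitting and stiffness decomposition.

A tissue indented by a spherical probe of radius R responds, in the Hertz
half-space model, with

    F = (4/3) · E_app · √R · δ^{3/2},

where δ is the indentation depth and E_app = E/(1−ν²) the apparent elastic
modulus (no Poisson-ratio assumption).  The module locates the contact
point on an approach curve, fits E_app, aggregates fits per sample, and
splits the measured tissue modulus into four additive contributions:
base fibrin gel, ECM remodeling, passive cell material, and active
cell-generated force.

Internally the fit works in SI units; inputs and outputs are in the
instrument's units (μm, nN, Pa).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ForceCurve",
    "HertzFit",
    "ModulusSummary",
    "StiffnessDecomposition",
    "hertz_force",
    "find_contact_point",
    "fit_hertz",
    "aggregate_modulus",
    "decompose_stiffness",
    "fold_change",
    "softness_pct",
    "read_force_curve",
    "read_force_curves",
]


@dataclass
class ForceCurve:
    """Approach segment of a force-distance curve.

    ``extension_um`` is the piezo extension (strictly increasing) and
    ``force_nn`` the measured cantilever force.
    """

    extension_um: np.ndarray
    force_nn: np.ndarray
    probe_radius_um: float = 25.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.extension_um = np.asarray(self.extension_um, dtype=float)
        self.force_nn = np.asarray(self.force_nn, dtype=float)
        if self.extension_um.shape != self.force_nn.shape:
            raise ValueError("extension and force must have equal length")
        if np.any(np.diff(self.extension_um) <= 0):
            raise ValueError("extension must be strictly increasing")
        if not np.all(np.isfinite(self.force_nn)):
            raise ValueError("force contains non-finite samples")


@dataclass(frozen=True)
class HertzFit:
    """Result of fitting one curve to the Hertz sphere model."""

    apparent_modulus_pa: float
    contact_point_um: float
    indentation_range_um: tuple[float, float]
    residual_rms_nn: float
    success: bool
    message: str = ""


@dataclass(frozen=True)
class ModulusSummary:
    mean: float
    median: float
    sem: float
    n: int
    n_failed: int
    flagged: bool  # True when fewer successful fits than required


def hertz_force(
    indentation_um: np.ndarray | float, apparent_modulus_pa: float, radius_um: float
) -> np.ndarray:
    """Hertz sphere-on-half-space force in nN for indentation in μm."""
    delta_m = np.asarray(indentation_um, dtype=float) * 1e-6
    f_newton = (
        (4.0 / 3.0)
        * apparent_modulus_pa
        * np.sqrt(radius_um * 1e-6)
        * np.clip(delta_m, 0.0, None) ** 1.5
    )
    return f_newton * 1e9


def _hertz_stiffness_si(apparent_modulus_pa: float, radius_um: float) -> float:
    return (4.0 / 3.0) * apparent_modulus_pa * np.sqrt(radius_um * 1e-6)


def find_contact_point(
    curve: ForceCurve,
    baseline_fraction: float = 0.3,
    k: float = 3.0,
    refine: bool = True,
) -> tuple[float, bool]:
    """Locate the tip-sample contact point on an approach curve.

    The pre-contact baseline is estimated by a robust (Theil-Sen) linear
    fit over the first ``baseline_fraction`` of the extension range; the
    contact point is the first sustained crossing of baseline + k·(noise
    sd), optionally refined by minimizing the Hertz-fit residual over
    nearby candidate points.  Returns ``(contact_point_um, success)``.
    """
    z, f = curve.extension_um, curve.force_nn
    if z.size < 100:
        raise ValueError("need at least 100 samples to locate a contact point")
    n_base = max(int(baseline_fraction * z.size), 10)
    res = stats.theilslopes(f[:n_base], z[:n_base])
    baseline = res.slope * z + res.intercept
    resid = f[:n_base] - baseline[:n_base]
    noise_sd = float(stats.median_abs_deviation(resid, scale="normal"))
    above = (f - baseline) > k * noise_sd
    # require a sustained crossing (3 consecutive samples) to reject spikes
    sustained = above & np.roll(above, -1) & np.roll(above, -2)
    sustained[-2:] = False
    idx = np.flatnonzero(sustained)
    if idx.size == 0:
        return float("nan"), False
    z0 = float(z[idx[0]])
    if not refine:
        return z0, True

    # grid search over candidate contact points minimizing Hertz residual
    step = float(np.median(np.diff(z)))
    lo = max(z[0], z0 - 50 * step)
    candidates = z[(z >= lo) & (z <= z0 + 10 * step)]
    best = (np.inf, z0)
    for zc in candidates:
        rms = _hertz_residual_rms(curve, float(zc))
        if rms < best[0]:
            best = (rms, float(zc))
    return best[1], True


def _hertz_residual_rms(curve: ForceCurve, contact_um: float) -> float:
    delta = np.clip(curve.extension_um - contact_um, 0.0, None)
    mask = delta > 0
    if mask.sum() < 5:
        return np.inf
    x = (delta * 1e-6) ** 1.5
    f_si = curve.force_nn * 1e-9
    k_fit = float(x[mask] @ f_si[mask] / (x[mask] @ x[mask]))
    resid = f_si - k_fit * x
    return float(np.sqrt(np.mean(resid**2)) * 1e9)


def fit_hertz(
    curve: ForceCurve,
    radius_um: float | None = None,
    contact_point_um: float | None = None,
    max_indentation_um: float | None = None,
) -> HertzFit:
    """Fit the Hertz sphere model to one approach curve.

    The contact point is located automatically unless given, then contact
    point and modulus are refined jointly by nonlinear least squares on
    F = k·max(z−z₀, 0)^{3/2}.  The fit window is capped at the
    indentation where the contact radius √(Rδ) reaches R/2, to stay
    within the Hertz regime; at least 0.2 μm of post-contact indentation
    is required.
    """
    r = float(radius_um if radius_um is not None else curve.probe_radius_um)
    if contact_point_um is None:
        z0, ok = find_contact_point(curve)
        if not ok:
            return HertzFit(float("nan"), float("nan"), (0.0, 0.0), float("nan"),
                            False, "no contact point found")
    else:
        z0, ok = float(contact_point_um), True

    cap = r / 4.0 if max_indentation_um is None else float(max_indentation_um)
    z, f = curve.extension_um, curve.force_nn
    delta0 = np.clip(z - z0, 0.0, None)
    if delta0.max() < 0.2:
        return HertzFit(float("nan"), z0, (0.0, float(delta0.max())), float("nan"),
                        False, "less than 0.2 μm of post-contact indentation")
    window = (z > z0 - 1.0) & (delta0 <= cap)
    zw, fw = z[window], f[window] * 1e-9

    def model(params: np.ndarray) -> np.ndarray:
        k_si, zc = params
        return k_si * (np.clip(zw - zc, 0.0, None) * 1e-6) ** 1.5 - fw

    k0 = _hertz_stiffness_si(max(_initial_modulus(curve, z0, r, cap), 1.0), r)
    sol = optimize.least_squares(model, x0=[k0, z0], method="lm", max_nfev=200)
    k_si, z0_ref = sol.x
    e_app = 3.0 * k_si / (4.0 * np.sqrt(r * 1e-6))
    resid_rms = float(np.sqrt(np.mean(model(sol.x) ** 2)) * 1e9)
    delta = np.clip(z - z0_ref, 0.0, None)
    used = (delta > 0) & (delta <= cap)
    if not sol.success or e_app <= 0 or not np.isfinite(e_app):
        return HertzFit(float("nan"), float(z0_ref), (0.0, 0.0), resid_rms,
                        False, "non-convergent or non-positive modulus")
    return HertzFit(
        apparent_modulus_pa=float(e_app),
        contact_point_um=float(z0_ref),
        indentation_range_um=(0.0, float(delta[used].max()) if used.any() else 0.0),
        residual_rms_nn=resid_rms,
        success=True,
    )


def _initial_modulus(curve: ForceCurve, z0: float, r: float, cap: float) -> float:
    delta = np.clip(curve.extension_um - z0, 0.0, None)
    mask = (delta > 0) & (delta <= cap)
    if mask.sum() < 5:
        return 0.0
    x = (delta[mask] * 1e-6) ** 1.5
    f_si = curve.force_nn[mask] * 1e-9
    k_si = float(x @ f_si / (x @ x))
    return 3.0 * k_si / (4.0 * np.sqrt(r * 1e-6))


def aggregate_modulus(fits, min_n: int = 50) -> ModulusSummary:
    """Summarize successful Hertz fits for one sample.

    At least ``min_n`` successful curves are expected per sample; fewer
    produces a flagged (but still reported) summary.
    """
    ok = [f.apparent_modulus_pa for f in fits if f.success]
    n_failed = sum(1 for f in fits if not f.success)
    if not ok:
        return ModulusSummary(float("nan"), float("nan"), float("nan"), 0, n_failed, True)
    arr = np.asarray(ok)
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return ModulusSummary(
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        sem=sem,
        n=arr.size,
        n_failed=n_failed,
        flagged=arr.size < min_n,
    )


@dataclass(frozen=True)
class StiffnessDecomposition:
    """Four-component split of the measured tissue modulus.

    Percentages are defined against the untreated control modulus E_CNT:
    base fibrin = 100·E_fibrin/E_CNT; ECM remodeling =
    100·(E_Decellular−E_fibrin)/E_CNT; cell material =
    100·(E_CytoD−E_Decellular)/E_CNT; active force is the remainder,
    algebraically 100·(E_CNT−E_CytoD)/E_CNT, so the four always sum to
    exactly 100.
    """

    e_fibrin_pa: float
    e_decellular_pa: float
    e_cytod_pa: float
    e_cnt_pa: float
    base_fibrin_pct: float
    ecm_remodeling_pct: float
    cell_material_pct: float
    active_force_pct: float
    ordering_violated: bool


def decompose_stiffness(
    e_fibrin_pa: float,
    e_decellular_pa: float,
    e_cytod_pa: float,
    e_cnt_pa: float,
) -> StiffnessDecomposition:
    """Split the control modulus into its four stiffening contributions.

    The expected ordering E_fibrin ≤ E_Decellular ≤ E_CytoD ≤ E_CNT is
    flagged (not fatal) when violated; a violation shows up as a negative
    contribution.
    """
    if e_cnt_pa <= 0:
        raise ValueError("control modulus E_CNT must be positive")
    base = 100.0 * e_fibrin_pa / e_cnt_pa
    ecm = 100.0 * (e_decellular_pa - e_fibrin_pa) / e_cnt_pa
    cell = 100.0 * (e_cytod_pa - e_decellular_pa) / e_cnt_pa
    active = 100.0 - base - ecm - cell  # = 100·(E_CNT − E_CytoD)/E_CNT
    ordering_ok = e_fibrin_pa <= e_decellular_pa <= e_cytod_pa <= e_cnt_pa
    return StiffnessDecomposition(
        e_fibrin_pa=float(e_fibrin_pa),
        e_decellular_pa=float(e_decellular_pa),
        e_cytod_pa=float(e_cytod_pa),
        e_cnt_pa=float(e_cnt_pa),
        base_fibrin_pct=base,
        ecm_remodeling_pct=ecm,
        cell_material_pct=cell,
        active_force_pct=active,
        ordering_violated=not ordering_ok,
    )


def fold_change(modulus_pa: float, reference_pa: float) -> float:
    """Stiffness fold change relative to a reference condition."""
    if reference_pa <= 0:
        raise ValueError("reference modulus must be positive")
    return modulus_pa / reference_pa


def softness_pct(modulus_pa: float, reference_pa: float) -> float:
    """Percentage softening relative to a reference: 100·(1 − E/E_ref)."""
    return 100.0 * (1.0 - fold_change(modulus_pa, reference_pa))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_force_curve(
    path: str | Path, probe_radius_um: float = 25.0, **metadata
) -> ForceCurve:
    """Read a two-column (position μm, force nN) delimited text file.

    Whitespace- and comma-delimited files are accepted; lines starting
    with ``#`` and a single non-numeric header line are skipped.
    """
    path = Path(path)
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[-1] else None
    try:
        data = np.loadtxt(path, comments="#", delimiter=delimiter)
    except ValueError:
        data = np.loadtxt(path, comments="#", delimiter=delimiter, skiprows=1)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (position, force)")
    return ForceCurve(
        extension_um=data[:, 0],
        force_nn=data[:, 1],
        probe_radius_um=probe_radius_um,
        metadata={"source": str(path), **metadata},
    )


def read_force_curves(
    directory: str | Path, pattern: str = "*.txt", probe_radius_um: float = 25.0
) -> list[ForceCurve]:
    """Read every matching force-curve file in a directory (sorted order)."""
    files = sorted(Path(directory).glob(pattern))
    if not files:
        raise FileNotFoundError(f"no {pattern} force-curve files in {directory}")
    return [
        read_force_curve(p, probe_radius_um=probe_radius_um, position_index=i)
        for i, p in enumerate(files)
    ]
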