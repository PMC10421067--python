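# Methods

This note documents the models and procedures the package implements,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open.

## Data model and conventions

Volumes are voxel grids in `(z, y, x)` axis order with anisotropic
physical spacing in micrometres; z is perpendicular to the glass
substrate ("transversal"), x/y are in-plane ("lateral"). The reference
imaging geometry is 21 slices at a 10-μm z-step over a 1.27 × 1.27 mm
field at 1.24 μm in-plane pitch. Intensities are arbitrary units and
are never rescaled on read. Physical quantities are reported in μm,
Pa, nN, and cm/s. Region metrics are averaged to one value per device
before any cross-device statistics.

## Synthetic vessel networks

`synthsim.generate_tree` grows a forest from root nodes on the
upstream face of a tissue slab. Defaults encode the day-7 morphology
of the microvascular networks the generator emulates:

| parameter | default | rationale |
|---|---|---|
| slab | 210 × 1270 × 1270 μm | the imaging region |
| segment length | 50 + Exp(40) μm, truncated at 900 | mean 90 μm within the observed 50–900 μm range |
| lumen diameter | lognormal, mean 44 μm, shape 0.35, truncated to 5–150 μm | observed distribution of day-7 lumen diameters |
| transversal/lateral anisotropy | 30/44 | vessels are flattened toward the substrate |
| bifurcation opening angle | N(70°, 10°) | typical microvascular branching |
| branching probability | 0.35 per completed segment | produces realistic junction densities |
| tortuosity | A·sin²(πs/L) bow, A = 6 μm | smooth centre-line waviness |

Design choices worth noting:

* The tortuosity perturbation has zero value *and zero slope* at both
  segment ends, so junction tangents — and therefore measured branch
  angles — are unaffected by the waviness.
* Bifurcation planes are drawn with a damped vertical component
  (factor 0.25) and re-drawn (up to 30 times) until both daughters fit
  in the slab. Thin-slab vascular beds branch quasi-in-plane, and this
  is also what lets the sampled opening-angle distribution actually be
  realized; with isotropic branching in a 210-μm slab, wall collisions
  would systematically distort the angles. Segments that would still
  leave the slab keep their sampled heading reflected at the faces
  (preserving the sampled length), and only as a last resort is a
  shorter length re-drawn.
* Rasterization marks a voxel as lumen when its offset from the
  nearest centre-line point satisfies
  (d_xy/a)² + (d_z/b)² ≤ 1 — an elliptical tube with rounded
  (ellipsoidal) end caps.

## Tracer-leak forward model

At t1 the tracer fills the root-connected lumens at intensity I_v over
a small interstitial baseline. By t2 = t1 + Δt (default 20 min) the
interstitial mean has risen by exactly

ΔI = P·Δt·(S/V_int)·(I_v − I_i(t1)),

with S the perfused-lumen surface area (marching-cubes mesh on the
rasterized mask) and V_int the interstitial volume. The spatial
pattern of the leaked intensity is an exponential halo around the
perfused vessels with a 150-μm decay length — the diffusion length of
a 70-kDa tracer over 20 min is several hundred μm, so a broad halo is
the physical choice — globally rescaled so the interstitial mean
matches the closed form to machine precision. Gaussian noise is added
last. The closed-form mean is the generator's contract; the halo shape
is free.

When the perfused fraction is below 1, top-level subtrees are dropped
in seeded random order until the perfused lumen volume reaches the
target fraction.

## Skeletonization and morphometry

Anisotropic masks are resampled to isotropic spacing (linear
interpolation, 0.5 threshold) before thinning. The 3D thinning is the
package's own **distance-ordered homotopic thinning**: border voxels
are deleted one at a time in increasing order of distance to the
background, only when deletion is topologically safe — the standard
simple-point characterization (one 26-connected foreground component
in the 26-neighbourhood and one 6-connected background component
touching the centre by face adjacency) — and never when the voxel is a
curve endpoint. The result is a one-voxel-wide, 26-connected curve
skeleton with exactly the input's connectivity, centred on the medial
axis. Simple-point decisions are cached by the 3×3×3 neighbourhood
pattern, which makes the sequential algorithm fast on tubular masks.
The 2D projected mode uses the standard 2D thinning of the maximum
z-projection.

Graph conversion merges adjacent junction voxels into single junction
nodes and degree-2 chains into single edge polylines. Three
regularizations follow:

* **Spur pruning**: terminal edges shorter than 2× the local vessel
  diameter (from the mask's Euclidean distance transform) are removed;
  thinned blobs whose total length falls below the same bound are
  dropped entirely.
* **Centre-line smoothing**: a 5-point moving average (endpoints
  fixed) suppresses the voxel-path staircase, which otherwise inflates
  arc length for oblique vessels.
* **End-cap trimming**: under thinning, a vessel's rounded end erodes
  to a line that runs past the medial axis toward the cap pole and can
  wander on the distance-transform plateau. Walking from the interior
  with a running local tangent, the cap entrance is detected where the
  path departs laterally from the local axis; the cap pole is found by
  marching along the tangent to the mask boundary; and the centre line
  is cut back to one local radius inside the pole — where the medial
  axis of a round-capped tube ends — with the new endpoint placed on
  the interior axis. Ends that leave through a grid face are left
  untouched. On rasterized test tubes this recovers the true tube
  length to within one voxel pitch (axis-aligned; obliquely oriented
  tubes stay within two pitches from residual staircase effects).

Diameters are measured at fixed arc-length steps along each edge: the
mask is probed from the centre point along the horizontal in-plane
axis (lateral) and the remaining, z-tilted perpendicular axis
(transversal) in 0.25-voxel steps until leaving the foreground.
Samples whose centre misses the mask or whose section escapes the grid
are skipped and counted; samples within one local diameter of a
junction are excluded. The branching angle of a junction is defined as
the smallest pairwise angle between the outgoing edge tangents (fitted
over the first three polyline points) — the opening between the two
diverging daughter branches; pairs involving the parent direction are
never smaller for openings below ~120°.

Hydraulic diameter uses the ellipse area and Ramanujan's second
perimeter approximation. Per-vessel D_h values are computed first and
then averaged; note this differs slightly from the D_h of the mean
axes (for mean axes 44/30 μm the latter is 35.4 μm).

## Perfusion metrics

* Perfusability reslices the stacks into x–z cross sections; each
  connected vessel-section component containing at least one
  suprathreshold tracer voxel contributes its full area. The tracer
  threshold defaults to Otsu on the t1 volume; a constant volume means
  no tracer anywhere and scores 0.
* The interstitial region is the complement of the EC mask dilated by
  one voxel (configurable), which avoids vessel-wall bleed-through.
  Interstitial means for permeability are volumetric by default; a
  projected option exists. Barrier function uses the mean z-projection
  so that a uniform interstitial intensity I gives exactly 1/I.
* Permeability follows the two-timepoint estimate above with the
  measured V_int/S; an override allows the single-vessel d/4
  convention. No transient-diffusion fitting is attempted.
* The assay's driving pressure is ρgΔh for water.

## AFM analysis

Synthetic approach curves are flat to the contact offset, then follow
the Hertz sphere model to the 30-nN set force (probe radius default
25 μm — a 50-μm glass microsphere), sampled at 10 nm.

The contact point is found from a robust (Theil–Sen) baseline over the
first 30% of extension, crossed at 3× the baseline noise (median
absolute deviation) for three consecutive samples, then refined by
grid search minimizing the Hertz residual. The final fit refines
contact point and modulus jointly by nonlinear least squares on
F = k·max(z − z₀, 0)^{3/2}. The fit window is capped at the
indentation where the contact radius √(Rδ) reaches R/2 to stay within
the Hertz regime. Fits are performed in SI units and reported in
Pa/nN/μm. Per-sample aggregation expects at least 50 successful curves
and flags (but still reports) smaller samples. The four-component
decomposition computes the active-force term as the remainder, so the
contributions sum to exactly 100 algebraically.

## Digital volume correlation and strain

A single-pass windowed scheme (default 32³ windows, 50% overlap; 16³
in the down-scaled test scenes) with a discrete window offset: the
circular FFT cross-correlation provides an integer first guess; a
direct normalized-cross-correlation hill-climb over re-extracted
deformed windows locks the integer offset free of wraparound
contamination; and a three-point Gaussian (log-parabola) fit on the
NCC values adds the subvoxel remainder. A perfect content match
(NCC = 1) terminates refinement at the exact integer, so pure integer
translations are recovered exactly; measured subvoxel accuracy on
smooth speckle is ~0.01–0.1 voxel. Node quality is the peak NCC;
featureless windows are flagged (quality 0), and nodes below quality
0.3 are excluded from histograms and statistics. This is not an
iterative multi-resolution method; displacements above ~window/4
voxels are outside its contract.

The nonzero-displacement histogram thresholds |u| at 2× the measured
subvoxel precision (0.1 voxel) by default and normalizes to relative
frequencies. Strain is the symmetric gradient of u by central
differences in physical units (exact for affine fields, one-sided at
boundaries); principal strains come from the symmetric
eigendecomposition. An optional rigid-drift removal subtracts the
quality-weighted mean displacement. Near-vessel statistics compare
|u| (or the largest-magnitude principal strain) in an interstitial
shell around the lumen surface against the remaining far field.

## Problem sizes

The packaged scenarios run the full analysis on down-scaled regions
that keep the day-7 morphology on tractable grids: 120 × 400 × 400 μm
at (8, 2, 2) μm spacing for image stacks, 48³ isotropic speckle
volumes for displacement fixtures, and 50 synthetic force curves per
sample. The acceptance script simulates three such regions per run;
sampling-based checks pool ≥2000 segments, ≥500 junctions, or 10
seeds per modulus as appropriate.

## What the generator does not emulate

The synthetic scenes are idealized in ways real data is not: vessel
walls have zero thickness and uniform intensity (no point-spread
blur, shading, or photobleaching); the tracer leak is spatially smooth
and conserves the closed-form mean exactly (no focal leaks or flow
gradients); force curves have no baseline drift, hydrodynamic drag, or
adhesion; and speckle deformation is purely geometric (no
decorrelation from remodeling). Passing tests therefore demonstrate
correctness of the measurement operations under known ground truth,
not robustness to every imaging artefact. Segmentation of real
embryo-scale data (the deep-learning route) is out of scope; the
morphometry operates on any binary mask however obtained.

## Known limitations

* Skeleton accuracy is stated for vessels at least ~3 voxels in
  radius; thinner vessels rasterize and thin poorly (a warning is
  logged when voxel spacing exceeds the smallest radius).
* The permeability estimate inherits discretization error from the
  voxelized surface area and interstitial volume (a few percent at
  the packaged resolutions).
* The DVC quality measure is a correlation coefficient, not a
  confidence interval; strain at the field boundary uses one-sided
  differences.
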