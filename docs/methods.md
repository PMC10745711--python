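# Methods

This note documents the models behind each `vasckit` module, the
defaults and why they were chosen, the numerical details that affect
results, and what the synthetic-data generators do and do not emulate.

## Study conditions and reference parameters

The defaults throughout the package describe a pressure-driven
microvessel-on-chip culture: a fibrin gel channel (~3 mm long) seeded
with endothelial and stromal cells, perfused by a hydrostatic reservoir
at pressure drops of 0 / 3 / 7 mmH₂O (≈ 0 / 30 / 70 Pa). The reference
quantities used as generator ground truths and oracle inputs are:

| quantity | value | role |
|---|---|---|
| mean interstitial velocity, low flow | 0.30 μm/s | drift-velocimetry truth |
| mean interstitial velocity, high flow | 1.23 μm/s | drift-velocimetry truth |
| 70-kDa dextran diffusivity in fibrin | 34.5 μm²/s | FRAP truth |
| central channel length L | 3 mm | Peclet length scale |
| mature lumen diameter | ~40 μm | network stroke width |
| media density / viscosity | 998.2 kg/m³, 9.4×10⁻⁴ Pa·s | CFD lumen |
| gel density / viscosity | 985 kg/m³, 1×10⁻² Pa·s | CFD gel (Brinkman) |
| gel porosity / permeability | 0.3, 1×10⁻¹³ m² | CFD gel |
| applied pressure drop | 70 Pa | CFD boundary condition |
| indenter radius / stiffness / ν | 25 μm, 0.027 N/m, 0.5 | Hertz fitting |
| imaging calibration | 0.64 μm/pixel | generator default |
| FRAP bleach spot / frame interval | 30 μm Ø, 0.4 s | FRAP fixtures |

With these values Pe = vL/D evaluates to ≈26 (low flow) and ≈107 (high
flow), both above the Pe > 10 threshold commonly associated with a
vasculogenic response to interstitial flow.

## Synthetic data

**Vessel networks.** Node positions are seeded uniformly with a
dart-throwing minimum spacing; edges follow the relative-neighborhood
rule (lune-empty criterion, a subset of the Delaunay graph) and the
largest connected component is kept. This produces sparse, loopy,
planar networks that look like self-assembled vascular beds without
modelling angiogenesis. Branches are stroked at constant width (drawn
from N(width_mean, width_sd)); a pixel is vessel iff its center lies
within width/2 of a centerline — no anti-aliasing, so area and length
stay analytically checkable. Round caps are the default (the medial
axis then runs endpoint to endpoint); the `bar_mask` helper draws a
flat-capped, half-open band so an axis-aligned L×w bar covers exactly
L·w pixels.

**Noise model.** All imaging noise is Poisson-like: σ ∝ √signal, scaled
by `noise_scale`. The imaging noise level of the emulated experiments is
not documented, so fixtures default to noiseless and the acceptance
fixtures use `noise_scale = 0.5` (pixel SNR ≈ 20 at the 100-AU imaging
baseline — typical for single confocal frames).

**Dye leakage.** Intravascular intensity is constant (I₁); extravascular
signal accumulates uniformly in a perivascular band. The image-intensity
accumulation rate is calibrated to a *cylindrical* vessel of diameter
d_eff rendered in 2D projection: dΣ/dt = 4·(A_v/d_eff)·(I₁−I₀)·P, the
image-domain form of the wall flux J = P·S·ΔC with S/V = 4/d. This is
the same geometric convention the estimator's d/4 factor assumes, so the
generator–estimator pair closes exactly; a planar-slab convention
(S/V = 2/d) would differ by a factor of 2 in both places and cancel the
same way.

**FRAP movies.** The post-bleach frames are the exact linear
advection–diffusion evolution of a uniform-disc deficit: the initial
deficit is propagated spectrally with the factor
exp(−k²Dt − i k·v t) on a 3×-zero-padded grid. No PDE time stepping is
involved, so the movie is its own oracle for both the recovery curve
and the drifting centroid. Ten pre-bleach frames are generated by
default, emulating the pre-bleach reference series instruments record;
averaging them matters for velocimetry (below).

**Bead movies, indentation, pressure decay.** Beads are Gaussian blobs
on separated y-lanes (the non-crossing regime) advected at per-bead
speeds drawn around `v_mean`; truth stores every track. Indentation
curves are exact Hertz loading ramps (12-μm depth) with an optional
flat pre-contact segment and multiplicative load noise; the
`compliance=True` variant emits raw piezo travel δ + F/k_probe.
Pressure decays are single exponentials ΔP = ΔP₀·e^(−t/τ) sampled every
4 h from ΔP₀ = 7 mmH₂O.

**What the generators do not emulate:** 3D image formation (everything
is a 2D projection), bleaching during acquisition, flow-deformed bleach
profiles (drift is uniform), bead–wall hydrodynamic interactions, vessel
wall heterogeneity (permeability is spatially uniform), and adhesion or
viscoelasticity in indentation. Passing the closed-loop tests therefore
demonstrates estimator correctness under each model's assumptions, not
robustness to every artifact of real microscope data.

## Morphometry

Segmentation follows the standard macro order: maximum projection,
Gaussian smoothing (σ in μm), median-based outlier replacement
(|I − median| beyond a threshold, default 5× the robust sd of the
median residual), then a global threshold (Otsu by default; the
threshold method the original macros use is not documented, so it is
configurable per channel). Degenerate thresholds (all-foreground /
all-background) raise with the offending threshold value.

Skeletonization is topological thinning (`skimage.morphology.
skeletonize`). Pixels with ≥3 8-neighbors are junction pixels and are
merged into single junction nodes by connected components — raw thinning
produces junction clumps that would otherwise inflate counts. Terminal
branches shorter than a prune length (default 10 μm, configurable)
are removed iteratively; this suppresses pixel-scale spurs without
deleting real branches.

Two numerical corrections keep length-derived metrics accurate to the
±5% contract on constant-width fixtures:

1. **Polyline simplification.** Branch lengths are measured on
   Ramer–Douglas–Peucker-simplified polylines (1-px tolerance), not raw
   8-connected chains; the chain sum overestimates diagonal branches by
   up to 8% (staircase effect), the simplified polyline does not.
2. **Terminal extension.** Thinning retracts branch tips by roughly half
   the local width. Each surviving terminal branch is extended along its
   end direction until it exits the mask (capped at twice the local
   distance-transform value), restoring centerline length. The skeleton
   *pixel* set is untouched, so skeleton ⊆ mask remains exact.

Connectivity is junctions/endpoints and is reported as NaN with a
`connectivity_defined=False` flag when the graph has no endpoints
(pure loops), never as infinity. The ROI for density/coverage is the
full image unless a gel-region mask is supplied.

## Permeability

P = (d_eff/4) · (dI/dt) / (I₁ − I₀), where I(t) is the
background-subtracted intensity integrated over the vessel plus a
perivascular band (default 30 μm), normalized to vessel area; I₁ is the
initial mean intravascular intensity; d_eff/4 is the volume-to-surface
ratio of a cylinder of the morphometric effective diameter (computed
from the supplied mask when not given). The ratio form is invariant to
affine intensity rescaling; the slope is an ordinary least-squares fit
over the measurement window, which starts at the first frame by default
(configurable to skip a convective-stabilization period). Units: cm/s.

## FRAP diffusivity

The normalized recovery f(t) = (I(t) − I(0⁺))/(I_pre − I(0⁺)) of the
mean intensity inside the bleach disc is fit to the Soumpasis
uniform-disc closed form scaled by a mobile fraction M, using
exponentially-scaled Bessel functions (`scipy.special.ive`) for
stability and a half-time-seeded Levenberg–Marquardt fit. The bleach
ROI radius is taken from metadata, not estimated from the image — the
bleach geometry is an instrument setting, and estimating it from a
noisy first frame would correlate errors between w and τ_D. The
half-time cross-check D = 0.224·w²/t_half references the *fitted*
mobile fraction (a finite movie need not reach its plateau). Fits whose
observed recovery stays below 20% of the plateau are flagged
low-confidence.

## Centroid-drift velocimetry

The per-frame intensity deficit (mean pre-bleach frame minus current
frame) is Gaussian-smoothed (default 2 px — a symmetric kernel cannot
shift the centroid but suppresses the noise floor), thresholded at 3×
the smoothed pre-bleach noise sd, and its weighted centroid computed
inside a window iterated mean-shift style around itself. The windowed
iteration matters: a full-field centroid is biased toward the field
center once the spreading deficit reaches the image edge, while a
window centered on the spot truncates the tail symmetrically. Speed is
the magnitude of a weighted linear fit of centroid vs time, with
weights ∝ (deficit mass)² since the centroid sd of a frame scales
inversely with its deficit mass. Frames whose peak deficit falls below
15× the noise sd are dropped: in such frames the static residual of the
pre-bleach reference noise competes with the real deficit and produces
a seed-dependent drift bias (this is also why averaging ~10 pre-bleach
frames, not 2, is the generator default). At the slow condition
(0.30 μm/s) the movie must be long enough for total displacement to
clear several pixels; 150 frames at 0.4 s (18 μm of drift) suffices.

## Bead tracking

Detection is scale-normalized Laplacian-of-Gaussian filtering at
σ = blob_diameter/(2√2) with 3×3 local maxima above an intensity
threshold (defaults: 5-μm blobs, 2 AU) and per-axis quadratic subpixel
refinement. Linking replaces an LAP assignment solver with greedy
nearest-neighbor matching (pairs assigned in order of increasing
distance, ties broken by coordinates so results are independent of spot
order) within a 15-μm radius, gap closing across up to 2 missing
frames, and a 5-μm minimum-displacement filter for nonmoving objects
(the filter the emulated workflow applies without a documented value).
Greedy linking is equivalent to LAP for the sparse, non-crossing,
similar-speed regime generated here; it is a documented limitation for
dense or crossing scenes. Track mean speed is path length / duration.

## Stokes–Brinkman solver

One unified momentum equation covers both domains:
−∇p + ∇·(μ(x)∇u) − χ_gel(x)·(μ_gel/k)·u = 0 with ∇·u = 0, μ = media
viscosity in lumen, gel (Brinkman effective) viscosity in gel. Inertia
is dropped: at the device's velocities and scales Re ≲ 1, and the
resulting linearity in ΔP is verified exactly in the tests. Choices:

- **Grid**: staggered (MAC), pressure-centered, supporting rectangular
  cells (dx ≠ dy) — Poiseuille and Darcy fixtures are x-invariant and can
  be resolved finely across the channel while remaining coarse along it.
- **Boundary conditions**: Dirichlet pressure at the left (inlet, ΔP)
  and right (outlet, 0) edges via ghost-cell mirroring; no-slip
  top/bottom walls via velocity mirror ghosts; zero-gradient tangential
  velocity at the open ends.
- **Interface coefficients**: viscosity at staggered flux points is
  harmonically averaged across the lumen–gel interface; the Darcy drag
  at a face is the *arithmetic* mean of the adjacent cell drags — a
  harmonic mean would vanish at every interface (lumen drag is zero) and
  de-anchor the gel boundary layer.
- **Solve**: one sparse LU factorization (SuperLU) plus a single step of
  iterative refinement; the divergence residual reaches machine
  precision (~1e-16 relative), reported on the field object.
  Singular systems raise.
- **Shear scalar**: τ = μ(x)·√(2E:E) from central differences of the
  cell-centered velocities (second-order one-sided at edges). The
  emulated commercial solver does not document its reported scalar;
  this invariant of the strain-rate tensor is the package's choice.
- **Gel velocities** are superficial (Darcy) velocities; region
  statistics also report the pore velocity (superficial/porosity, 0.3),
  since which of the two a surface-average table reports is ambiguous.

Default problem sizes keep a direct solve comfortable: masks are
majority-vote coarsened to ≲200×300 cells (a 75×150-cell network solves
in ~1–2 s); oracle fixtures use 80 cells across the channel.

The printed interstitial shear stresses of the emulated study
(~1.3×10⁻⁵ / 3.8×10⁻⁵ Pa) are *not* reproduced by the standard Brinkman
scaling τ = μv/√k with the stated μ, v, k (which gives ~10² more);
the exact equations and parameters behind those printed values are not
restated in the source. `interstitial_shear` therefore labels its
result with the formula used, and no test asserts those printed values.
Likewise the study's Table-1 region means depend on its segmented
geometries, which are not deposited; the tests assert the qualitative
structure instead (gel mean velocity ≥1 order of magnitude below the
lumen mean, tissue mean in between).

## Hertz fitting

Contact is the first depth where the load persistently (5 consecutive
samples) exceeds baseline mean + 3 sd, with the baseline taken from the
first 15% of samples; a "baseline" that rises beyond 3× its own
residual scatter means the curve starts in contact (offset 0, warning),
and a curve that never leaves its baseline is an error. The fit is
linear least squares of F on δ^{3/2} over the loading segment (up to a
configurable fraction of max depth), so it is exact on noiseless data;
E = (3/4)·a·(1−ν²)/√R with ν = 0.5 (incompressible gel). Cantilever
compliance (δ_sample = δ_piezo − F/k, k = 0.027 N/m) is toggleable
because exported instrument curves are usually already corrected.
Fits with E ≤ 0 or R² < 0.8 are flagged unreliable. Unloading,
adhesion, and viscoelastic relaxation are out of scope.

## Pressure decay

ΔP(t) = ΔP₀·e^(−t/τ), seeded by a log-linear fit and refined by
nonlinear least squares. τ is a descriptive hydraulic relaxation
constant (resistance × reservoir capacitance); series that do not decay
(fitted τ beyond 50× the record length, or a non-negative log-slope)
are flagged rather than rejected. The emulated experiment reports but
does not model its decay curves, so the single-exponential form is a
package choice, not a claimed physical law.

## Problem sizes and tolerances in the test suite

Closed-loop recoveries assert 10% (FRAP D, permeability, drift
velocimetry), 5% (bead speed, noiseless Hertz, effective diameter), or
15% (Hertz at 5% load noise, FRAP-vs-bead cross-modality agreement).
CFD oracles assert 2% (Poiseuille u_max, Darcy velocity), 3% (wall
shear, region means) and 1% (cross-section mass conservation). FRAP
movies run 60 frames (24 s) at the fast conditions and 150 frames at
the 0.30 μm/s condition; CFD fixtures use ≤80×150-cell grids. These
sizes were chosen so every oracle has comfortable numerical margin at
second-order discretization accuracy.
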