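# Methods

## The mechanical model

The embryo is idealised as a thin, flat, linearly elastic sheet occupying a
disc of radius R_AO = 5 mm (the mounting ring), partitioned into
concentric elliptical regions sharing a centre and axes:

| region          | semi-axes (ML, AP) mm | thickness μm | default E kPa |
|-----------------|----------------------|--------------|---------------|
| midline         | 0.18, 2.2            | 84           | 2.4           |
| intermediate    | 0.23, 2.25           | 56           | 1.3           |
| area pellucida  | 1.15, 2.8            | 56           | 2.1           |
| area opaca      | disc to r = 5        | 76           | 11.9          |

The "Ellipse Axes" entries of the morphology table are interpreted as
**semi-axes** (the AP pellucida value 1.15 mm must fit inside the 5 mm
ring); both the interpretation and every value are overridable through
`build_default_geometry` / the `geometry` config block. In the 4-region
variant the intermediate ellipse is the midline ellipse grown by 0.05 mm
on both semi-axes (configurable `intermediate_offset`) with the pellucida
thickness; the 3-region variant drops it.

Coordinates: x = mediolateral, y = anterior–posterior, origin at the
ellipse centre, caudal = −y. The default loads are a 190 nN caudal force
at (0, 0) ("midline") and a 200 nN caudal force at (0.665, 0) mm, half-way
between the midline ellipse edge (0.18 mm) and the pellucida edge
(1.15 mm) ("area_pellucida"). Whether the experimental midline force sits
exactly at y = 0 is not knowable from morphology alone, so the position is
a config input.

**Plane stress.** For a sheet this thin the out-of-plane stress vanishes
and in-plane equilibrium reduces to 2D elasticity with the membrane
stiffness proportional to E·t per region. Consequently only the product
E·t is identifiable; thicknesses are treated as known inputs (measured
independently) and the fit returns E. A property test asserts the exact
degeneracy (t → c·t, E → E/c leaves displacements unchanged). Poisson's
ratio is fixed at ν = 0.3; sweeping ν over [0.1, 0.4] changes the lattice
field by at most ~7% relative RMS (the acceptance script recomputes this),
which is why ν cannot be estimated from these data and why fixing it is
harmless.

**Boundary and load.** The ring clamps both displacement components on
r = 5 mm. The pipette force is applied as a nodal point force at the mesh
node nearest the requested position; meshes are refined around load
positions (geometric rings down to 10 μm edges) so the snap distance is
essentially zero. The true contact is a ~3 μm-radius pipette inserted
through the thickness; the point-load idealisation is only trusted at
lattice distances (≥ ~17 μm), never at the singularity itself.

## Meshing

`generate_mesh` builds a Delaunay triangulation of ~3000 nodes (±20%,
configurable): curvature-adaptive arc-length sampling of each ellipse
boundary (the midline tip has a 15 μm radius of curvature and needs local
refinement for region areas to converge), per-region hexagonal background
lattices with spacing weights 1 : 1 : 2 : 4 (innermost to outermost) so
the narrow midline is resolved, deterministic jitter for triangle quality,
refinement rings at the loads, and exact boundary nodes on the outer
circle. Elements are 3-node linear (constant-strain) triangles tagged by
the region containing their centroid; ellipse boundaries belong to the
inner region. Tagged region areas match the analytic ellipse-ring areas
to well under 5%; the assembly passes the uniform-strain patch test to
machine precision, and probe displacements 0.5 mm from the load change by
<1% between 3000 and 12000 nodes.

For joint geometry+modulus fitting the mesh is **morphed**, not
regenerated: nodes move along rays from the centre by the piecewise-linear
radial map that carries the old region boundaries onto the candidate ones.
The objective is then continuous in the semi-axes (a remeshing generator
would make it piecewise-constant at the scale of finite-difference steps).
Inverted sliver triangles, which extreme optimiser candidates can produce,
are re-oriented so the assembly stays positive definite; such candidates
score poorly and are rejected by the trust region.

## The analytic point-force solution

For validation the package provides the 2D Kelvin-type fundamental
solution under plane stress,

u_i = F_j /(8π μ t (1−ν\*)) · [(3−4ν\*) ln(r0/r) δ_ij + x_i x_j/r² − c0 δ_ij],

with ν\* = ν/(1+ν). A 2D point-force displacement is only defined up to a
constant: r0 (default 5 mm) sets where the logarithm vanishes and c0
(default 1.0) was calibrated once against a mesh-refined clamped-disc
finite-element solution so that, with r0 equal to the disc radius, the
formula reproduces the clamped-disc near field to ~1% well inside the
boundary. The far field diverges logarithmically whatever the constants —
the physical reason a finite clamped domain, not the infinite-sheet
formula, must be used for the embryo.

## PIV

Displacements between the reference and loaded image are estimated per
16 px interrogation window (zero overlap; 640×512 px at 1.5 μm/px →
40×32 vectors). The correlation is a locally normalised cross-correlation:
for every shift the correlation coefficient is computed over the actual
overlap region with that region's own means and variances, which removes
the triangular bias of plain zero-padded correlation and bounds the
surface in [−1, 1]. The peak is refined per axis by a three-point Gaussian
fit (parabolic fallback for non-positive neighbours); a numerically
perfect correlation (ρ ≥ 1 − 1e−7) is an exact integer-shift match and is
reported without sub-pixel adjustment, since the data then carry no
evidence of a fractional offset. Windows with contrast below 5% of the
image standard deviation, border peaks, or flat surfaces are flagged
invalid and excluded downstream. A 3×3 median validation filter exists but
is off by default. Image-frame fields (y down) are converted to the model
frame by one documented flip/shift.

On synthetic speckle the estimator recovers uniform integer shifts exactly,
a 0.5 px shift to better than 0.01 px in the mean, and smooth fields up to
4 px with ~0.05–0.09 px RMS — comfortably inside the 0.2 px the inversion
tolerates.

## Pipette calibration

The pipette tip is a slender cylinder (immersion L = 50 μm, radius
R = 3 μm) dragged transversely through silicone oil (η = 0.934 Pa·s) at
terminal velocity. The implemented drag law is
F = 4π η L v / (ln(2L/R) + C) with C = 0.5 by default; different
slender-body treatments put slightly different constants beside the
logarithm, so C is an explicit parameter of this package (a ±0.5 change in
C moves F by ~12% at this L/R) and no particular value is attributed to
any external source. The force constant k is the zero-intercept
least-squares slope of force against deflection — the intercept is forced
because zero deflection must mean zero force — with its standard error.

## Synthetic data and what it does (not) show

Grid-level synthesis (the default, used by the tests and the acceptance
script) forward-solves the truth model, interpolates to the 40×32 lattice
centred on the load, scales each replicate to a force drawn uniformly from
the experimental 100–430 nN range, and adds i.i.d. Gaussian noise per
vector component with σ set so RMS(signal)/RMS(noise) equals the
per-measurement SNR (default 1.0, the regime of the real images where
pixel size ~1.5 μm rivals the displacements). "Ensemble relative variance
0.10" is interpreted as (vector-RMS noise of the force-normalised average)
÷ (mean displacement magnitude over the lattice sites within one window
spacing of the load); when the embryo count is not given it is calibrated
from that target, which lands at ~14–24 replicates per load case for the
default conditions — a plausible 4 replicates × a few embryos. Noise is
spatially white; real PIV noise is mildly correlated between neighbouring
windows, and real embryos vary ~10% in region sizes, neither of which the
default generator emulates. Passing recovery tests therefore demonstrate
the inversion is well-posed and unbiased under the stated noise model, not
that every systematic error of a real experiment is controlled.

Image-level synthesis (speckle + warp + PIV) exists to exercise the image
stage: band-limited Gaussian textures (grain = autocorrelation HWHM)
warped by inverse-mapped bilinear resampling so PIV should recover
+field.

## Inversion

The objective is Σᵢ |u_c(Xᵢ) − u_m(Xᵢ)|² over valid lattice sites, summed
over the load cases (each case has its own mesh, refined at its load; the
moduli are shared). Invalid or out-of-domain sites are excluded, never
imputed. Reported residual RMS is sqrt(error / n_sites) in μm per lattice
site.

Moduli are optimised as log E (they are positive and spread over
1–12 kPa) inside bounds [10 Pa, 1 MPa] by trust-region-reflective least
squares. Because the stiffness matrix is K(E) = Σ_r E_r K_r with
pre-assembled per-region blocks, each objective evaluation is one sparse
factorisation, and the modulus Jacobian is exact:
∂u/∂E_r = −K⁻¹ K_r u. Convergence uses relative cost decrease < 1e−6 or
relative step < 1e−4, capped at 200 iterations (the best point is returned
with `converged=False` beyond that). From a deliberately poor 100 Pa
initialisation the joint two-case fit on noiseless data reaches the
generating moduli exactly in ~11 iterations; the error trace is
monotone at accepted steps.

Uncertainties are linearised from the residual Jacobian at the solution
(σ_E = E·σ_logE with covariance s²(JᵀJ)⁻¹). A replicate-bootstrap
(`bootstrap_fit`) is offered as an alternative because replicate scatter
and lattice noise contribute differently; neither is labelled the
authoritative error.

Joint geometry fitting (`fit_geometry_and_moduli`) appends selected region
semi-axes to the parameter vector (default: the pellucida pair, the
boundary with the largest stiffness contrast; any subset of
midline/intermediate/pellucida may be chosen) under nesting-safe box
bounds, with finite-difference derivatives over the morphed meshes. It
needs two load cases, and it needs lattices that actually sample the
moving boundary: with the default ~1 mm field of view the radii are nearly
unidentifiable (the fit stalls in a flat, E_opaca-correlated valley),
whereas lattices spanning the pellucida edge recover a +10% perturbation
of its semi-axes to a few percent on noiseless data.

## Problem sizes and numerical defaults

Defaults throughout: 3000-node meshes, 40×32 lattices, ν = 0.3,
bounds [10 Pa, 1 MPa], ftol 1e−6, xtol 1e−4, max 200 iterations. The test
suite uses 1200–3000-node meshes and 20–50 Monte-Carlo draws per study;
one forward solve takes tens of milliseconds, a full joint fit a couple of
seconds, the entire suite a couple of minutes on one CPU.

## Known limitations

* **Near-field magnitude.** The point-load plane-stress field is
  log-singular; window-averaged model displacements at the sites nearest
  the load (~17 μm) are ~1.5 μm for a 190 nN midline force at the default
  moduli. Measured central displacements in this kind of experiment are
  typically several μm — the pipette physically occupies and damages the
  near field (finite 3 μm tip, insertion hole, local nonlinearity), which
  a linear point-force model cannot reproduce. The inversion is driven by
  the 1280-site lattice, not by the few near-singular sites, so this gap
  inflates the residual locally without visibly biasing the moduli; treat
  model values within ~1–2 window spacings of the load as qualitative.
* Linear elasticity only: no viscoelasticity, creep or plasticity — the
  analysis applies to short-time (sub-second to seconds) displacements.
* Uniform thickness and modulus per region; no 3D variation, no bending,
  no somite/notochord attachments or inter-layer slippage.
* Region geometry is idealised as concentric ellipses with a shared
  centre; per-embryo morphology variation (~10%) is not modelled by the
  default generator.
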