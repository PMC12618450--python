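# Methods

This note documents the models, numerical choices and deliberate
simplifications behind `swellanchor`, in the order the pipeline runs.

## Synthetic trabecular micro-CT

Real inputs to this kind of study are micro-CT scans of trabecular bone
(tens of µm voxels). The generator replaces them with a controlled
surrogate: Gaussian white noise smoothed by an isotropic kernel of width
`correlation_length` and thresholded at the empirical quantile that yields a
prescribed bone volume ratio. Defaults: target BVR 0.47 (the far-field value
of healthy ovine lumbar trabecular bone), bone HU band 200–1000, background
HU 0, voxel size 0.25 mm. The correlation length (default 0.6 mm) is a free
choice in the range of trabecular spacing; no quantitative descriptor of the
real microarchitecture constrains it, and none of the package's conclusions
depend on its exact value.

HU values inside the bone phase ramp linearly with distance from the marrow
phase and saturate at the top of the band after `ramp_scale = 3` correlation
lengths. The scale matters: a ramp that saturates within one correlation
length makes nearly every strut core read HU 1000, the histogram collapses
to two spikes, and the discrete material-type binning becomes trivial. With
the default, strut cores span the band and the initial interface density of
the demo lands near 1.3 g/cm^3.

What the surrogate does **not** emulate: scanner physics (noise spectra,
beam hardening, partial volume), anisotropic fabric, plate-like vs rod-like
morphology, cortical shells. Tests passing on this surrogate therefore
demonstrate correctness of the *pipeline* (segmentation thresholds, ROI
geometry, calibration, solver, remodeling dynamics), not fidelity to any
particular animal's microarchitecture.

The surgical defect is an axis-aligned cylinder (8 mm diameter, 10 mm deep
by default) with a coaxial anchor; the default anchor diameter equals the
drill diameter (press-fit). Cylinder membership is tested at voxel centers;
coordinates are 0-based `(x, y[, z])` with physical position
`origin + (index + 1/2) · voxel_size`.

## Units and material calibration

Canonical units: length mm, force N, stress/modulus MPa, density g/cm^3.
Strain energy density then comes out in mJ/mm^3 = J/cm^3, and the stimulus
`U/rho` is numerically J/g with no hidden conversion — which is what makes
the reference stimulus `k = 0.004 J/g` usable directly. The calibration's
native units (g/m^3, Pa) are converted once at the mapping boundary; a
dedicated test audits the bookkeeping by comparing elementwise SED against
the globally assembled `1/2 u^T K u − u^T f + const`.

Densities are clamped to the remodeling bounds `[0.01, 2.0] g/cm^3` already
at mapping time so the initial and evolved states obey one invariant.
Poisson's ratio defaults to 0.3 for bone and anchor alike (a conventional
value; the calibration provides none). The library default anchor modulus is
2500 MPa (glassy PMMA-class co-polymer); see the demo section for why the
packaged demo overrides it with a swollen-state value.

## Swelling model

Hygroscopic swelling is a steady-state isotropic eigenstrain
`beta_h · delta_alpha · saturation`, not a diffusion transient: uptake
completes over weeks while remodeling plays out over a much longer
characteristic time, so the interface load is effectively constant during
remodeling. The registry's three parameter sets are measured free-swelling
values for the 80/20, 85/15 and 90/10 MMA/AA ratios. Anisotropic,
viscoelastic and nonlinear swelling are out of scope.

The closed form for unconstrained swelling (`Delta d = d0 · beta_h ·
delta_alpha`) doubles as the solver's patch test: a free body under uniform
eigenstrain must develop exactly that strain with zero stress.

## Voxel FE solver

Elements are the image voxels themselves: 4-node quadrilaterals (2D) or
8-node hexahedra (3D) with 2-point Gauss quadrature, per-element isotropic
properties, and shared nodes everywhere — meshing-free and standard for
image-based bone FE. Because all elements are congruent, one unit stiffness
matrix per Poisson ratio is scaled by each element's modulus, and assembly
is a single sparse construction. The system is solved by direct sparse LU.

2D supports both plane stress and plane strain: plane stress for the
free-swelling and shrink-fit verifications (whose closed forms are plane
stress), plane strain for the transverse demo section. In-plane eigenstrain
components are applied in 2D; under plane stress this reproduces free
swelling exactly.

Stress uses the elastic strain, `sigma = C (eps − eps_hs)`, and SED is
`U = 1/2 sigma : (eps − eps_hs)`. Computing U from the *elastic* strain is a
deliberate choice where the formulation is ambiguous: it makes stress-free
swelling energy-free, so only constrained swelling generates stimulus. Free
boundary conditions are realized by minimal rigid-body constraints chosen to
be compatible with pure dilation (reference node fixed; rotation anchors on
nodes sharing its transverse coordinates), so patch tests hold to machine
precision.

**Bone–anchor interface.** The interface is tied (shared nodes), not
frictional contact: swelling keeps it in compression, and for normal
pressure transfer a tied interface is equivalent to closed frictional
contact. The friction coefficient 0.4 enters only the push-out estimate.

**Interface pressure recovery.** On the voxelized cylindrical interface the
contact normal is taken as the geometric radial direction, and each facet's
area is projected onto it, so the summed projected area approximates the
true lateral surface and the Coulomb integral is subdivision-invariant.
One-sided element-stress recovery at the staircase is systematically biased
(measured on the Lamé disc at voxel size a/40: bone side −24%, anchor side
+21%), while the two-sided average lands within ~2% of the closed form —
traction is continuous across the interface, so averaging the two one-sided
recoveries is the natural estimator and is the default (`side=` selects
one-sided variants). The analytic shrink-fit pressure for a swelling disc in
an annulus is the independent oracle; the FE value must match it within 5%
at the refined mesh, and a `mesh_convergence` helper repeats any analysis on
halved voxel sizes until the monitored peak changes by less than 5%.

## Remodeling integration

The rate law's lazy-zone boundaries are inclusive (rate exactly zero at
`(1±delta)k`), removing a measure-zero ambiguity. Forward Euler with
`dt = 0.01` and clamping advances densities; element moduli are re-mapped
from density after every window. Elements at the floor keep stiffness
`E(0.01) ≈ 59 MPa` rather than being deleted — no re-meshing, and
"complete resorption" remains a state, not a topology change. Anchor
elements never remodel. Time is the dimensionless unit implied by the
constants; no physiological calendar is claimed.

Per-step density changes are ~10^-5, so a 2% convergence criterion cannot
bind per step. The stimulus is therefore frozen over a window of
`resolve_every` Euler steps (default 100; the demo uses 1000, i.e. 10 time
units) between FE re-solves, and convergence is evaluated per window: the
run stops when the largest relative density change over a window is below
`convergence_tol = 0.02`, or every element is at a bound or in the lazy
zone. Both the window and the tolerance are configuration knobs, covering
the range of defensible readings of "iterate until changes are below 2%".

Single-element helpers (`equilibrate_constant_stimulus`,
`equilibrate_frozen_energy`) iterate to cessation: a frozen stimulus drives
the density to a bound, and frozen strain energy drives the stimulus to the
upper lazy-zone edge, with fixed point `rho = U/((1+delta)k)` when inside
the bounds. These closed-form equilibria, a dt-vs-dt/100 trajectory oracle,
and the rate-curve landmarks (`S_peak = (1+delta)k + B/2D`,
`rate_peak = B^2/4D`, `S_zero = (1+delta)k + B/D`) anchor the test suite.

## The packaged 2D demo

The demo models a plane-strain transverse section of the implanted region:
a 6 mm radius disc of heterogeneous continuum bone (synthetic image, voxel
0.15 mm, seed 7, ~5000 elements) around the press-fit 8 mm anchor, outer
boundary fully fixed — the desk-scale analogue of meshing a thin region of
interest around the drill hole and fixing its lateral faces. Geometry was
chosen so that the whole bone shell is loaded by the swelling: in larger
square domains the far corners see stimuli below the lazy zone and slowly
resorb by disuse over the run, an artifact of simulating without any
physiological background load.

Two demo parameters deserve comment:

- **Anchor modulus 100 MPa (swollen state), not the 2500 MPa glassy
  default.** The hydrated co-polymer at saturation is orders of magnitude
  softer than dry; with a glassy anchor the interface pressure reaches
  hundreds of MPa and *every* composition sits far beyond the overload
  zero-crossing, which destroys the compositional contrast the demo exists
  to show. At 100 MPa the measured 85/15 stimulus field spans
  0.0013–0.019 J/g — inside the apposition window and below the
  zero-crossing — while 90/10 (stimulus ∝ eigenstrain², ×0.26) sits near
  the lazy zone and 80/20 (×7.2) beyond the zero-crossing.
- **Domain = loaded ROI shell.** With everything loaded, the 85/15 run
  densifies the interface shell from 1.31 to 1.65 g/cm^3 with no floored
  element, converges by the 2% window criterion, and the push-out force
  strictly increases. The increase is small (+0.15%): with a soft swollen
  anchor, the anchor's own compliance dominates the series stiffness, so
  bone densification shifts the interface pressure only slightly — the sign,
  not the magnitude, is the meaningful desk-scale statement.

Directional outcomes on this geometry mirror the mechanism's predictions:
85/15 densifies most favorably; 80/20 fully resorbs the interface shell;
90/10 responds modestly (in this 2D section its mean interface density
drifts slightly *down*, since much of its stimulus falls just below the lazy
zone rather than just above it). Absolute forces and densities are not
comparable to any in vivo or commercial-solver result: this is a 2D
continuum section with a tied interface and a 1 mm thickness convention.

## BVR analysis

ROI geometry uses voxel centers and half-open radial intervals (no double
counting between adjacent shells). The interface ROI is a hollow cylinder
(default: inner radius 4 mm = anchor radius, 2 mm thick, height = defect
depth — the axial extent is a convention, as nothing pins it); far-field
ROIs are spheres of equal volume at deterministic offsets (an annulus in the
2D demo). Bone is thresholded by the HU band; the paired t-test is the
classical closed form on the paired differences, cross-checked against
scipy, with degenerate zero-variance cases handled explicitly. The
density-to-HU projection inverts the affine calibration so a remodeled FE
field can be pushed through the identical image pipeline as a scan; capped
elements project to HU ≈ 943, inside the bone band.

## Known limitations

- 2D plane-strain demo; 3D runs are supported but limited by the direct
  solver's memory at fine grids.
- Tied interface: no gap opening, no frictional sliding, no push-out
  force–displacement curve — only the Coulomb integral.
- Steady-state swelling; no uptake kinetics or polymer degradation.
- The remodeling constants are literature values for human bone; the
  simulation makes no species-specific claim.
- Without a background physiological load, regions with near-zero stimulus
  resorb by disuse; conclusions are restricted to the loaded ROI shell.
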