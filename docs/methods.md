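# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `lvflow`, in the order of the pipeline.

## Image model and phantoms

Clinical cine cMR stacks are read from DICOM; the reader requires
`PixelSpacing`, `ImagePositionPatient` and `ImageOrientationPatient`,
validates direction-cosine orthonormality to 1e-6, orders phases by
`TriggerTime` (falling back to `InstanceNumber`), and groups files into one
stack per orientation. Views are classified by the angle between a stack's
normal and the normal of the orientation holding the most slices (> 45° ⇒
long-axis); the literature distinguishes views but gives no rule, so this
deterministic convention is ours. Pixel indices are 0-based `(row, col)`
with the DICOM convention `P = IPP + col·Δcol·X̂ + row·Δrow·Ŷ`.

The phantom stack emulates the acquisition the pipeline is configured for:
0.7 mm pixels, 8 mm slice planes, 20 phases per cycle, a bright blood pool
(200) inside a darker myocardial ring (80) on background (20). The lumen
radius (22 mm at the base at ED) tapers linearly to 35% at the most apical
slice and contracts by 25% at ES with the piecewise-linear systolic blending
law. Noise is additive Gaussian with SNR defined as (lumen − myocardium)/σ;
edges are anti-aliased over one pixel so sub-pixel trace accuracy is
measurable. The generator draws from a single seeded RNG stream and writes
deterministic UIDs, so identical spec + seed yields byte-identical DICOMs.
The phantom reproduces intensity contrast, taper, motion and noise — it does
**not** contain papillary muscles, trabeculation, myocardial texture, bias
fields or wrap artifacts, so a passing Dice score bounds algorithmic error,
not clinical robustness.

## Segmentation

1. **Anisotropic diffusion** (gradient/Perona–Malik family, via SimpleITK):
   10 iterations, conductance = 10% of the intensity range, time step 0.124.
   Edge-preserving; extrema are not amplified.
2. **Fuzzy c-means** on the intensity distribution: memberships by the
   reciprocal-distance rule
   `u_ij = 1/Σ_k (‖q_i−c_j‖/‖q_i−c_k‖)^{2/(m−1)}`, centers by the
   membership-weighted centroid computed over the exact intensity histogram
   (unique values weighted by counts — identical to the per-pixel update to
   1e-9, tested). Defaults: C = 10 clusters for short-axis frames, fuzzy
   exponent m = 2 (the field-standard default; theory requires only m > 1),
   centers initialized at uniform intervals of the intensity range, stop at
   |ΔJ| < 1e-8. The objective is recorded each iteration and is
   non-increasing. There is no randomness anywhere in the pipeline
   ("seedless by construction"); ties in hard assignment break to the lowest
   cluster index. The "optimal cluster count" question is exposed as a
   diagnostic table (`cluster_count_diagnostic`: mean inter-center distance
   and candidate-lumen circularity per C), not an automatic selector,
   because no reproducible criterion exists for it.
3. **Lumen-region selection**: pixels are hard-assigned, connected regions
   of the *bright* clusters (center above the mean image intensity) are
   ranked by their minimum pixel distance to the user's ventricle-center
   hint; regions within the closest decile of that distance are kept and the
   largest wins, followed by a small morphological closing (disk radius 2).
   Proximity is measured to the region rather than its centroid because the
   myocardial ring is concentric with the lumen: same centroid, often larger
   area. No bright region within `search_radius` (15 px) raises a
   lumen-not-found error — the manual-retrace path, which on the SNR-10
   phantom affects ~2% of frames (clinical workflows report ~5%).
4. **Trace extraction**: marching squares at the 0.5 level of the largest
   component, light circular moving average (window 3), counter-clockwise
   orientation. Traces with circularity `4πA/P²` below 0.5 or centroid
   outside the central third of the image are returned as explicit
   rejections carrying the reason (thresholds are ours; the workflow they
   implement specifies the filters but no numbers).
5. **Snake refinement** on the diffused image (flag to use the original):
   `skimage.segmentation.active_contour` with α = β = 0.1, γ = 1 and
   periodic boundary. Two numerical points matter: intensities are
   normalized to [0, 1] first (raw scanner units make every step clamp at
   the maximum pixel move and oscillate), and the convergence threshold is
   tightened to 0.01 px (the stock 0.1 px stalls ~0.6 px short of the
   gradient ridge). On a noise-free disk the refined trace lands within
   0.2 px RMS of the true edge from ±3 px initializations.
6. **Smoothing**: circular moving average along the contour and a sliding
   window across adjacent slices at corresponding indices; area change stays
   below 2% at the default windows.

## Geometry

* Normalized cycle time `T ∈ [0,1]`, ED at both ends, ES at the systolic
  fraction (default 0.4 of the cycle; heart rate default 60 bpm).
* **2D**: eight keyframe wall polylines (closed traces are clipped to their
  y ≤ 0 part between the two IO crossings), resampled to a common count by
  arclength from the left IO endpoint; node positions interpolate linearly
  in T, wrapping ED→ED. Interpolated polygons are checked to stay simple at
  50 sampled phases.
* **3D**: accepted per-slice traces at one phase are mapped to patient mm,
  ordered base→apex (the tapered end is the apex), and resampled to a common
  angular count with the datum ray toward patient +x projected into each
  ring plane — a deterministic convention for circumferential
  correspondence, which the source workflow leaves unspecified. The model
  frame puts the most basal ring at z = 0 (the open IO disc) with +z toward
  the base. ED and ES surfaces are built by the identical procedure — a
  structured cylindrical quad grid split into triangles plus an apical fan
  grouped into four patches — which guarantees index-wise node/element
  correspondence. The apex point defaults to the apical-ring centroid pushed
  half an inter-ring spacing toward the apex; phantoms with a known tip pass
  it explicitly. Motion uses only ED/ES with the piecewise-linear blending
  law `s(0)=0, s(0.4)=1, s(1)=0`; both the 8-keyframe and the 2-keyframe
  laws sit behind one interface so 20-phase data drops in.
* **Lumen meshes** (mm): 2D lumens get a polar fan of P2/P1 triangles around
  an interior center (star-shaped silhouettes only — true for LV long-axis
  shapes); rectangle verification meshes use Q2/Q1 quadrilaterals. An
  earlier all-quad polar design needed collapsed cells at the center whose
  singular Jacobians defeated Gauss quadrature, so triangles are used for
  lumens even though the reference workflow meshed 2D with quadrilaterals.
  3D lumens get a structured polar (level × radial × angular) grid split
  into tetrahedra by the Freudenthal pattern, with collapsed axis/apex cells
  reduced to wedges and pyramids; conformity and positive volumes are
  test-checked. Volumes are measured by the divergence theorem with the IO
  opening capped by its flat spanning fan; areas by the shoelace formula.
  At the phantom defaults (48 points per ring, 16 rings) the surface volume
  is within 1% of the analytic value; the deficit is the inscribed-polygon
  bias, which largely cancels in ED−ES differences.

## Flow solver

Incompressible Newtonian Navier–Stokes in ALE form, SI units internally
(geometry converts mm→m; the conversion is tested):

* viscous term in stress-divergence (symmetric-gradient) form, so the
  natural IO condition is literally zero traction `σ·n = 0` and sets the
  pressure gauge (reported pressures are relative to the IO);
* wall boundary: direct kinematic velocity `v = w` (mesh velocity) at wall
  nodes — equivalent to the prescribed-displacement structural wall of the
  original formulation for imposed motion;
* interior mesh motion: harmonic (Laplace) extension of the boundary
  displacement, computed once per keyframe on the ED mesh and blended in
  time; IO nodes stay in the IO plane and slide freely within it. Element
  inversion anywhere raises immediately;
* time integration: backward Euler (default 200 steps/cycle in the library,
  coarser in the shipped studies; see below) with Picard linearization of
  convection, assembled on the end-of-step mesh with `w = Δx/Δt`. This
  discrete form transports uniform fields on a moving mesh exactly (checked
  to 1e-8), the discrete analog of geometric conservation;
* elements: Taylor-Hood (quadratic velocity / linear pressure) triangles or
  quads in 2D; equal-order P1/P1 tetrahedra with PSPG pressure stabilization
  in 3D. The stabilization vanishes against constant pressure test
  functions, so global mass conservation is exact to solver tolerance
  regardless of it. Verification: the force-driven Poiseuille channel is
  reproduced to machine precision (the quadratic profile lies in the Q2
  space), and a manufactured vortex shows L2 velocity convergence of order
  ≈ 3 (contract: ≥ 1.8);
* linear solves: sparse LU, reused across Picard iterations and time steps
  as a GMRES preconditioner (rtol 1e-12) and re-factored when that stalls —
  a pure runtime optimization, results change only within the stated
  tolerance;
* backflow stabilization at the IO during filling is available behind a
  flag and OFF by default (plain zero traction); the phantom flows
  (Re ≲ 250) do not need it. The convective CFL is reported (warning
  above 5), not enforced — implicit stepping tolerates moderate CFL;
* simulations start from rest at ED; with two or more cycles a periodicity
  diagnostic (relative L2 difference of velocity between cycle ends) is
  reported. On the 2D LV phantom the second cycle repeats the first to <1%.

No turbulence model (peak Re ~ 10³ in patients, laminar-transitional at
most), no elastic wall coupling, no valves, no prescribed velocity profiles.

## Energetics

All integrals use the discretization's own quadrature and are cross-checked
against dense brute-force oracles in the tests (≤ 0.5%). Conventions:

* vorticity-magnitude average integrates `|Ω_z|`: the defining equation is
  sometimes typeset without the absolute value, but the quantity named is
  the magnitude average (the signed average is reported separately as the
  rotational balance; both are zero-mean-flow frame-invariant). In 3D the
  package reports the volume averages of ‖Ω‖ and of the axial component,
  labelled distinctly;
* HDF sign convention: +y (2D) / +z (3D) points from apex toward base, and
  `F = ∮σ·n` with n outward from the fluid, so a positive HDF pushes blood
  toward the base. Published HDF curves use unstated signs; ours is
  documented rather than guessed. The traction integral and the
  residual-based reaction force are independent routes to the same quantity
  and agree within 1% on the piston benchmark (both are reported);
* 2D fluxes are per unit depth: Q′ in mm²/s, force in N/m. The 2D flow rate
  is the IO line integral; mass conservation makes it equal −dA/dt, exposed
  as a cross-check column;
* stroke volume `SV = V_ED − V_ES` is cross-checked against the systolic
  `∫Q dt` using the right-endpoint rule, which is the integral consistent
  with implicit stepping (exact for the piecewise-constant flux that
  linear-in-time wall motion produces);
* the volume-derivative column uses backward differences for the same
  reason; the mass-conservation metric excludes the initial rest state,
  whose flow predates any motion.

## Study configurations and problem sizes

The shipped studies are deliberately coarse so the full suite runs on one
CPU in minutes; accuracy quoted is at these sizes.

| study | mesh | steps | result |
|---|---|---|---|
| piston box 2D | h = 1 mm, ~440 tris | 20 per cycle | Q′ = W·s to 1e-13 |
| Poiseuille channel | 20 cells across H | steady | L2 error ~1e-14 |
| manufactured vortex | 8/16/32 grids | steady | order ≈ 3.0 |
| half-ellipsoid LV 3D | 12 rings × 24, h = 7 mm | 50 per cycle | SV −2.0%, peak Q −2.0% |
| long-axis LV 2D | h = 4 mm | 60 × 2 cycles | mass err < 0.1%, periodic to <1% |
| segmentation | 5 slices × 20 phases, SNR 10 | — | Dice 0.98 mean, ~2% retraces |

The half-ellipsoid deficits are geometric (inscribed polygons), not
hydrodynamic: mass conservation holds to machine precision, so SV and Q
inherit exactly the surface-volume bias.

## Known limitations

* The heart base, mitral/aortic orifices and valve dynamics are outside the
  model: one flat IO opening carries both filling and ejection, so intra-
  ventricular vortex structure near the base is not representative.
* 3D motion interpolates ED↔ES only; filling/ejection waveforms within each
  phase are not imaged kinematics but the linear law.
* Blood is Newtonian; shear-thinning effects at low shear are ignored.
* The 2D model neglects out-of-plane flow and is sensitive to the chosen
  long-axis plane.
* Segmentation assumes one bright, roughly convex blood pool per frame;
  severe trabeculation or flow voids would require the manual-retrace path
  (polyline CSV import is provided in place of an interactive GUI).
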