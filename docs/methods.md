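# Methods

`aortagrow` is a desk-scale analysis chain linking acute structural wall
stress in a dissected aorta to its subsequent growth.  It consists of a
synthetic-geometry generator, a reduced-order lumen hemodynamics model, a
forward-penalty wall-stress solver, a registration-based growth-rate
mapper, and a random-slope mixed-effects regression connecting the two
fields region by region.  This note records the models, their
assumptions, the defaults, and the numerical choices; every number quoted
here is computed by the test suite or the pipeline itself.

## Synthetic dissected aortas

Patient imaging cannot be redistributed, so all geometry is generated.
A scene is a tube of controllable radius profile (straight or an
inverted-U "candy cane": ascending segment, 180° arch, descending
segment) with

* an internal **flap**: a ruled chord surface across each cross-section
  over a prescribed arclength range, splitting the lumen into true (TL)
  and false (FL) channels.  Its edges coincide with outer-wall grid
  nodes, reproducing the non-manifold wall–flap junction of segmented
  dissections.
* circular **tears** (fenestrations) punched into the flap; only their
  hydraulic role matters, so shape is the simplest possible.  Default:
  one proximal and one distal tear of radius 5 mm.
* optional **mural thrombus**: a structured block lining part of the FL
  wall (default depth 5 mm over 60% of the FL arc).
* smooth radius perturbations (Gaussian bumps, default amplitude
  0.6 mm) so that surfaces are not perfectly cylindrical.

The centerline, section frames (parallel transport, so the tube does not
twist) and the left-subclavian surrogate landmark (end of the arch) are
generated with the scene; no centerline extraction is needed.  All
generators are pure functions of their spec, which carries the seed.

Follow-up geometries apply a circumferential stretch field
`f(s) > 0` about the analytic section centers, optionally followed by a
rigid perturbation; the growth ground truth is therefore known exactly,
which is what the registration tests rely on.

What the generator does **not** emulate: arch branch vessels as true 3-D
branches (outlets are point attachments with areas), cardiac-phase
geometry changes, flap motion, non-circular tear shapes, and image noise
or segmentation artifacts.  Passing tests therefore demonstrate the
correctness of the numerical chain on clean geometry, not robustness to
imaging artifacts.

## Structured parameterization and regions

The outer wall is resampled onto a cylinder-topology grid of **200
layers × 50 nodes**: layer j lies on the cross-section at the j-th of
200 equally spaced arclengths; the 50 nodes sit at equally spaced polar
angles about the section centroid.  Cutting planes through the arch also
intersect the far limb, so the section segments are clustered into
connected loops and only the loop nearest the centerline point is kept.
The angular origin is the projection of the global +x axis (a fixed,
deterministic convention; the nonrigid registration absorbs any residual
angular offset between time points).

Local frames: radial = outward surface normal, axial = direction to the
next layer center (last layer copies the penultimate), circumferential =
their cross product, re-orthogonalized; triads are right-handed and
orthonormal to 1e-8.  A layer's **diameter** is twice the mean
center-to-node distance (not the max chord), so non-circularity is
averaged, not tracked.

The 200 layers are partitioned into **50 regions** by rounding equally
spaced boundaries: 12 proximal regions between layer 1 and the landmark
layer, 38 descending regions from the landmark to layer 200.  With the
landmark at layer 49 every region holds exactly 4 layers.  Regions
within each block differ by at most one layer.  Layers and regions are
1-based in all file output.

## Solid wall mesh

The image-derived surface is taken as the loaded reference configuration
and extruded along per-node averaged normals: outward by the FL wall
thickness (1 mm) everywhere, and inward by TL−FL (1 mm) on the TL side,
yielding a 2 mm TL wall, a 1 mm FL wall, and flap + FL wall = intact
wall — the acute-dissection build-up.  The wall uses 4 transmural
hexahedral layers; the flap, being half as thick, uses 2, which keeps
the transmural element size uniform and lets the flap-wall junction
share distinct wall nodes (a conforming T-junction).  Thrombus is a
conforming hexahedral block attached to the inner FL wall surface, with
its transmural index oriented outward to keep element handedness
uniform.  Offsets exceeding the local section radius raise an error
naming the offending nodes.

## Reduced-order hemodynamics

The pressure boundary-condition mathematics is retained while the 3-D
flow solve is replaced by a 1-D resistive surrogate — an explicit
fidelity substitution.  Components:

* **Inlet**: steady 1/7 power-law profile; mean/peak velocity =
  2n²/((n+1)(2n+1)) = 49/60 for n = 7; either an echo peak velocity or a
  target flow (default 25 L/min ≈ 417 mL/s) fixes the other.
* **Total resistance** = systolic pressure / systolic flow
  (mmHg·min/L).
* **Outlets**: conductance proportional to branch cross-sectional area
  (the Murray's-law flow split; literal "resistance ∝ area" would send
  more flow through smaller branches), recombining in parallel to the
  total exactly.
* **Network**: TL and FL are chains of Poiseuille segments with
  effective radii from the local lumen areas (FL area from the
  circular-segment fraction of the flap chord); tears couple the chains
  as short Poiseuille orifices of the tear radius and the flap thickness
  as length; outlets drain to a zero reference.  Kirchhoff conservation
  holds to the linear-solver tolerance.  A tearless FL is hydraulically
  stagnant and is assigned the TL pressure at its proximal end, with a
  warning.
* **WSS** per segment is 4μQ/(πr³); blood μ = 0.004 Pa·s,
  ρ = 1060 kg/m³ (standard values, configurable; density is unused in
  the steady resistive model but kept in the interface).
* **Calibration**: bisection on a scale factor of the total resistance
  in [0.1, 10] until the simulated arch pressure (mean TL pressure over
  the stations proximal to the landmark — the arch region is not
  otherwise defined) matches the measured systolic pressure within 2%
  MAPE.  On these smooth synthetic scenes the internal drop is small
  (fractions of a mmHg), so the tuned resistance stays near the
  calculated one; patient-specific image-based anatomies, with their
  tortuosity and stenoses, are where large adjustments arise.

## Forward-penalty wall stress

A thin pressurized wall is approximately statically determinate: its
stress balances the luminal pressure nearly independently of the
constitutive law.  The solver therefore assigns an artificially stiff
isotropic material — Young's modulus 5×10⁵ kPa for wall and flap,
2.5×10⁴ kPa for thrombus (20:1) — to the image-derived geometry and
solves small-strain elastostatics; the deformation is negligible
(≲10⁻² mm at 120 mmHg on the benchmark shell), so the input geometry is
simultaneously the deformed configuration.

Numerics: 8-node hexahedra, full 2×2×2 Gauss integration with a
mean-dilatation (B-bar) volumetric treatment; Poisson ratio defaults to
0.3 and is configurable up to 0.49 (the B-bar treatment guards against
volumetric locking; the sensitivity suite verifies that the choice is
immaterial for stress).  Tractions are facet pressures applied along
undeformed normals with consistent bilinear quad integration; facet
orientation is fixed by a stored lumen-to-solid hint, and flap facets are
loaded from both lumens with their own pressures.  Ends: inlet/outlet
rim rings clamped (default; the pipeline excludes the two structured
layers nearest each end from the stress region averages, where the
clamped rims perturb the field), or
axial-only restraint with a 3-2-1 pin for the closed-form cylinder
benchmark.  Stresses are recovered as element volume averages
extrapolated to nodes by volume weighting; reported invariants are the
maximum principal and von Mises stresses.

Verification: a single-element patch test is exact to 1e-8; the
pressurized shell (r_i = 14 mm, t = 2 mm, 120 mmHg) reproduces the
thin-wall estimate P·r_i/t and the Lamé profile within 5%; uniform
stiffness rescaling leaves the stress field unchanged to machine
precision while halving displacements when doubling stiffness; ±50%
single-region stiffness perturbations (TL wall, FL wall, flap, thrombus)
change the max-principal field by well under 10% MAPE (MAPE taken over
nodes above 5% of the field maximum, to avoid near-zero denominators in
unloaded corners); halving the element size changes the peak von Mises
by under 2% (meshes coarser than 32 circumferential × 24 axial are
pre-asymptotic for this check).

## Growth-rate mapping

Rigid alignment is iterative closest point with the SVD (Kabsch) update,
terminating when the average change of rotation and translation over the
three most recent iterations falls below 1e-4 / 5e-4.  Nearest-neighbour
queries go through a k-d tree (deterministic lowest-index tie-breaks).
An optional fallback tries 30° initial rotations about each coordinate
axis and keeps the result with the smallest mean residual — the remedy
for gross misalignment.  Note that ICP on near-axisymmetric tubes can
converge to an axially slid pose with the correct rotation; the
registration stage absorbs such residual sliding.

Nonrigid matching minimizes

    cost(μ) = D_varifold(Φ(T), S)/σ² + Σ_kl μ_kᵀ K_R(λ_k, λ_l) μ_l

with σ = 1 and Gaussian kernels of width 20 mm for both the data term
(K_W) and the deformation (K_R).  D is the **full squared varifold
distance** ⟨T,T⟩ − 2⟨T,S⟩ + ⟨S,S⟩ with squared-cosine orientation
weighting and facet-area weights — the cross term alone has no minimum
at coincidence.  The deformation is a single-step kernel displacement
field u(x) = Σ_k K_R(x, λ_k) μ_k on control points λ placed on a regular
grid (spacing = kernel width) within one spacing of the surface; this
preserves the cost structure of control-point flow frameworks at desk
scale but is not a geodesic flow and carries no diffeomorphism
guarantee (adequate for the modest, smooth deformations of follow-up
aortas; the uniform-dilation benchmark stays exact up to 45% dilation).

Optimization is L-BFGS with analytic gradients (verified against finite
differences to 1e-8).  Three performance/conditioning choices matter:
the data term runs on a decimated copy of the structured grid (every 4th
layer, every 2nd node — spacing ≈ 4 mm, far below the 20 mm kernels)
while the fitted field is applied to all 10 000 nodes; the kernel blocks
run in float32 (gradient noise ~1e-6 relative, below the stopping
tolerance), with an early exit when the surfaces already coincide at the
float noise floor; and the momenta are optimized in the
Cholesky-whitened variable ν = Lᵀμ (K_R(λ,λ) = LLᵀ), which turns the
kernel energy into |ν|² and removes the severe ill-conditioning of the
raw momentum parameterization (without it the optimizer stalls on
arched geometries).  Default iteration cap 150; a capped run is flagged
in the returned diagnostics, not raised.

Growth rate: with node-to-node correspondence from the deformed
template, the circumferential stretch at each node is the ratio of
central-difference arc elements along the circumferential grid
direction (the in-surface deformation gradient component in the
template's local frame — a deterministic stand-in for re-running the
displacement through a structural solve); the growth rate is
100·ln(stretch)/years, negative where the aorta shrinks.  Degenerate
patches are flagged invalid and excluded from region averages.  The
end-to-end benchmark (arched, tapered, bumpy aorta; sigmoidal stretch
up to 1.25; 3° + 3 mm rigid perturbation; ICP + nonrigid + strain)
recovers the prescribed field with a mean absolute region-averaged
error below 0.1 %/year — the acceptance bound is 0.5 %/year.

## Region tables and statistics

Per patient, stress (max principal, kPa), WSS (Pa), pressure (mmHg) and
growth rate (%/year) are transferred to the structured surface by
nearest-node assignment after alignment, then averaged over the 38
descending regions.  Local thrombus is present at a node when the
distance to the nearest thrombus mesh node is below the node's local
radius (distance to its layer center); a region is thrombus-occupied
(Tb = 1) when its mean presence strictly exceeds 0.5.  Note the
distance rule is deliberately coarse: with a 15 mm radius it marks
nodes up to arccos(r_t/2r_n) ≈ 1.1 rad beyond a mural thrombus edge —
the tests assert exactly this analytic margin.

The cohort model for growth rate GR in region i of patient m with
predictor x (stress; alternatively WSS, pressure, or Tb, plus optional
quadratic or follow-up-time fixed terms) is

    GR_im = β₀ + β₁ x_im + b0_m + b1_m x_im + ε_im,

with independent random effects b0_m ~ N(0, sd_b0²), b1_m ~ N(0, sd_b1²)
(diagonal covariance — the reported quantities are separate SDs with no
correlation parameter) and residual ε ~ N(0, sd_eps²).  Estimation is
direct maximum likelihood: β is profiled out by GLS per evaluation and
the marginal likelihood optimized over log-SDs (positivity enforced;
SD → 0 solutions surface as boundary flags).  Per-group covariance
solves use Cholesky factorizations of the 38×38 marginal covariances.
BLUPs are D Zᵀ V⁻¹ r.  AIC/BIC use the ML log-likelihood with
k = p + 3 parameters.  The implementation is cross-checked against an
independent mixed-model fitter in the test suite (it attains equal or
higher likelihood; generic optimizers struggle with the raw kPa scale).

Inference: the fixed-slope test is F = (β̂₁/SE)² with **Satterthwaite
denominator degrees of freedom** by default (gradient of Var(β̂₁) with
respect to the variance parameters against the observed information).
Residual df (n − p − 2·n_groups) is available for compatibility with
common commercial defaults, but with 9 patients and a genuine random
slope it is badly anti-conservative: the effective information about a
between-patient slope is ~8 df, not ~320.  Fixed-effect CIs use t
quantiles at the same df.  SD confidence intervals are
profile-likelihood intervals (bound where the profiled deviance rises by
χ²₁,0.95), which are right-skewed as variance-component intervals should
be; a lower bound that runs into zero is reported as 0.

Calibration (Monte-Carlo, part of the acceptance suite): with the
cohort presets β₁ = 0.095 %/(yr·kPa), sd_b1 = 0.13, sd_b0 = 27.8, the
mean of 200 replicate estimates is within 2 Monte-Carlo SEs of the
truth, slope-CI coverage lies in [0.90, 0.99], and the F-test type-I
error over 500 null replicates is within 3 binomial SDs of 5%.

Cohort generator defaults: β₀ = 0 %/yr and sd_eps = 10 %/yr are package
choices (neither is pinned down by the reported estimates; 10 %/yr is
the same order as the region-level variability the random-effect SDs
imply), and region stresses are drawn Gamma(mean 300 kPa, SD 150 kPa) —
strictly positive, right-skewed, centred on typical dissected-wall
stress magnitudes.

## Pipeline

`run_pipeline` chains the stages per patient: scene → calibrated
network pressures → solid mesh and penalty stress → generative growth
field driven by the patient's own region-averaged stress (Eq. above,
with patient effects drawn once per cohort) → follow-up geometry with a
rigid perturbation → ICP + nonrigid registration → growth map → region
table; then cohort-level mixed-model fits (stress/WSS/pressure/thrombus
predictors, quadratic and follow-up variants), per-patient Pearson
correlations, the TL/FL paired pressure test, the calibration report,
and follow-up duration statistics (365.25 days/year; percentiles by
linear interpolation — the quartiles depend on that convention).  The
nine-patient clinical scalars (admission pressures, systolic flows, CTA
dates, thrombus status) are the default patient records.  Every run is
a pure function of (config, seed): artifacts are stamped with a config
hash and reruns are bit-identical.

Because the generative model places part of its residual (sd_eps) at
single-region (~8 mm) spatial scale, beneath the 20 mm registration
kernels, the measured growth maps are a smoothed version of the injected
truth; the systematic stress-driven component survives (it varies at
centimetre scale) while the sub-kernel noise is attenuated.  This is the
intended behaviour of a smooth deformation model, and it is why
region-level measured-vs-true discrepancies of order sd_eps coexist with
accurate recovery of smooth prescribed fields.

Default problem sizes — scene grids of 64×32 (pipeline) with solid
meshes of ~10–25k hexahedra, decimated registration data terms, and
9-patient cohorts — were chosen so a full pipeline run completes in
minutes on a single core; resolutions are configurable upward, and the
mesh-independence and recovery benchmarks document the attendant
numerical error at the defaults.

## Known limitations

* The hemodynamic surrogate has no inertia, turbulence, pulsatility or
  secondary flow; WSS magnitudes are Poiseuille estimates, and TL/FL
  pressure differences hinge on the simple tear-orifice model.
* The penalty stress field is transmurally averaged in spirit: no
  prestress, residual stress, or hyperelasticity; flap bending stiffness
  at 1 mm thickness is resolution-limited.
* The single-step kernel deformation is not diffeomorphic; very large or
  highly localized growth (scales below the 20 mm kernels) is smoothed.
* ICP can slide along near-axisymmetric geometry; the nonrigid stage
  compensates, but rigid-transform parameters themselves are only
  identified up to such symmetries.
* Mixed-model inference assumes Gaussian effects and independent
  regions; spatial autocorrelation between neighbouring regions is not
  modelled (the paper-style region averaging is the only decorrelation).
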