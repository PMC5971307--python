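# Methods

`ivcsim` simulates the isovolumic contraction (IVC) of an idealised human
left ventricle (LV) with a quasi-static nonlinear finite-element model, to
quantify how the transmural gradients in electromechanical delay (EMD) and
myocyte shortening velocity (MSV) shape the intraventricular pressure rise.
This note records the model, its assumptions, the numerical machinery and
the deliberate design choices.

## Geometry and mesh

The LV wall is bounded by two truncated ellipsoids of revolution about the
z axis. Defaults: inner semi-axes 30/30/65 mm, truncation at the equatorial
plane (z = 0, the "base"), uniform 9 mm wall (the outer surface offsets
both semi-axes by the thickness, which makes the inter-surface distance
along parameter rays exactly 9 mm). These dimensions put the end-diastolic
(ED) cavity volume at 122.5 ml, the physiological target the geometry is
defined by. The wall is meshed into 7 transmural layers of trilinear
hexahedra, `n_circ` sectors x `n_long` apex-to-base strips per layer
(defaults 12 x 6, 504 elements); the apex strip uses collapsed
(wedge-degenerate) hexahedra. Because a coarse polygonal surface inscribes
the ellipsoid and under-represents the enclosed volume, the mesh is scaled
isotropically after construction so its *discrete* cavity volume equals the
analytic value (`volume_match`, a ~2% scale at the default resolution,
vanishing under refinement). The geometric quantity the physiology
constrains is the ED volume, so the discrete model honours it exactly.

Element centroid depths are measured as shortest distances to the
*triangulated* endo-/epicardial surfaces (distances to the smooth
ellipsoids would be biased near the apex where the chords sag by ~0.5 mm).
The depth fraction of layer k sits near (k - 1/2)/7.

Muscle fibres lie in the local layer surface at a helix angle to the
circumferential direction ramping linearly from +60 deg (layer 1,
subendocardial) to -60 deg (layer 7, subepicardial), constant per layer.

## Passive myocardium

Transversely isotropic hyperelastic energy

    W = a1 (I1b - 3) + a2 (I1b - 3)^2 + a3 (I1b - 3)^3
      + b1 (I4 - 1)^2 + b2 (I4 - 1)^4 + kappa/2 (J - 1)^2

with I1b = J^(-2/3) I1 the isochoric first invariant of C = F^T F,
I4 = a0.C.a0 the squared fibre stretch, and J = det F. Coefficients
(identified from planar biaxial data): a1 = 0.347, a2 = 13.438,
a3 = 48.846, b1 = 0.436, b2 = 27.692 kPa. Because passive myocardium is
viscoelastic and stiffens at beat-rate strain rates, all five constants are
multiplied by a rate factor of 6 before simulation (`apply_rate_factor`);
the factor is never applied during constitutive fitting.

Incompressibility is enforced by the quadratic volumetric penalty with
kappa = 1000 kPa (>> a1). Raising kappa to 4000 kPa changed the control
IVC metrics by < 0.3%, so the default is kept. The fibre term acts on the
full (not isochoric) I4 — the standard choice for fibre reinforcement; the
two coincide at J = 1 and |J - 1| stays at the percent level or below in
all runs.

## Active fibre contraction

Contracting myocytes occupy 80% of each element's volume and add a
rank-one Cauchy stress along the deformed fibre direction f:

    sigma_active = vf * E0 * exp(eps) * (exp(eps) - 1) * (f x f),  eps > 0

with E0 = 200 kPa and zero stiffness in compression (eps <= 0). eps is the
logarithmic *elastic* fibre strain measured from the shrinking natural
length: eps = ln(lambda_f) - ln(lambda_f_ED) - eps_a(t). The ED reference
lambda_f_ED makes the fibres stress-free when they activate (they are
inert during filling, so their natural length at activation is their ED
length). The prescribed contraction eps_a(t) follows *linear shortening of
the myocyte length* at fractional rate v (the MSV): L/L0 = 1 - v (t - t_on),
hence eps_a = ln(1 - v (t - t_on)) — equal to -v dt to first order but
accelerating late in systole, which is what places (dp/dt)max at the end
of IVC. A safety cap at eps_a = -0.25 exists but is never reached within
the simulated window.

## Activation boundary conditions

Electrical excitation starts on the entire endocardial surface at t = 0
and conducts transmurally at 0.47 mm/ms; an element's activation time is
its centroid depth over that velocity. EMD decreases linearly with depth
at (47 - 28)/9 = 2.1 ms/mm (canine transmural measurements referred to a
9 mm wall); the gradient is applied per mm of centroid depth rather than
re-normalised to the local discrete wall thickness, which is what makes
the conduction delay and the EMD gradient cancel: control mechanical
onsets span < 0.2 ms. MSV doubles linearly in depth fraction from endo-
to epicardium. The scenarios:

| scenario    | EMD          | MSV                  | electrical activation |
|-------------|--------------|----------------------|-----------------------|
| control     | gradient     | gradient             | endocardial           |
| const_emd   | 47 ms flat   | gradient             | endocardial           |
| const_msv   | gradient     | endocardial flat     | endocardial           |
| const_both  | 47 ms flat   | endocardial flat     | endocardial           |
| intramural  | gradient     | gradient             | inner half at t = 0   |

The intramural variant emulates species with intramural Purkinje fibres:
every element with depth fraction <= 0.5 depolarises at t = 0 and
conduction continues outward from the midwall.

## Phases and the isovolumic constraint

Basal-plane nodes are fixed. The ED geometry is not stress-free, so the
zero-pressure reference is recovered first by the backward-displacement
fixed point X <- X + (X_ED - (X + u(X))), where u(X) inflates candidate X
to the ED pressure (1.3 kPa) with purely passive material; convergence is
declared at <= 0.05 mm maximum nodal mismatch (3 iterations at default
resolution; unloaded cavity volume ~107 ml). Filling then inflates the
unloaded mesh back to 1.3 kPa with a follower pressure load.

During IVC the cavity volume is constrained to its ED value with the
cavity pressure as the Lagrange multiplier of the single scalar constraint
V(u) = V_ED, solved together with the displacements in a bordered Newton
system. For an enclosed fluid the nodal pressure load is exactly
p dV/du, so this is mechanically identical to filling the cavity with an
incompressible fluid. V(u) is evaluated by divergence-theorem quadrature
over the deformed endocardial faces plus a triangle-fan cap on the basal
ring (exact under rigid motion). Time marches in 1 ms steps until the
pressure reaches the diastolic aortic value (10.7 kPa) or 220 ms elapse;
the latent period before the earliest onset is skipped analytically (the
state cannot change). Volume drift over a run stays below 1e-9 relative.

## Calibration and metrics

The endocardial shortening rate (MSV scale) is the single calibrated
parameter: secant iteration in log-scale drives the control IVC duration
to 60 +/- 0.5 ms (monotone decreasing objective; an expansion step doubles
the scale if aortic pressure is never reached). The calibrated scale
(~1.86e-3 /ms) is reused by every scenario; homogenised-MSV scenarios
prescribe it uniformly.

IVC duration is measured from the onset of pressure rise (p exceeding
p_ED + 0.05 kPa) to p = 10.7 kPa by linear interpolation on the 1 ms
trace; dp/dt by central differences over the IVC window without smoothing
(the traces are noise-free), converted at 7.50062 mmHg/kPa. Two per-layer
stress histories are recorded as volume-weighted means: the *total* tissue
Cauchy stress resolved along the deformed fibre direction, and the *active
myocyte tension* of the contraction law (zero before activation). The
transmural end-IVC comparisons — subepicardial exceeding subendocardial
tension, and the control wall showing the flattest 20-80% depth profile —
are made on the myocyte tension, the quantity whose transmural uniformity
the synchronisation argument concerns; the passive background stress would
otherwise dominate the spread.

## Numerics

- Total-Lagrangian trilinear hexahedra with selective reduced integration:
  deviatoric + active stress at 2x2x2 Gauss points, volumetric penalty at
  the element centre (prevents volumetric locking).
- Consistent tangents by complex-step differentiation of the first Piola
  stress (dP/dF from 9 batched imaginary perturbations, exact to machine
  precision); load stiffness from the cavity-volume Hessian, which is
  obtained exactly because V is a cubic polynomial in the coordinates.
- Modified Newton with lazy refactorisation: the factorised (bordered)
  Jacobian is reused while the residual contracts by at least a factor of
  two per iteration and refreshed otherwise; residuals are always exact.
  Convergence: relative force residual < 1e-6 and relative volume
  constraint < 1e-8.
- Filling uses 8 incremental follower-pressure substeps with automatic
  bisection on failure; IVC steps start from a linear-extrapolation
  predictor.

## Synthetic biaxial data and parameter recovery

The constitutive-fitting stage is exercised on synthetic planar-biaxial
records: five stretch ratios (1:1, 1:0.75, 0.75:1, 1:0.5, 0.5:1), 20
samples per path up to stretch 1.10, additive Gaussian stress noise of
0.1 kPa, seeded. Stresses come from the closed-form incompressible
membrane solution (traction-free thickness direction eliminates the
hydrostatic term). The generator emulates the protocol shape and noise
level of sheet biaxial testing but not its real-data pathologies — no
preconditioning hysteresis, fibre-angle misalignment, shear coupling or
heteroscedastic load-cell error — so a successful recovery demonstrates
the estimator's correctness, not robustness to experimental artefacts.
Recovery uses bounded (non-negative) trust-region least squares; datasets
whose fibre direction is never stretched are rejected as unidentifiable.

## Problem sizes

Default runs use the 504-element mesh (1752 displacement dofs): a full
scenario simulation takes ~45 s and the five-scenario calibrated suite
~6 min on one CPU. Control metrics are mesh-converged at this size: at
16 x 8 x 7 (896 elements) the calibrated control (dp/dt)max changes by
~0.1% and IVC duration by < 0.1%.

## Limitations

- Idealised axisymmetric geometry; no right ventricle, papillary muscles
  or pericardium; rigid basal fixation exaggerates basal constraint.
- Quasi-static: no inertia; viscoelasticity reduced to the scalar rate
  factor on the passive constants.
- Transverse isotropy only (no sheet orthotropy); near-incompressibility
  by penalty rather than exact incompressibility.
- Prescribed kinematic activation: no electrophysiology, length- or
  velocity-dependent active tension, or force-calcium coupling; ejection
  and filling hemodynamics outside the ED-pressure step are out of scope.
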