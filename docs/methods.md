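# Methods

## Problem

Non-contact tonometry (NCT) estimates intraocular pressure (IOP) by firing
an air jet at the cornea and reading the deformation. Classical devices
read the IOP at the *first applanation* instant — when the central cornea
becomes flat — but that instant confounds the IOP with corneal stiffness
and central corneal thickness (CCT). The method implemented here replaces
the applanation reading with an *energetic* one: during the pulse, the work
done by the jet on the anterior corneal surface grows while the work
previously stored there by the IOP is given back; the instant at which the
two work curves are equal coincides with the maximum inward velocity of
the corneal apex, a quantity the device's camera measures directly.
Simulation across corneal stiffnesses, thicknesses and pressures shows that
this instant depends on the IOP but (to good approximation) not on the
cornea's material or thickness, which makes it the basis of a
material-independent estimate, the **wIOP**.

The estimator itself is a quartic polynomial in the maximum-velocity time,
obtained by composing two quadratic calibrations:

* Eq. A (pressurization): `IOP = a5·W0² + b5·W0 + c5` — IOP as a function
  of the *initial work of the IOP* `W0`, the work the cavity pressure does
  on the anterior corneal surface while inflating the eye from its
  stress-free (zero-pressure) configuration;
* Eq. B (timing): `W0 = a6·t² + b6·t + c6` — the initial work as a
  function of the maximum-apex-velocity time `t` (measured from puff
  onset).

`wIOP(t) = Eq.A(Eq.B(t))` expands exactly into a quartic; the package ships
the published coefficients as the default calibration and can re-derive its
own from a sweep.

## Reduced-order eye model

The full-physics reference for this methodology is a 3-D fluid–structure
interaction model (hexahedral solid eye + CFD air domain) that costs ~48 h
per case on a workstation. This package deliberately replaces it with a
desk-scale axisymmetric reduction whose purpose is the *energy-balance
structure*, not CFD fidelity:

* **Geometry.** A meridian from the corneal apex to the scleral equator,
  revolved about the anterior–posterior (y) axis: spherical corneal arc
  (anterior radius 7.7 mm, diameter 11.5 mm), a 1 mm limbal band, and a
  scleral arc (radius 12 mm) clamped at the equator. These dimensions are
  conventions (configurable); only CCT is varied by the study design. The
  discretized surface is the anterior surface; thickness is a nodal field,
  so CCT changes do not move nodes.
* **Kinematics.** Each meridian segment, revolved, is an incompressible
  plane-stress membrane frustum with principal stretches
  `λ_s` (meridional) and `λ_θ` (circumferential), `λ_n = 1/(λ_s λ_θ)`.
* **Constitutive laws.** Holzapfel–Gasser–Ogden for cornea and limbus:
  `ψ = C10(Ī1−3) + k1/(2k2) Σ_i [exp(k2(Īi−1)²)−1]`, fibres tension-only.
  In the axisymmetric reduction the cornea's two orthogonal (nasal-temporal
  / superior-inferior) families map to one meridional plus one
  circumferential family; the limbus keeps a single circumferential family.
  The sclera is Neo-Hookean. Scleral `C10 = 0.3 MPa` and limbal parameters
  (= corneal) are conventions chosen from the physiological stiffness
  ordering sclera ≫ cornea matrix; they are not printed in the study design.
* **Bending regularization.** A pure membrane wrinkles under the
  compressive stresses of central indentation, so each interior node
  carries a turning-angle spring scaled by the flexural rigidity
  `E_b t³/12` with `E_b = 6 C10` (the matrix Young's-modulus scale). This
  is the smallest shell ingredient that yields a well-posed applanation
  response; it is a regularization, not a calibrated shell model.
* **Humors.** A hydrostatic fluid cavity: spatially uniform pressure acting
  on the enclosed volume through its analytic gradient, with the stiff
  linear law `P = IOP + K_f (V0−V)/V0`, `K_f = 20 MPa`. At this stiffness
  the cavity volume changes by ≲0.01% during loading — an effectively
  incompressible humor whose pressure rise is set by scleral compliance,
  which is the physical regime (raising `K_f` further changes results only
  in the fourth digit).
* **Units.** g–mm–ms–MPa–mJ internally (the consistent system in which the
  study's printed units appear); pressures cross the API in mmHg
  (1 mmHg = 1.33322·10⁻⁴ MPa).

### Pipeline per simulated eye

1. **Zero-pressure recovery.** The measured geometry is the *loaded* state,
   so the stress-free configuration is recovered by the classic fixed-point
   pull-back `X0 ← X0 − (inflate(X0, IOP) − X_ref)`, each inflation being a
   quasi-static ramp. Round-trip tolerance: 1 µm–1 mm scale, default
   `1e-3 mm` max nodal error; the residual decreases monotonically in
   well-posed cases and three consecutive increases abort with the history.
2. **Pressurization.** Quasi-static equilibria at linearly ramped pressure
   (8 increments), each solved by minimizing total potential energy with
   analytic gradients (L-BFGS; adaptive pressure-step bisection for
   strongly nonlinear parameter sets). The trapezoidal work of the IOP on
   the anterior corneal nodes over these increments defines `W0`. A
   quasi-static solve has zero residual kinetic energy by construction.
3. **Transient loading.** Explicit velocity-Verlet with lumped masses and a
   CFL-based stable step re-estimated during the run; a short damped settle
   precedes load onset, and damping is zero while the load acts, so the
   energy balance closes without dissipation.

### Loading scenarios

* **Falling mass.** A rigid 2.02 g cube (side 1.5 mm) dropped from 8 mm
  above the apex, coupled through a frictionless penalty contact
  (equal-area circular footprint; stiffness such that stored contact energy
  stays below 1% of the transferred energy; penetration beyond 10% of CCT
  aborts the run as a time-step error).
* **Air puff.** A prescribed axisymmetric pressure field standing in for
  the jet: Gaussian footprint `exp(−(r/1.5 mm)²)`, `sin²` temporal pulse
  over 30 ms, peak 100 mmHg ≈ 13 kPa. The amplitude is a convention chosen
  so that the work curves exhibit the two intersection points in *every*
  row of the sixteen-case design (the structure the method rests on); it
  sits inside the measured on-cornea pressure range of clinical devices and
  produces apex indentations of 1–2 mm. An optional deformation-coupling
  factor can modulate the local pressure with surface recession; it
  defaults to off and is not used by the shipped calibration.
  Output sampling defaults to 140 frames per 30 ms, the camera rate of the
  clinical device.

## Work bookkeeping

All work series are accumulated nodally with the trapezoidal rule over
output increments (`W = Σ_j Σ_i ½(F_i^j + F_i^{j−1})(u_i^j − u_i^{j−1})`),
restricted to the anterior corneal node set (the surface the camera
tracks), signed along y. The nodal force of a pressure channel is the
pressure times the node's *current projected* area: on a curved surface the
y-force of a pressure is `P·a_i·n_y`, and using the projected area is what
makes the work channels close against the energy ledger (for a flat patch
it coincides with the plain area). Convergence is second order in the
output increment, verified against closed forms and fine-increment oracles.

Intersections of the two work curves are located by linear interpolation
between output increments; the first crossing after load onset is the
primary (inward-phase) event, the second (rebound) crossing is reported but
unused.

## Event detection

* **Maximum apex velocity**: global inward-velocity maximum, refined by a
  least-squares parabola over ±8 samples around the discrete peak (the
  physiological peak is flat, so a windowed fit localises it far better
  than a 3-point refinement under noise); measured traces are pre-smoothed
  with a 3-sample
  moving average, simulated traces are used raw. Traces whose maximum sits
  on the boundary are rejected explicitly.
* **First applanation**: the best-fit curvature of the central 3 mm chord
  of the anterior profile (axisymmetric even fit `y = c0 + c2 r²`) falls
  below 1 m⁻¹ — a documented convention; the device's own detector is
  proprietary. The threshold crossing is interpolated sub-increment.

## Calibration and estimation

The sixteen-case design varies corneal `C10, k1, k2` (rows 6–13), IOP
10–30 mmHg (rows 1–5) and CCT 484–600 µm (rows 14–16) around the baseline
(C10 = 0.045 MPa, k1 = 0.027 MPa, k2 = 180, IOP 15 mmHg, CCT 558 µm).
Both quadratics are ordinary least squares fitted on the IOP series (the
subset across which IOP actually varies; configurable), with
`R² = 1 − SS_res/SS_tot`; the quartic is the exact algebraic composition.
The published quartic is shipped as the default calibration; since the
published fitted time range is not printed, a nominal 5–11 ms window (the
physiological range of maximum-velocity times) flags extrapolation without
refusing it.

In the desk-scale reproduction the re-derived pressurization intercept
lands near the published one (≈6.0 vs 6.18 mmHg) while the remaining
coefficients differ — expected, since the reduced model's compliance and
jet differ from the full-physics reference; the acceptance surface is the
composition algebra and the qualitative relations, not the printed
regression coefficients.

## Synthetic traces

The trace generator emulates the morphology of device recordings: zero
velocity before motion onset, a C¹ `sin²` rise through the applanation
instant to the velocity peak at `t_app + lag`, a cosine decay through zero
at the highest concavity, an outward (negative) lobe, plus additive
Gaussian noise. Healthy vs keratoconic-like archetypes differ only in peak
amplitude (0.11 vs 0.16 mm/ms) and lag distribution (1.5–3.5 vs 1–5 ms);
they exercise batch behaviour and are not claims of clinical realism. The
generator returns its ground truth, and all randomness is seeded.
What passing tests on these fixtures shows is that the *analysis* side
(event detection, estimation, batch I/O) is correct; it says nothing about
how faithfully a real Scheimpflug trace is modelled.

## Numerical choices and degenerate inputs

* Static solves accept an equilibrium when the residual force falls below
  10⁻³ of the applied pressure-force scale (hard failure beyond 10⁻²),
  with up to four L-BFGS restarts and six levels of pressure-step
  bisection.
* The membrane kernel caps the fibre exponent at 200 and continues the
  energy linearly in the exponent beyond it (gradient stays exact), so
  equilibrium searches probing unphysical trial states are repelled rather
  than overflowing; the 3-D constitutive API instead raises a material
  instability error beyond `k2(Ī−1)² > 700`.
* Zero IOP short-circuits both pressurization (zero displacement) and
  pull-back (identity); zero peak pressure holds equilibrium; a cube with
  zero gravity never makes contact.
* Explicit stability: the step is the minimum of the membrane CFL estimate
  (tangent moduli differenced from the analytic first derivatives), a
  bending estimate, and penalty/cavity stiffness bounds, with safety 0.25,
  re-estimated every 500 steps.
* Simulation timeline: the transient starts from the statically
  pressurized state with a ~4 ms damped settle and load onset at 5 ms;
  all event times are reported relative to load onset, so the compressed
  timeline is observationally equivalent to a longer hold.

## Problem sizes

Default mesh resolution 1 gives 41 meridian nodes (20 corneal elements);
a puff transient integrates ~25k explicit steps in ~10 s, the full
sixteen-case sweep (zero-pressure recovery + pressurization + transient
per case) runs in ~6 minutes, and the falling-mass run in ~15 s. Doubling
the resolution changes the anterior-area estimate by <0.5% and the
headline event times by well under the output increment spacing used to
assess them.

## Known limitations

* **Through-thickness energy pathway.** In the membrane reduction the
  cornea transmits indentation energy to the fluid and sclera rather than
  storing it through-thickness; the full-physics reference reports the
  corneal internal-energy change close to the (sign-reversed) IOP work,
  whereas here that ratio is ~0.1–0.3. Consequently the work value at the
  intersection sits near 0.35·W0 instead of the reported ≈0.5·W0. The
  *timing* structure — which is what the estimator uses — is insensitive to
  this: the intersection time still tracks the maximum-velocity instant and
  stays material/CCT-independent.
* **Intersection vs maximum-velocity timing.** The work-curve crossing
  tracks the apex maximum-velocity instant, but the coincidence is
  approximate and its apparent precision depends on how the peak of a
  plateau-topped, ringing velocity curve is defined. In the mass scenario
  the smoothing-based detector places the peak on the crossing, while the
  raw sample maximum and the cube's own velocity maximum sit 0.7–0.9 ms
  earlier — at that plateau flatness the instant is not physically defined
  to better than ~1 ms. In the air-puff scenario the baseline gap is
  ~0.5 ms (two to three camera frames), growing toward the extremes of the
  IOP series where the crossing drifts later than the velocity peak. The
  calibration therefore regresses on the maximum-velocity time directly —
  the quantity the device measures — and the estimator never needs the
  crossing itself.
* The jet is a prescribed pressure field: no nozzle flow, turbulence, or
  true deformation-coupled stagnation field; whole-eye retraction and
  viscoelasticity are absent; geometries are axisymmetric (no keratoconus).
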