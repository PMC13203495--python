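# Methods

`nestedfsi` models the mechanical protection of the fetal brain during
maternal convulsive (seizure) motion as three nested fluid–structure
interaction layers: the uterine wall enclosing amniotic fluid, the amniotic
fluid enclosing the fetal body, and — inside the fetal head — the skull,
cerebrospinal fluid (CSF) and brain.  The package synthesises its own inputs
(anatomy and seizure kinematics), integrates the coupled system explicitly,
and reports the cushioning observables: baseline-normalised landmark
separations at both protective levels, brain stress invariants, and the
protected-vs-unprotected attenuation ratio.

## Model components

### Fluids: weakly compressible SPH

Both fluid layers are smoothed-particle-hydrodynamics domains with the cubic
B-spline kernel (support `2h`, `h = 1.3 Δx` by default).  Density evolves
through the SPH continuity equation and pressure closes with the linear
equation of state `p = c0² (ρ − ρ0)`.  The numerical sound speed `c0` is
chosen by the weak-compressibility rule (≥ 10× the fastest material speed,
here wall speeds of ~1 m/s), not as the physical acoustic speed; this keeps
density variations below ~1 % while allowing an explicit time step.
Momentum uses the symmetric pressure-gradient form plus Monaghan artificial
viscosity (`α = 1`, `β = 2`), which is also the only representation of
physical viscosity: the momentum equation carries no separate laminar
operator, and at these scales the water-like `μ ≈ 1 mPa·s` of amniotic fluid
and CSF is dynamically negligible next to the stabilising artificial term.

Two numerical choices matter for long runs:

- **Integration order.**  Each step is kick → density → drift: accelerations
  from the current state, velocity kick, continuity evaluated with the
  *kicked* velocities, then the position drift.  Evaluating continuity with
  pre-kick velocities makes the acoustic density–velocity coupling fully
  explicit and slowly amplifies lattice-scale modes on fine particle bands
  (we observed e-folding times of ~3 ms on the CSF layer); the semi-implicit
  ordering is neutrally stable there.
- **Density reinitialisation.**  Every 30 steps the integrated density is
  re-anchored by a Shepard-normalised summation.  The Shepard correction
  removes the kernel-deficiency bias at free surfaces and walls; it controls
  drift in multi-second weakly compressible runs.

An isolated fluid conserves mass exactly (masses are never mutated) and
linear momentum to integrator order; the still-column verification
reproduces `p = ρ0 g · depth` within 5 % per particle in the interior
(outside one kernel support from walls and surface) after drag-assisted
settling.

### Solids: explicit viscoelastic finite elements

The uterine wall, fetal body, skull and brain are linear-triangle meshes
(2-D plane strain; all extensive quantities per metre of out-of-plane
depth) with lumped mass, mass-proportional damping and central-difference
(semi-implicit Euler) time stepping.  Kinematics are small-strain and
linear, matching the linear equation of motion
`M ü + C u̇ + K u = F_ext + F_FSI`; no corotational correction is applied,
so large-rotation scenarios are outside the model's validity.

The constitutive law splits volumetric from deviatoric response: pressure is
linear-elastic in the bulk modulus `K`, while the deviator follows a
generalized Maxwell (Prony) series
`G(t) = G∞ + Σ_k G_k exp(−t/τ_k)`, integrated with the midpoint exponential
internal-variable recurrence
`s_k^{n+1} = e^{−Δt/τ_k} s_k^n + 2 G_k e^{−Δt/(2τ_k)} Δe`.
Against the hereditary-integral solution for a step strain the recurrence is
first-order accurate and stays within 1 % at `Δt = τ/100`.

### Coupling: penalty contact

Fluid–solid (and, in the unprotected scenario, solid–solid) interaction is
normal penalty contact `F = k_c δ n` against the deformed surface polyline,
with the exact reaction distributed to the segment nodes by linear weights —
Newton's third law holds to machine precision by construction, and the
driver can assert global fluid–solid force balance each step (debug flag).
Fluid particles carry an engagement offset of half a lattice spacing (an SPH
particle represents fluid out to `Δx/2` from its centre), which makes the
seeded fluid layers load-bearing from the first step instead of leaving a
dead band between fluid and wall.  Contact is frictionless, purely normal;
consequently tangential drag between walls and fluid is not modelled.

The default `k_c = 10⁵ N/m²` (fluid) keeps the steady hydrostatic
penetration below one tenth of a particle spacing
(`δ = p Δx / k_c ≈ 0.04 Δx` at the column base); the solid–solid contact in
the unprotected scenario uses `10⁶ N/m²`.  Both penalty oscillator
frequencies are resolved by the global time step.

### Brain-skull restraint web

A submerged neutrally buoyant body in a closed fluid cavity has **no static
centring or rotational stiffness** — squeeze-film pressure resists only the
*rate* of approach, and frictionless normal contact transmits no torque — so
a brain coupled to the skull purely through the CSF drifts and rocks on the
slow components of the forcing until it meets the skull (a single-point
anchor was tried first and left an under-restrained rocking mode right in
the forcing band).  Anatomically the brain is restrained by the brainstem at
the foramen magnum, the dural septa (falx, tentorium) and the arachnoid
trabeculae distributed over the subarachnoid space.  The model represents
this as a distributed web: every brain boundary node is tied to its nearest
inner-skull node by a damped spring (defaults: total stiffness 12 kN/m per m
depth, total damping 250 N·s/m per m — near-critical for the ~3 kg/m brain;
both configurable).  The tangential lever arms of the web are what restrain
relative rotation.  The web handles slow centring and rotation; the CSF
still carries the dynamic normal load as a spread, nearly hydrostatic
pressure field, which is why brain von Mises stress stays low in the
protected scenario.

## Synthetic inputs

### Anatomy

The anatomy is concentric ellipses with configurable semi-axes and gaps —
a deliberate stand-in preserving the nested-layer topology the analysis
measures.  Defaults are of mid-gestation order (uterine cavity
110 × 85 mm, fetal body 85 × 60 mm, skull 52 × 40 mm, brain 37 × 25 mm,
amniotic gap 25 mm, CSF gap 10 mm) but are placeholders, not patient
measurements; no published anatomical dimensions back them and every length
is a config field.  The fetal-body annulus and the skull annulus share their
interface nodes (the skull is rigidly embedded); the brain disk is an
unstructured Delaunay mesh; fluids fill the two gaps on regular lattices
with half-spacing clearance.  Landmarks sit at fixed parametric angles:
four on the fetal surface tracked against the uterine cavity wall (frontal,
occipital, placenta, lower back) and six on the brain surface tracked
against the inner skull (left/right frontal, occipital, hemisphere).  At the
axis-aligned landmarks the baseline separations equal the configured gap
widths in closed form, which anchors the geometry tests.

The 2-D plane-strain configuration is the supported simulation dimension;
the SPH and stress machinery is dimension-agnostic, but no 3-D mesh
generator is provided (a 60 s 3-D run is far beyond this package's
desk-scale intent).

### Seizure kinematics

The boundary condition is roll (rotation about the longitudinal axis) only,
driving the uterine outer wall as a rigid rotation; pitch, yaw and
translation are not synthesised because the reference recordings captured
roll alone.  Target statistics (mannequin-derived): peak angular velocity
9.5 ± 1.1 rad/s, peak-to-peak excursion 0.50 ± 0.10 rad, dominant frequency
0.5 ± 0.1 Hz, duration 60 s.  These are mutually unreachable for any smooth
narrowband signal — a 0.5 Hz sinusoid spanning 0.5 rad peaks at ~0.8 rad/s —
so the generator produces a primary sinusoid at the dominant frequency plus
seeded band-limited jitter (3–9 Hz) with an acceleration-flat spectrum
(equivalently flat angle-PSD in band), which concentrates angular velocity
at high frequency while keeping angle excursions small.  A bounded per-seed
calibration loop scales the jitter to the peak-velocity target, nudges the
primary amplitude toward the displacement-range target, ratchets the
primary up if its periodogram line loses dominance (relevant for short
traces with coarse frequency bins), and redraws the jitter (up to 8 draws
from the seeded stream) if a realization cannot satisfy all three bands;
irreconcilable targets raise an error listing realized vs requested values.
The angular velocity is the exact spectral derivative of the angle.  The
recorded peak angular *acceleration* statistic (5 rad/s²) is incompatible
with the other three rows (peak ω of 9.5 rad/s at ≥ 0.5 Hz implies ≥
30 rad/s²); the generator reports realized acceleration but does not
calibrate to it.

A complementary filter
(`θ_fused = α(θ_prev + ω Δt) + (1 − α) θ_accel`) is provided for fusing
user-supplied raw gyroscope/accelerometer CSVs into a trace; the synthetic
path produces fused angles directly.

## Scenarios and observables

The **nested** (protected) scenario is the full model.  The **unprotected**
counterfactual removes both fluids and collapses both gaps to a 1 mm
clearance so that uterine-wall motion reaches the fetal body, and skull
motion the brain, through direct penalty contact; the brain mesh and
material are identical across scenarios, making the peak-stress comparison
like-for-like.  With gaps left at nominal size and no fluid, a rotating
smooth cavity never touches the fetus and the comparison would be vacuous —
collapse is the minimal meaningful reading of "unprotected".

Observables per output step (5 ms cadence): the ten landmark minimum
distances (exact point-to-segment against the deformed opposing surface),
normalised by their baselines — each level's headline separation curve is
the mean of its normalized series (four outer, six inner), with
per-landmark extremes reported alongside; the per-element brain stress tensor reduced
to principal stresses, von Mises stress, mean stress, triaxiality and first
deviatoric principal stress; and the brain–skull relative displacement
(difference of mean nodal displacements).  The attenuation report compares
peak brain von Mises stress and peak relative displacement across scenarios
as `100 (1 − protected/unprotected)`.

Von Mises stress is what separates the two coupling routes physically: fluid
cushioning transmits load as nearly hydrostatic pressure spread over the
whole surface (small deviator, small σ_VM), while direct contact produces
concentrated deviatoric stress.  The attenuation percentage therefore
measures exactly the mechanism the nested architecture is claimed to
provide.

## Scaled default scenario

The default run is 2-D, ~420 amniotic + ~270 CSF particles, ~1060 solid
elements, 6 s simulated (three convulsion cycles at 0.5 Hz) at a global
explicit step of ~7·10⁻⁵ s (CFL factor 0.4 over the fluid acoustic, solid
element and penalty-contact limits) — a few minutes on one core.  These
problem sizes are the package's intended desk scale; claims tolerant of the
reduction (separation ratios, attenuation percentages, bounds) are the
supported outputs.  Absolute stress magnitudes are *not* validated: all
solid moduli are documented placeholders (no quantitative fetal tissue
values exist to adopt), so stress fields should be read as order-of-
magnitude and pattern information only.

## What the synthetic data does and does not emulate

The generator reproduces the nested topology, water-like fluid layers,
stress-free quiescent initial state, and roll forcing with the recorded
summary statistics.  It does not emulate patient-specific anatomy, fetal
posture, the placenta or umbilical cord as distinct materials, multi-axis
seizure kinematics, gravity-driven settling (the default scenario is
neutrally buoyant with gravity off), fluid exchange between the two
domains (they interact only through solids, consistent with anatomy), or
3-D effects.  Passing tests therefore demonstrate the *mechanism* —
hierarchical attenuation through nested fluid layers under calibrated
forcing — not patient-level prediction.

## Numerical choices and degenerate inputs

- Explicit stability: `dt = 0.4 × min(h/c0, ℓ_min/c_dil, 2√(m_min/k_c))`
  over all domains; violating configs are rejected with the offending
  component named.
- Contact search: k-d-tree candidate lists refreshed every 10 steps and
  resolved exactly against cached candidates (particles move ≪ a segment
  length between refreshes); dense exact scans below 5·10⁵ point-segment
  pairs.
- Neighbour search: k-d-tree pair query at the support radius, rebuilt every
  step.
- Degenerate elements (non-positive area) are rejected at mesh construction
  with the element index; non-finite state aborts the run with the step
  number; penetrations beyond a configurable cap abort with a stiffness/step
  diagnosis.
- Geometry configs that violate nesting (brain ≥ skull cavity, fetus ≥
  uterine cavity, spacing ≥ gap) raise configuration errors naming the
  violated gap.
- Determinism: no randomness outside the seeded kinematics generator; two
  runs with one seed produce byte-identical metrics CSVs.

## Known limitations

- Small-strain linear solids: the unprotected scenario drives brain strains
  toward the limit of the linear regime; its stresses are indicative.
- Frictionless contact omits tangential fluid drag on walls; rotational
  fluid-solid coupling comes only from surface eccentricity and the anchor.
- Placeholder material magnitudes (see above).
- 2-D plane strain cannot capture out-of-plane flow escape; fluid stiffness
  in the gap is accordingly overestimated relative to 3-D.
- The complementary filter path is provided but unused by the synthetic
  pipeline (fused angles are synthesised directly).
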