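# Model and methods

This note documents the model implemented in `kneesim`: its structure,
assumptions, parameter defaults, numerical choices and limitations.

## Planar reduction

The knee is modelled in the sagittal plane.  Flexion/extension is
prescribed from the driving gait record; the anteroposterior (AP) and
proximal–distal translations of the tibia relative to the femur are the
free degrees of freedom.  Frontal- and transverse-plane motion
(varus–valgus, internal–external rotation, medial–lateral shift) is out
of scope.  The laboratory frame is tibia-aligned (+x anterior,
+y proximal, origin at the knee center); prescribed flexion rotates the
femur-fixed sites about the origin, and the free translations move the
tibia-fixed sites.  All of the headline outcomes — AP tibial
displacement, cruciate/collateral tensions, tibiofemoral contact
force — are expressible in this plane; out-of-plane ligaments enter via
their sagittal projections (see below).

The driving skeleton (trunk, pelvis, thigh) is not simulated as rigid
bodies.  Its three effects on the knee enter directly: prescribed knee
flexion, the ground reaction force (GRF), and the inertia of the
shank+foot segment, including the acceleration of the knee point
carried by the thigh (pelvis assumed to translate uniformly, thigh
orientation following hip flexion).  This keeps an identical loading
path with a far smaller state space.

## Synthetic gait

The generator produces a time-normalized 1 s stride with the canonical
structure of level walking:

* knee flexion: a small stance wave (default peak 18°, centered at 15 %
  of the cycle) plus a large swing wave (default peak 64°, centered at
  72 %), built from periodic von-Mises bumps
  `exp(kappa (cos 2pi(t-c) - 1))`.  Two well-separated bumps guarantee
  exactly two local maxima — the invariant downstream logic relies on.
  The widths (kappa 10 and 3.3) were chosen so that the inverse-dynamics
  knee moment has a physiological shape: extensor in early stance,
  flexor in terminal stance, and a hamstring braking burst of ~30 N·m
  in late swing, when the shank decelerates before heel strike.
* hip flexion: a single near-sinusoid (mean 12°, amplitude 15.5°,
  peak at 92 %), which both shapes the segment kinematics and sets the
  hamstring line of action (below).
* vertical GRF: a double-bump stance profile
  `BW (1.10 sin pi s + 0.12 sin 2pi s + 0.33 sin 3pi s)` with toe-off at
  60 %; per-leg impulse ≈ 0.48 BW·s per cycle (both legs together carry
  body weight; double support shares load, so the stance-mean is
  ~0.8 BW).  The AP component is a braking/propulsion sine of amplitude
  0.12 BW.
* stochastic variability: seeded jitter of the waveform amplitudes and
  baselines (default SD 0.5°), not additive sample noise, so the
  waveform topology survives every draw.

None of these shapes is a fit to a specific subject; they emulate the
*structure* of normative gait, which is what the experiments depend on.

## Geometry and calibration defaults

No subject-specific imaging underlies this model; attachment
coordinates, the condyle/plateau profile, ligament stiffnesses and
muscle PCSAs are literature-typical calibration defaults, all exposed in
the configuration file.  The default geometry was calibrated once
against clinical laxity behavior computed by the package's own
quasi-static drawer harness: a 90 N posterior drawer gives ~2–3 mm
intact and ~4–5 mm with the PCL removed across 0–90° flexion, an
anterior drawer of 134 N gives ~4 mm, and the intact-knee gait
simulation shows stance contact peaks of ~3.5 and ~5 BW (computational
models of this type characteristically over-predict the in-vivo 2–3 BW).

Choices a maintainer should know about:

* **Cruciate convention.** The femoral PCL sites are placed posterior to
  the femoral ACL sites (and likewise on the tibia).  Functionally the
  ACL resists anterior and the PCL posterior tibial translation through
  the tibial-site placement, which is what the experiments exercise.
* **Near-isometry.** Cruciate femoral sites sit close to the flexion
  axis, positioned so the PCL is just slack over the whole flexion arc
  and engages under posterior translation at any flexion, while the ACL
  slackens slightly with flexion.  Reference lengths make every bundle
  exactly slack at the full-extension neutral state (no prestrain; a
  per-bundle reference-strain override exists in the config).
* **Sagittal projections of out-of-plane ligaments.** The collaterals
  and capsule are collapsed onto the plane as near-vertical fascicles.
  A vertical fascicle is a *delayed, stiffening* AP restraint: its
  length grows quadratically with AP offset, so it is dormant for the
  first millimetres and then recruits with a large tension per unit AP
  restraint.  That reproduces the secondary-restraint behavior of the
  collaterals (dormant in the intact knee, strongly recruited — with a
  large compressive by-product — when the PCL is deficient).  The deep
  MCL additionally carries a small posterior offset so it is the first
  substitute restraint.
* **Plateau dish.** The tibial plateau is a parabolic well (radius
  35 mm against a 25 mm condyle) whose surface slope saturates at the
  rim (default 0.095).  The resulting AP centering force is
  proportional to the compressive load and capped at `slope × N`: the
  heavily loaded stance knee is essentially rigid in AP (the behavior a
  congruent 3D surface pair provides), while the lightly loaded swing
  knee lets the ligaments govern.  This is the planar stand-in for
  articular congruence and is the reason the stance phase is insensitive
  to PCL deficiency in the simulations.
* **Hamstring lines of action.** The semitendinosus, semimembranosus
  and long biceps head originate on a pelvis frame (ischial offset from
  the hip center), so their posterior obliquity on the tibia follows hip
  flexion: small in stance, large in late swing.  This hip-coupled
  obliquity is what concentrates the PCL loading episode in the second
  half of swing.  The short biceps head stays on the femoral shaft; the
  quadriceps act through effective inferior-patella points and the
  patellar-tendon insertion (anterior tendon tilt near extension,
  reversing in deep flexion); the gastrocnemii run from the posterior
  condyles to the calcaneus.
* **Stiffness table** (N per unit strain, per anatomical ligament,
  split equally over bundles): ACL 10 000, PCL 18 000, LCL 6 000,
  superficial MCL 8 250, deep MCL 5 000, capsule 9 000.  PCSAs are
  standard anatomy-table values (e.g. vastus lateralis 3 500 mm²,
  semimembranosus 1 900 mm²).
* **Anthropometrics.** Dempster-type fractions of a 70 kg, 1.72 m
  subject: shank 4.65 %, foot 1.45 % of body mass, shank length 0.246
  and thigh length 0.245 of height, shank COM at 43.3 % and radius of
  gyration 30.2 % of shank length, foot lumped 5 cm beyond the ankle.

## Muscle-force sharing

The knee moment demand is solved per sample by a linear program
(min σ s.t. F_i ≤ PCSA_i σ, F_i ≥ 0, Σ r_i F_i = M; HiGHS backend).
At the optimum all agonists work at the common stress and antagonists
are silent; no co-contraction is imposed beyond what the criterion
yields.  Muscle forces are computed once from the intact-knee driving
kinematics and then held fixed across injury conditions — hamstring
force is an experimental input scaled directly, not re-optimized.  Only
the knee moment is balanced; multi-joint consistency (e.g. ankle demand
for the gastrocnemii) is a known restriction.

## Contact and damping

Penalty contact: normal force `k_c δ + c_n δ̇` clamped non-negative,
with `k_c = 4·10⁴ N/mm` (maximum penetration on the default runs
< 0.09 mm) and critical damping (`ζ = 1`) as the inelastic,
zero-restitution law.  Friction is regularized Coulomb: magnitude
`μ N tanh(v/1 mm s⁻¹)` with μ = 0.01.  Ligament damping defaults to
zero; a small joint-level viscosity (0.8 N·s/mm on both free dof)
stands in for unmodelled soft tissue and provides the dissipation that
brings cycle 2 into periodic steady state (cycle 2 and cycle 3 agree to
well below the integrator tolerance).

## Integration

The free dof are advanced by an adaptive Kutta–Merson scheme (embedded
4th-order Runge–Kutta with local error estimate), base step 0.02 s,
per-step error targets 0.01 mm in position and 0.5 mm/s in velocity.
In addition the sub-step is capped at `1.8/ω_c`, where
`ω_c = sqrt(k_c/m)` is the stiff penalty-contact frequency: an explicit
scheme left to its error controller alone hovers at the stability
boundary of that overdamped mode and rings; the cap resolves the mode
instead.  Two cycles are simulated from rest and the second is analyzed.
Halving the output step changes the analyzed AP curve by far less than
5 % of its range.

The quasi-static drawer test minimizes the total potential energy
(ligament strain energy + contact penalty + load potential) with BFGS,
using the analytic force residual as the gradient, with numerical
continuation in 25 N force steps; displacement is reported from the
unloaded equilibrium under a 100 N seating preload.

## Experiments and statistics

* PCL sweep: residual stiffness 100…20 % in 10 % steps plus 15 %, one
  two-cycle simulation each, identical gait and muscle forces.
* Hamstring sweep: residual hamstring force 100/90/80/70/60 % at 15 %
  residual PCL stiffness, referenced to the 100 %-force condition; the
  intact-knee contact curve is attached for comparison.
* Statistics: mean difference from the reference over the late-swing
  window 76–100 % of the cycle (closed at both ends; the grid point at
  exactly 100 % belongs to the next cycle), windowed extrema with
  earliest-sample tie-breaking, and least-squares polynomial trends
  (default degree 2) across sweep factors.

Default problem sizes: 100 samples per cycle, 2 cycles per simulation,
10 + 6 simulations for the two sweeps — a full study runs in about a
minute on one CPU.

## What the synthetic model does and does not show

The generator and the default geometry emulate the *structure* of
normal walking and of knee laxity, not any specific subject.  Passing
simulations therefore demonstrate the directional physics of PCL
deficiency — monotonically growing late-swing posterior tibial
displacement, stance insensitivity, deep-MCL/LCL substitution with a
contact-force penalty, and its reversal by hamstring relaxation — with
magnitudes proper to this generic planar model (tenths of a millimetre
to millimetres of windowed mean displacement; a few to tens of newtons
of windowed mean contact-force change).  A subject-specific 3D model
with imaging-derived surfaces produces the same orderings at much
larger amplitudes; the planar congruence surrogate, straight-line
muscle paths and ligament projections compress the compliance of the
real joint.  Known limitations: no menisci or cartilage, no
patellofemoral joint outputs, no wrapping, no activation dynamics, no
varus–valgus/rotatory laxity, knee-moment-only optimization, and a
penalty (not impulse-based) contact.
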