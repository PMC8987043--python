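# Model and methods

`oculoplant` simulates the mechanics of the human oculomotor plant with
actively controlled rectus pulleys: a spherical globe rotating about its
fixed center, six extraocular muscles (EOMs) represented as massed
musculotendon strands, rigid pulley tubes for the two horizontal recti, and
an optimization-based neural controller that solves for muscle innervations
in velocity space.  This note records the model's assumptions, the
parameters that matter, the numerical choices, and what the synthetic
default anatomy does and does not represent.

## Mechanical model

**Globe.** A uniform sphere (radius 12 mm, mass 7.5 g) constrained to rotate
about its geometric center.  Orientation is a unit quaternion; gaze is
reported as Fick angles (horizontal then vertical), positive horizontal =
abduction of the modelled right eye, positive vertical = supraduction.
Besides the muscle torques, the globe feels passive orbital-tissue
elasticity, modelled as an isotropic rotational spring (10 gf·mm/deg)
plus an additional stiffness about the line of sight (20 gf·mm/deg)
representing the torsional stability imposed by the pulley apparatus and
orbital fascia, and viscous drag (0.5 gf·mm per deg/s).  Without the
orbital spring, the static torque balance could not simultaneously produce
the agonist (~25 gf) and antagonist (~10 gf) horizontal tensions observed
at 30° ductions; without the torsional term, ocular torsion would be set by
small active imbalances rather than by the tissues.

**Strands.** Every musculotendon segment is a clamped cubic B-spline whose
control points are point masses (0.1 g).  The horizontal recti (LR, MR) are
bilaminar: a *global layer* (GL, 8 control points) runs from the annulus
region through the pulley tube and continues as an elastic tendon (4 points)
to the sclera; an *orbital layer* (OL, 8 points) inserts on the pulley tube
itself.  SR, IR and SO are single contractile strands in series with elastic
tendons; IO is a single contractile strand.  Contractile strands follow a
three-element Hill law

    F = a · Fmax · FL(l/l₀) · FV(v/v_max) + F_passive(l, v),

with a Gaussian force–length bell (width 0.3), a Hill hyperbola for
shortening (curvature 0.25) joined C¹ to a saturating lengthening branch
(plateau 1.4), an exponential passive toe (exponent 5) above the slack
length, and a linear passive viscosity (GL: 0.2 gf·s/mm) that produces the
stretch-rate tension transients seen in fast eye movements.  Tension is
computed from the whole-strand length (control-polygon arc length) and is
uniform along the strand up to a small node-spacing regularisation; strands
can never push.  Strand nodes ride over the sclera on a frictionless radial
penalty (C¹ quadratic toe), which is how tendon paths wrap the globe.

**Pulley tubes.** Each horizontal rectus pulley is a rigid tube
(bore radius 2.5 mm, length 4 mm) that can translate (rotation locked) and
acts as the common junction of the OL insertion, the GL passing through the
bore, and eight elastic suspensions:

- four *outer* suspensions anchored on the orbital wall at the
  anterior/posterior × superior/inferior corners (modelled as 4-point
  elastic strands).  The anchors sit 7 mm above/below and 2 mm outward of
  the tube with ±2.5 mm axial offsets, so transverse stiffness is high while
  anteroposterior travel stays compliant; anterior pretension exceeds
  posterior so the anterior-superior suspension carries the largest load.
- four *inner* suspensions coupling the tube to the GL at ±45° azimuths
  (superior/inferior × inward/outward bore points).  They attach to the
  point where the GL crosses the tube mid-plane — a *sliding* attachment,
  realised as a smooth tent-kernel average over the GL nodes within
  ±2.5 mm of the mid-plane — so the GL slides longitudinally freely while
  transverse motion is restrained.  Because the attachment is non-material,
  these four couplings are evaluated as straight massless elastic elements
  rather than 4-node strands.

With the ±45° azimuths, the eight suspensions pair superior/inferior, and
in pure horizontal gazes each inferior tension equals its superior partner.
A frictionless penalty contact (100 gf/mm) between the GL and the bore
guarantees the GL can never leave the tube even if the inner suspensions
were overpowered; in calibrated operation the contact stays disengaged.

**Suspension calibration.** Suspension stiffnesses, orientations, and
pretensions are not measurable quantities; they were determined empirically
(the packaged `calibration` module implements the search) so that (i)
vertical-duction pulley sideslip stays within physiologic bounds (< 0.4 mm
LR, < 0.8 mm MR at 30° ductions), and (ii) all suspension tensions across
the horizontal sweep stay within the empirically reported 3–13 gf band.
The frozen result: outer stiffness 50 gf/strain with 16 %/21 %
anterior/posterior pretension; inner stiffness 15 gf/strain with 50 %
pretension.

## Neural controller

Each control step (5 ms) the controller solves for the eight innervations
A = [a_LR_GL, a_LR_OL, a_MR_GL, a_MR_OL, a_SR, a_IR, a_SO, a_IO] by
minimising

    w_a · ‖A‖²  +  w_x · ‖v_eye(A) − v_target‖²,     w_a = 1, w_x = 10³,

over [0,1]⁸.  v_eye(A) is predicted by a trial rollout of the plant over
one control interval (the mean angular velocity of the second half of the
horizon, so fast strand transients do not alias into the loop), linearised
by finite differences around the currently applied innervation.  The
resulting convex QP is solved exactly (Cholesky factorisation + bounded
least squares, with enumeration of the binding differential constraints).
No reciprocal-innervation pairing is assumed; the eight actuators are
independent.

During fixation and any phase with globe speed below 20 deg/s, two linear
constraints enforce greater orbital- than global-layer drive for each
contracting horizontal rectus: a_OL ≥ a_GL + 0.05 (a rectus counts as
contracting when its solved GL innervation exceeds 0.01).  Between saccade
onset and offset — globe speed of at least 20 deg/s — the constraints are
lifted.

Two numerical regularisers stabilise the discrete-time loop and are *not*
part of the cost definition: a rate penalty w_da‖A − A_prev‖² and a
per-step trust region on |ΔA|.  Both blend smoothly with speed and are
removed entirely during the saccadic phase, which is also why the
antagonist's innervation is released immediately at saccade onset.

**Fixation servo.** A pure zero-velocity target cannot correct position
drift in a finite-stiffness plant, so fixation targets add a proportional
gaze-direction correction v = k_p·e (k_p = 5 s⁻¹, capped at 15 deg/s so
distant targets are approached as a bounded slew).  The torsion component
of the error carries a 3× gain because the obliques' torsional authority is
weak.  Static solves settle dynamically with the controller in the loop
(no root-finding): convergence requires globe speed < 0.1 deg/s and gaze
error < 0.05° for 50 consecutive integrator steps; near the target the
solved innervation is held for progressively longer intervals (up to
100 ms) so the damped plant truly settles between updates, and after the
criteria are met a short polish phase (servo gain ×2.5, up to 2.5 s)
relaxes the full orientation — including torsion — to ~0.002°, returning
the quietest state observed.  This polish is what lets the
superior/inferior suspension symmetry hold to 10⁻³ gf.

**Saccades.** Targets follow a minimum-jerk velocity profile between the
endpoint gazes plus the same servo correction (ceiling 150 deg/s during
saccades).  The packaged 30° saccade uses a 200 ms profile: its peak demand
(281 deg/s) matches the plant's peak capability, so the whole trajectory is
tracked by agonist modulation alone.  A 100 ms profile (peak 562 deg/s)
exceeds what the calibrated muscles can deliver at this scale and would
force active antagonist braking during the lag, contrary to the observed
silent antagonist; the slower, matched profile is the package's deliberate
choice.

## Integration and numerics

Semi-implicit (symplectic) Euler at dt = 0.5 ms.  Velocity damping terms are
applied implicitly (unconditionally stable): per-node viscous damping
(3000 s⁻¹), overdamped tube translation (4000 s⁻¹), and strand viscosity as
an implicit per-segment tangential velocity filter.  The force–velocity
response operates on a low-pass-filtered strand velocity (first-order lag,
8 ms, representing crossbridge force dynamics); an instantaneous FV response
would act as an explicit damping feedback through the moving scleral
insertions whose rate exceeds the explicit stability limit under strong
co-contraction.  Quaternions are renormalised every step; a divergence
detector aborts if any node exceeds 10⁴ mm/s.  Degenerate inputs
(zero-length segments, slack strands, points on the tube axis) short-circuit
to zero force.

## Default anatomy: what it is and is not

The packaged right-eye anatomy uses standard human values — globe radius
12 mm, rectus scleral insertions at spiral-of-Tillaux-like eccentricities
(55° from the anterior pole), origins ≈ 36 mm posterior near the annulus of
Zinn, trochlea nasal-superior-anterior — but it is an idealisation, not a
transcription of any single anatomical study:

- LR and MR are exactly mirror-symmetric about the sagittal plane, including
  their pulley tubes and suspensions (a shared tendon length of 7 mm).
- Optimal fibre lengths, slack lengths, and suspension rest lengths are
  derived from the constructed geometry with explicit pretension factors.
- Maximal isometric forces (GL 80 gf, OL 20 gf, SR/IR 60 gf, obliques
  20 gf) and shortening velocities (GL 400 mm/s) are chosen so static
  tensions and saccadic velocity capability are physiologic.
- Vertical recti are placed 2 mm nasal of the mid-sagittal plane and the
  obliques run from nasal origins to posterior-temporal insertions, giving
  them realistic secondary actions; this cross-coupling is what makes the
  controller co-contract several muscles at every fixation.

`perturb_anatomy` supplies reseedable jittered variants for robustness
testing (insertions re-projected onto the globe so all invariants hold).

Consequences for interpretation: passing tests show that *this calibrated
mechanical configuration* reproduces the published fixation, duction and
saccade behaviours; they do not validate the specific numeric anatomy
against any subject, and pulley sideslip magnitudes (≈ 0.05 mm here) land
well under the physiologic bounds rather than at any particular measured
value — the suspension calibration controls the bound, not the exact
number, which is not identifiable without the original stiffness data.

## Known limitations

- Secondary gazes only: tertiary (oblique) gaze directions, and with them a
  full treatment of Listing's law, are out of scope; torsion is stabilised
  passively and servo-damped, not controlled to Listing's plane.
- Vertical recti and obliques have no pulley tubes; their paths wrap the
  globe but are otherwise straight.
- During the saccadic main course the orbital layer's oculorotary
  effectiveness (acting through the tube) is much weaker than the global
  layer's, so the minimum-effort controller recruits the OL to its maximum
  only when the GL saturates at peak velocity; the enforced OL > GL margin
  holds whenever the differential constraint applies (all fixations and
  pre/post-saccadic phases), but a sustained OL > GL across the entire
  unconstrained high-velocity phase does not emerge from this cost.
- At extreme antagonist-side gazes a muscle's GL innervation can reach
  exactly zero; co-contraction keeps both layers of both horizontal recti
  active over most of the ±30° range but not strictly everywhere.
- The rigid tubes cannot rotate; tube rotation is a plausible refinement
  flagged in the configuration.
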