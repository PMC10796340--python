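# Methods

This note documents the models inside `spastigen`, the defaults and why
they were chosen, what the generator does and does not emulate, and the
numerical choices a user extending the package should know about.

## Cohort

The 92-patient reference table is packaged verbatim
(`data/cohort.csv`) rather than re-derived: the character generator it
originates from assigns stature and limb segment lengths from internal
presets per (phenotype, sex, age) that are not published, so the table is
the ground truth. The loader validates every invariant on each load
(positivity, slider ranges in [25, 75] %, tabulated ages, contiguous ids)
and refuses a corrupted table.

`anthropometry_for` answers non-tabulated ages by linear interpolation
between the two *nearest* tabulated ages of the same (phenotype, sex,
mass, tone) combination, clamped outside the tabulated range. Linear
interpolation with clamping is the simplest monotone scheme; nothing is
known about the true age dependence beyond the three tabulated points, so
anything higher-order would be invented precision.

The mass and tone percentages are carried as opaque bookkeeping: they do
not alter kinematics or segment lengths. An optional hook
(`scale_force_by_tone`) scales maximal isometric force by tone/50 for
users who want tone to be mechanically visible; it is off by default
because no quantitative mapping is established.

## Movement synthesis

Each movement is a 6 s round trip — start pose, full range of motion at
3 s, return at 6 s — matching rehabilitation practice of 2–3 s per
directed movement. Interpolation between keyframes is the minimum-jerk
quintic, chosen over animation-software spline defaults because it is the
standard model for point-to-point human reaching and fully analytic: zero
velocity and acceleration at every keyframe, symmetric about each segment
midpoint, and exactly no overshoot. Cosine and linear kernels are
available via config for sensitivity checks.

Ranges of motion default to the central values (elbow 140°, shoulder 90°
both planes, pronation 150°) with ±20°/±10°/±10° tolerance bands exposed
as per-run overrides. The pronation sweep is centred on neutral
(−75° → +75°, full supination to full pronation): a 0→150° sweep would be
outside physiological forearm limits, while the excursion is unchanged.
The wrist rotation (+90° elbow movement, −90° shoulder flexion and
pronation) is held as a static preset for the whole movement.

The sampling rate defaults to 100 Hz (a typical optical motion-capture
rate; 601 frames over 6 s). The peak time must fall exactly on the
sampling grid — otherwise the sampled maximum would silently undershoot
the nominal range of motion, so synthesis raises instead.

Angles are stored in degrees everywhere trajectories travel (the motion
file convention) and converted to radians only at the dynamics and
constraint boundary, which is also where the model file expresses limits.

## Skeleton and markers

The 71 joints (6 per lower limb, 24 per upper limb, 11 core/head/neck)
mirror a character-generator rig. Only the right upper-limb chain is
articulated; the four movements drive nothing else, so the rest of the
body is static scenery scaled to stature. Chain segment lengths are the
patient's anthropometry exactly, so segment-length conservation under
forward kinematics is testable to machine precision. Pronation is
modelled as axial rotation about the instantaneous forearm axis: radius,
ulna and hand markers orbit the axis while the wrist centre is unmoved.

The 14-target reduction map (R_Shoulder, R_Elbow, R_Radius, R_Ulna,
WristRight, R_Hand, L_Shoulder, C7, T10, Clavicle, Sternum, Pelvis, Head,
L_Elbow) covers the articulated chain plus the torso references a
marker-scaled upper-limb model needs. It is a package convention, stored
as a user-replaceable two-line text file, because the canonical identity
of such a set lives in whatever downstream model consumes it.

The animation→model frame change is a −90° rotation about the vertical
axis plus a vertical offset; the default offset grounds the pelvis marker
at height 0, a concrete and reproducible choice for "pairing" the two
vertical axes. The transform is an isometry, verified as such.

## Spastic muscle

A rigid-tendon Hill-type muscle. The rigid tendon removes a per-frame
nonlinear equilibrium solve; the qualitative grade separation the package
exists to produce does not hinge on tendon compliance, and an
elastic-tendon mode is a clean extension point. Curve constants are
classic first-order defaults, all config-overridable:

| constant | value | meaning |
|---|---|---|
| γ | 0.45 | active force–length Gaussian width |
| a_f | 0.25 | force–velocity curvature |
| f_ecc | 1.4 | eccentric force plateau |
| k, ε₀ | 5, 0.6 | passive exponential shape / normalising strain |
| τ_act, τ_deact | 10, 40 ms | activation / deactivation time constants |
| v_max | 10 l_opt/s | maximal shortening velocity |

Per-muscle constants (f_max, l_opt, l_slack, pennation) for the 16
catalogue muscles ship in `data/muscles.csv` with physiologically
plausible magnitudes; they are placeholders enabling relative,
grade-ordered comparisons, not subject-specific claims.

Activation dynamics solve da/dt = (e − a)/τ with τ switched on the sign
of e − a. The per-sample update is the exact zero-order-hold exponential
a′ = e + (a − e)·e^(−Δt/τ) rather than forward Euler: at 100 Hz the step
equals τ_act, where Euler degenerates to a one-step jump, while the
exponential update reproduces the closed-form step response
1 − e^(−t/τ_act) to machine precision at any rate. It is contractive, so
activation provably stays in [0, 1].

The reflex is velocity-gated: e_sp(t) = clip(G·max(0, ṽ(t−d) − v_th)),
with ṽ the normalized fiber lengthening velocity (positive on stretch)
obtained by finite differences of the rigid-tendon fiber length. Before
t = d the reflex sees quiescent history. Delays off the sampling grid are
handled by linear interpolation of the velocity history.

**The MAS grade table is the single most consequential free choice in the
package.** No published quantitative mapping from MAS grades to (gain,
threshold, delay) exists; the default table — gains 0, 0.5, 1, 2, 4, 8;
thresholds ∞, 0.20, 0.15, 0.10, 0.05, 0.02 l_opt/s; delay 30 ms — is
constructed to be strictly monotone so that grade ordering is a provable
property, and is fully configurable. Grade 0 has zero gain (no increase
in muscle tone); its threshold is stored as +∞ so the monotonicity
invariant holds vacuously and the reflex can never fire.

## Pipeline

The per-sample pipeline is a desk-scale analogue of the standard
five-stage marker-driven workflow:

1. **Scaling** — per-segment factor = patient/generic length; the generic
   model uses the cohort mean (no canonical generic lengths exist).
   Muscle default lengths l_mt,0 scale with their segment.
2. **Inverse kinematics** — per-frame bounded least squares over the
   driven angles against model-predicted marker positions, warm-started
   at the previous frame; per-frame residual RMS is reported. For
   internally generated (noise-free) markers the residual is numerically
   zero, which is the package's stand-in for a residual-reduction stage;
   the default dataset path feeds the synthesized trajectory directly
   (IK of noise-free self-generated markers is an identity up to solver
   tolerance, verified by a round-trip property test).
3. **Constraint check** — every sample against joint limits stored in
   radians (elbow [0°, 150°], shoulder flexion [−60°, 180°], abduction
   [0°, 180°], pronation [−90°, 90°]); catalogue movements are clean by
   construction.
4. **Musculotendon length** — constant moment arm per (muscle, joint):
   l_mt = l_mt,0 − r·θ. Constant arms keep every length analytic and
   testable; polynomial arms are an extension point. Signs follow the
   stretch-reflex logic: agonists of the positive direction have r > 0.
   Rest fiber lengths are tabulated per (muscle, joint) so that every
   cohort × movement combination keeps a strictly positive fiber length
   (verified across all 92 × 4 combinations in the test suite).
5. **Forward muscle simulation** — excitation-driven, as above. Muscle
   recruitment per movement follows the motion–muscle table, taking the
   union of both movement directions.

Motion is prescribed and muscles respond — the passive-mobilisation
scenario of a clinical spasticity exam — so no rigid-body forward
dynamics or muscle-control optimisation is performed, and the default
baseline excitation is 0 (a relaxed patient). External-load files
(MOT columns time, force/point/torque xyz, applied at the WristRight
marker) are accepted and recorded in provenance only; they do not enter
the rigid-tendon simulation. That hook exists for instrumented
human–robot interaction data and is a documented limitation.

## Dataset generation

The default run is the full factorial: 92 patients × 4 movements TRC
(one per motion, 14 markers, mm, 601 frames) and × 6 grades STO bundles
(per-muscle excitation, activation, normalized fiber length and velocity,
force). Optional isotropic Gaussian marker noise (default σ = 0) emulates
capture imperfection on the exported TRC only; simulations always consume
the noise-free motion, so file counts and simulation content are exact
under any noise setting. Noise streams derive from the run seed plus the
(patient, movement) indices, making trees byte-reproducible for equal
seed+config. The manifest records a content hash per file, the seed and a
canonical config hash; verification re-hashes everything and re-parses a
sample through the readers.

## What the generator does and does not emulate

Synthetic cohort, idealised kinematics (no soft-tissue artefact, marker
occlusion, bimanual or compensatory movement), constant moment arms,
rigid tendon, placeholder muscle constants, and an invented (monotone,
configurable) MAS parameterisation. Passing tests therefore demonstrate
internal consistency, exact bookkeeping and correct model *ordering*
across grades — not clinical validity against real patients. File formats
(TRC/MOT/STO), by contrast, follow the consumer software's conventions
exactly and round-trip losslessly.

## Problem sizes used in tests and the acceptance script

Unit and property tests run at reduced rates (10 Hz IK round trips,
0.4–0.5 s muscle sweeps, 1,000-case randomized bounds sweep) — sizes
chosen so each property is exercised far above its noise floor while the
whole suite stays interactive. The acceptance script regenerates the full
2,208-sample dataset at the default 100 Hz.
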