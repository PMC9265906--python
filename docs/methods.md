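# Methods

## Model overview

The foot is modeled as three rigid segments (phalanx, forefoot, hindfoot)
plus the shank as the proximal reference body.  All computation happens in
a fixed lab frame: right-handed, x along the walking direction, z vertical
up.  Input positions are converted to SI on read; marker trajectories and
plate signals are low-pass filtered (zero-lag fourth-order Butterworth,
10 Hz cutoff, odd-reflection padding, run as second-order sections so the
DC gain is exact to machine precision); the 1000 Hz plate records are then
decimated to the 100 Hz marker clock by nearest-sample selection so the
kinetic chain runs on a single time base.

## Segment frames and sign conventions

Each segment frame keeps its first-listed defining axis exact and
Gram-Schmidt-orthogonalizes the second against it; the third axis is their
cross product (x = y × z).  The landmark definitions fix the axes only up
to sign, so polarities are resolved anatomically: z points dorsally
(toward CA for the hindfoot, toward the knee for the shank) and y points
laterally for right feet.  For left feet the rule mirrors across the
sagittal plane (y points medially), which keeps dorsiflexion positive
about y on both sides.

Joint angles are intrinsic Euler decompositions of R = B_proxᵀ B_dist:
y-x-z at the ankle, z-x-y at the midtarsal and MTP joints, so the dominant
flexion axis is always adjacent to the frame whose motion it describes.
With these frame polarities the raw x/y/z components read +eversion,
+dorsiflexion, +adduction on a right foot; reported tables apply the
per-side sign map (+1, +1, −1) right / (−1, +1, +1) left so that reported
angles and moments are positive for eversion, dorsiflexion and abduction.
Raw components are kept for all mechanics; powers are unaffected because
the same sign flips both moment and angular velocity.  The MTP joint is
treated as a flexion hinge and only its y angle is reported.  Frames whose
middle Euler angle passes ±89.9° are flagged rather than rejected.

## Aponeurosis geometry

Attachment coordinates of the five slips (insertions on the proximal
phalanges, via points under the metatarsal heads, one shared calcaneal
origin) are shipped as a normalized table expressed in anatomical axes
(x anterior, y medial, z dorsal) and scaled by the subject's quiet-standing
|ANKL−VMH| distance.  Because the package's segment frames have x
posterior and y lateral (a consequence of the polarity rule above), the
anatomical coordinates are mapped into segment axes through the proper
rotation diag(−1, −1, +1) before placement; left feet mirror the table's y
column first.  Placement is the affine map p_lab = origin + basis · p_local
per host frame (phalanx/forefoot/hindfoot with origins VMH/VMB/HE).

Slip lengths use the two-leg polyline through the via point — a fixed
frictionless point, not a wrapping surface — and tensions are
tension-only linear springs.  The calibration inverts the tension law by
construction: stretching every slip by exactly the calibration strain of
its natural length makes the summed tension equal 1.5 body weights to
machine precision.  Natural lengths default to 0.98 of the quiet-standing
lengths (the standing arch is slightly flattened, so the standing PA is
already a little stretched); per-slip stiffnesses use each slip's own
quiet-standing length, so the five values differ slightly.

## Inverse dynamics

The Newton–Euler chain is solved per time step from the phalanx inward.
Moments are balanced about each segment's COM; the angular-momentum term
M{ω×(Iω) + Iω̇} is evaluated in the segment frame, where the inertia
tensor is constant, with ω obtained from the skew-symmetric part of Ṁ Mᵀ
(central differences, second-order one-sided at the ends — exact for
quadratic trajectories).  Joint moments are reported at the joint centers
and re-expressed in the proximal segment frame (shank for the ankle,
hindfoot for the midtarsal, forefoot for the MTP).

Plate wrenches (force + vertical free moment at the COP; horizontal
couples at the COP are taken as zero, the standard plate convention) are
assigned per time step by projecting the COP on the foot's longitudinal
axis: the front plate loads the phalanx when its COP is distal to the MTP
center, else the forefoot; the rear plate loads the hindfoot when its COP
is proximal to the midtarsal center, else the forefoot.  A plate whose
force magnitude is below the 10 N contact threshold is unloaded.  Gait
events are detected from the *raw* vertical plate force crossing the same
threshold — the 10 Hz kinetic filter would smear the low crossing by tens
of milliseconds — while all kinetic signals use the filtered versions.

The aponeurosis-free comparison run zeroes all attachment forces and
changes nothing else, which isolates the spring terms exactly.  Because
each slip applies a zero net wrench to the foot, the ankle load is
provably identical between the runs, and the with/without moment
difference at the MTP and midtarsal joints equals minus the torque of the
distal-side attachment forces about the joint; both identities are
regression-tested at 1e-9.

The %PA contribution is 100·(n_without − n_with)/n_without on the flexion
component, evaluated at "push-off" — operationalized as the instant of
peak no-PA plantarflexion moment within the last 40 % of stance.  Because
"push-off" and "toe-off" are used near-interchangeably in the gait
literature, the value at the toe-off sample is reported alongside.  The
denominator below 1e-6 N·m flags the ratio undefined (NaN).

Joint power is n·ω_rel in the proximal frame (frame-invariant as a dot
product); positive/negative work integrate the clipped power with the
trapezoid rule over the cycle window, so W₊ + W₋ equals the net integral
identically.

## Inertial constants

Relative masses (14.4/42.4/43.2 % of foot mass), COM positions
(43.6/41.9/55.4 % of segment length from the proximal joint) and relative
inertia tensors are shipped as a versioned JSON table.  The tensors are
interpreted as expressed in their own segment frames about the COM — the
only frame in which time-constancy makes sense — and scale as
I = I_rel·m^(5/3), the exponent of a shape-preserving constant-density
family; the underlying 1.1 g/cm³ density is baked into the table and not
used at run time.  COM lines run ankle→midtarsal (hindfoot),
midtarsal→MTP (forefoot) and MTP→PM (phalanx; the phalanx has no distal
joint, so the most distal landmark closes the line).  The sensitivity
analysis multiplies masses and tensors directly by 0.5/1.0/1.5 — a
perturbation of the final parameters, deliberately not re-applying the
m^(5/3) rule.

## Synthetic trials

The generator exists so the full pipeline, including its oracles, runs at
desk scale.  Design choices that matter for interpreting test results:

* **Template geometry.**  The marker template is a stylized right foot,
  uniformly rescaled so the attachment scaling length |ANKL−VMH| is
  exactly 0.25 m.  That makes the placed aponeurosis geometrically
  consistent with the normalized attachment table, at the price of an
  oversized foot (≈0.47 m long): moment magnitudes and PA forces are
  correspondingly larger than physiological values.  The template is a
  versioned fixture, not an anatomical claim; structural properties
  (invariances, monotonicities, energy bookkeeping) are what transfer to
  real data, absolute magnitudes are not.
* **Exact angle ground truth.**  Joint motion is prescribed as flexion
  profiles and realized by rotating each distal marker set about the
  template joint line along the relevant frame's own y axis (PM about the
  FMH–VMH line, forefoot+PM about the TN–VMB line, the shank about its
  own y axis with reversed sign).  Because the flexion angle is last in
  the z-x-y sequences and first (proximal-side) in y-x-z, the prescribed
  profile adds exactly to the template's constant offset angles — the
  emitted ground truth is recoverable by the kinematics module up to
  filtering error, which is what the 0.2° RMS recovery test measures.
* **Profiles.**  Raised-cosine bumps reproduce the qualitative gait
  sequence: early-stance MTP plantarflexion (10°) with midtarsal
  dorsiflexion (8°), late-stance MTP dorsiflexion (30°) with midtarsal
  (15°) and ankle (20°) plantarflexion, neutral recovery in swing.  With
  the 0.98 natural-length fraction the slips are taut near the standing
  pose and go slack around toe-off, so both spring branches are
  exercised.  Cycle duration 1.03 s, stance fraction 0.61, walking speed
  1.33 m/s — the mean study conditions of the reference data set.
* **Ground reactions are prescribed, not simulated.**  A double-hump
  vertical profile (peaks 1.10 BW, valley 0.75 BW, 3 %-of-stance contact
  on/off envelope so the 10 N threshold crossing is sharp), biphasic
  shear (±0.15 BW), and a small vertical free moment are split between
  rear and front plates by a smooth weight; the COPs progress heel→toe
  crossing both assignment boundaries.  Trials are therefore not
  dynamically consistent at the whole-body level — inverse dynamics
  remains well-defined and every oracle is term-by-term, but the absolute
  joint moments of synthetic trials should be read as test quantities,
  not predictions.
* **Determinism.**  All randomness (marker noise only) flows from the
  spec's seed; identical specs produce byte-identical files.

The static load case generator emits hand-computed statics (explicit
cross products, no Euler terms) as an independent oracle for the chain
solver; the gravity-only variant gives the closed-form gravitational
torque check.

## Numerical choices and limitations

* g = 9.8 m/s² throughout, matching the constant inside the stiffness
  calibration.
* Derivatives by central differences (edge order 2); no spline smoothing.
* Degenerate geometry (plane-defining points with triangle area
  < 1e-9 m², via points within 1e-9 m of an attachment) raises rather
  than propagating NaNs.
* Problem sizes: the default synthetic trial is one gait cycle
  (~134 marker frames, ~1330 plate samples); the full analysis plus the
  27-cell sensitivity grid completes in about a second.
* Not modeled: PA viscoelasticity or hysteresis; thickness/age/sex
  individualization (stiffness varies only through body weight); muscle
  force decomposition; joint translations; skin-artifact simulation.
  C3D input is out of scope — TRC and plate CSV are the reference
  dialects behind the same in-memory contract.
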