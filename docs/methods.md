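# Methods

This note documents the models and numerical choices behind `artikin`: the
articulator coordinate convention, the forward and inverse kinematics, the
condylar-path personalization, the verification metrics, the occlusion
simulation, and — because the package validates itself on synthetic
patients — exactly what that validation does and does not show.

## Coordinate convention

The articulator (world) frame is anatomical and derived from three
landmarks: origin at the midpoint of the intercondylar axis, **+X** toward
the patient's right condyle along the hinge axis, **+Z** normal to the
chosen cranial reference plane (Frankfurt, through the infraorbital point,
or Camper, through the nasal alar point) pointing superiorly, and
**+Y = Z × X** pointing anteriorly. With the condyles on the reference
plane this puts them at (±w/2, 0, 0) for intercondylar width w, makes the
mid-sagittal plane x = 0 and the horizontal plane z = 0, so the two planar
path projections used in fitting are literal coordinate drops. Lengths are
millimetres, angles radians internally and degrees at every file and CLI
surface. The plane-normal sign is fixed by requiring the anterior landmark
to have positive y; an optional up-hint (default CT +z) is checked and a
warning logged if it disagrees — that almost always means swapped
left/right condyle labels.

Every rigid map is a `FramedTransform` carrying source/target frame names;
compositions verify the chain. This is bookkeeping, not mathematics, but
it is what makes the marker/camera chain (below) safe to assemble.

## Forward and inverse kinematics

The mandible is rigid; its pose is parameterized about the *working-side*
condyle rest position `c = (x0, y0, z0)` as a rotation
`R = Rz(θz)·Ry(θy)·Rx(θx)` (this composition order is fixed; no other
Euler convention is exposed) followed by a translation `t`:
`p′ = R (p − c) + c + t`.

Six constraints determine the six unknowns from one measured incisal point:
the posed incisal point must equal the target (3); the condyle translation
must follow the personalized path, `tx = f(y0 + ty) − x0`,
`tz = g(y0 + ty) − z0` (2); and the roll must satisfy
`θy = atan(Δz′/Δx′)` over the posed condyles, wrapped to (−π/2, π/2] (1).

A note on the roll constraint: with the axes above, the wrapped arctangent
of the posed intercondylar axis is the *undirected* tilt of that axis, and
the fixed-point of the constraint pins θy to essentially zero for
physiological poses — the opposite sign convention would make the equation
an identity and the system rank-deficient. We keep the well-posed form;
the synthetic forward model resolves θy from the same fixed point, so
forward and inverse models agree exactly.

The solver is damped Newton–Raphson: central finite-difference Jacobian
(step 1e−6 per component; an analytic Jacobian would be straightforward
but is deliberately omitted — the system is 6×6 and solved at most a few
hundred times per trajectory), step-halving when a full step increases the
residual norm, convergence when the max-abs residual falls below 1e−8
(applied component-wise to millimetre and radian entries alike, which
avoids inventing unit weights), at most 100 iterations. After convergence
one extra undamped Newton step "polishes" the iterate to machine
precision, which is why warm-started and cold-started trajectory solves
agree to better than 1e−9 on clean data. Trajectory solves warm-start each
sample from the previous solution; a per-sample failure is recorded as a
NaN gap marker rather than aborting the trajectory.

The working side must be given explicitly; for symmetric movements
(protrusion, opening) the package's convention is the right side.

## Condylar-path personalization

Per side, from tracked condyle trajectories:

* **Sagittal quadratic** `z = a·y² + b·y + c`, ordinary least squares on
  the (y, z) projection of the protrusive path. The **condylar
  inclination** is `atan(|dz/dy|)` at the rest position (the first
  sample's y unless given), measured against the z = 0 reference plane.
* **Horizontal line** `x = m·y + k`, least squares on the (y, x)
  projection of the *working-side* lateral-excursion path. The **Bennett
  angle** is `atan(|m|)`.
* **Clamped cubic NURBS** through the 3D protrusion samples: chord-length
  parameterization, knots by parameter averaging, least-squares control
  points, uniform weights by default (non-uniform weights are supported in
  evaluation and serialization). Control-point count is
  `max(4, ⌈N/5⌉)` capped at 25 — enough to follow a border path without
  chasing noise. Basis functions use the Cox–de Boor recursion with the
  0/0 → 0 convention and a closed final span so u = 1 is representable.

The inverse kinematics consumes the two scalar planar fits `f`, `g` (so
the path constraint stays a scalar function of the antero-posterior
coordinate y); the NURBS is the export/visualization representation.
Outside the fitted y-domain both fits are continued linearly from the
nearest endpoint with the endpoint slope, with a
`DomainExtrapolationWarning` — tracked motion only reaches the patient's
extreme position, and the solver legitimately probes slightly beyond it.

## Registration

Condyle centers are sphere-fit centers: an algebraic (linearized)
least-squares sphere refined by Gauss–Newton on the geometric residual
`|‖p − c‖ − r|`; coplanar inputs are rejected (the center is unconstrained
along the plane normal). Point-cloud alignment is Kabsch (SVD with the
determinant sign forced to +1) inside a trimmed point-to-point ICP: exact
nearest neighbours from a k-d tree, worst 10 % of pairs dropped,
convergence when the trimmed RMS improves by < 1e−6 mm, at most 50
iterations. A step that would increase the trimmed RMS keeps the
best-so-far transform and stops, so the reported RMS sequence is
non-increasing by construction. A final RMS above a quality threshold
produces a warning in the result, never an exception — a bad registration
is a result, not a crash. Point-to-plane ICP and rotation interpolation in
pose streams are out of scope; pose-stream lookups are nearest-sample.

Tracked jaw motion enters through the relative marker chain
`T_0↑ · T_cam↑⁻¹ · T_cam↓` applied to lower-marker-frame points: any
common (camera) motion cancels, which is load-bearing for handheld or
wobbling cameras and is property-tested with injected per-frame camera
transforms.

## Verification metrics

* **ATE**: mean Euclidean distance between index-aligned trajectories.
  Read as a plain (not squared) distance so the number carries millimetre
  units; a squared variant sits behind a flag. Length mismatches are
  errors — silently resampling would hide a protocol mistake.
* **Discrete Fréchet distance**: iterative Eiter–Mannila dynamic program,
  O(N·M) time, O(M) memory, no recursion. Unequal lengths are fine; no
  resampling is done.
* **Comparison protocol**: each movement is recorded from centric
  occlusion to the extreme position and back, twice; the
  distance-from-rest profile is segmented at its local extrema (optionally
  smoothed by a 3-sample moving average for noisy tracking) into
  forward/backward repetitions; each tracked/simulated segment pair is
  scored with the discrete Fréchet distance; per-direction averages are
  plain means over repetitions and the grand mean is the mean over all
  segments. Tracked and simulated trajectories are segmented at the *same*
  sample boundaries.

## Occlusion simulation

Tooth meshes become sphere clouds: vertices voxel-downsampled (default
spacing 0.5 mm, one sphere per occupied cell at the cell centroid, default
radius 0.3 mm — small enough to resolve cusp-scale contact on desk-scale
meshes; both configurable). Collision detection hashes upper-sphere
centers into a uniform grid with cell size twice the largest radius and
tests the 27-neighbourhood per posed lower sphere; the output is identical
to the all-pairs test (property-checked against an O(n²) oracle).
Interference beyond a clearance (default 0.01 mm) is resolved by bisecting
an added inferior (−Z) translation — a hinge-opening proxy — up to 1 mm;
deeper interference raises an error carrying the contact report. A
constrained re-solve that rotates about the hinge axis instead of
translating would be the physiological alternative; pure −Z was chosen for
predictability and is isolated in one function. Contacts are always
reported, even after successful adjustment.

## Synthetic patients: what they emulate, and what they don't

`generate_patient` draws anatomically plausible parameters from a seeded
generator: intercondylar width 100–120 mm, Bennett angle 5–20°, condylar
inclination 25–50°, condyle radius 8–12 mm, incisal point ~(0, 90–105,
−35–45) mm — textbook articulator ranges. True condylar paths pass
exactly through the rest condyles with a mild sagittal curvature
(−0.015 to −0.005 mm⁻¹). Movement schedules (protrusion 8 mm of condylar
advance, lateral excursions 3 mm with ~1.3°/mm of yaw, opening 10 mm with
2°/mm of pitch) are modest, clinically shaped choices; roll follows the
height constraint's fixed point, so simulated motion satisfies the inverse
model's constraints by construction. Measurement noise is isotropic
Gaussian per emitted point, independent across samples.

That noise model is deliberately simpler than real optical tracking, which
has anisotropic, distance-dependent, temporally correlated error, plus
calibration and registration biases; the synthetic skin surface is an
ellipsoid patch with a nose ridge, not a face scan; and no CT artifacts or
segmentation error are emulated. Passing the synthetic suite therefore
demonstrates the *mathematical* correctness and noise sensitivity of the
pipeline — forward/inverse consistency to machine precision, parameter
recovery to fractions of a degree at 0.1 mm noise, grand-mean Fréchet
around 1–2 mm at 0.5 mm noise (the regime of low-cost lab tracking) — not
clinical accuracy on real patients.

Default problem sizes in the tests and the acceptance script (6–12 samples
per half-cycle, 2 cycles, 10–100 seeds per study) were chosen as the
smallest sizes at which the statistics above are stable; all are plain
function arguments and scale up freely.

## Known limitations

* No muscle/force model: kinematics only.
* The Bennett fit is a straight line — no immediate side shift or curved
  (Fischer-angle) vertical component beyond what the planar fits capture.
* The IK working side is an explicit input; the model does not infer it
  from the motion.
* Sphere proxies approximate contact; exact triangle–triangle collision
  and prosthesis surface editing are out of scope.
* DICOM/CT processing, marker detection and camera calibration are
  upstream of this package: it consumes landmarks, meshes and pose
  streams as files.
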