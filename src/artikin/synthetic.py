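"""Ground-truth virtual patients and simulated measurement streams.

A virtual patient bundles everything a CT scan plus optical jaw tracking
would provide — landmark positions, articulator parameters, a known
condylar-path model per side, condyle surface geometry — generated from
anatomically plausible seeded distributions so that every downstream
module can be tested end to end without a scanner or camera.

The forward motion model mirrors the inverse kinematics exactly: the
working-side condyle advances along its true path (t_x and t_z slaved to
the path functions of the antero-posterior advance t_y), pitch and yaw
follow movement-specific schedules, and the roll angle is resolved from
the condyle-height constraint by fixed-point iteration.  Noise, when
requested, is isotropic Gaussian added independently to every emitted
point — a deliberately simple stand-in for optical tracking error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .articulator import (
    ARTICULATOR_FRAME,
    AnatomicalLandmarks,
    ArticulatorParameters,
    JawPose,
    jaw_pose_transform,
)
from .condylar_path import CondylarPathModel, fit_nurbs
from .errors import InvalidArgumentError
from .ik import condyle_height_rotation
from .registration import MarkerPoseStream
from .trajectory import Trajectory
from .transforms import FramedTransform, compose, invert, make_rotation, make_translation

MOVEMENTS = ("protrusion", "right_excursion", "left_excursion", "opening")
_MOVEMENT_INDEX = {m: i for i, m in enumerate(MOVEMENTS)}

#: per-movement schedules: (working side, condylar advance mm, pitch rad/mm,
#: yaw rad/mm).  Rates are modest textbook-scale values: protrusion pitches
#: the mandible slightly open as the condyles run down the eminence;
#: lateral excursions swing the jaw toward the working side; opening is a
#: hinge-dominated movement with a large pitch per mm of condylar advance.
_SCHEDULES = {
    "protrusion": ("right", 8.0, -0.006, 0.0),
    "right_excursion": ("right", 3.0, -0.004, -0.023),
    "left_excursion": ("left", 3.0, -0.004, 0.023),
    "opening": ("right", 10.0, -0.035, 0.0),
}

_SAMPLE_RATE = 100.0  # Hz


@dataclass(frozen=True)
class VirtualPatient:
    """Ground truth for one synthetic subject (articulator frame, mm)."""

    seed: int
    landmarks: AnatomicalLandmarks
    params: ArticulatorParameters
    true_paths: dict  # side -> CondylarPathModel
    condyle_radius: float
    noise_sigma: float = 0.0

    @property
    def bennett_angle(self) -> float:
        return self.true_paths["right"].bennett_angle

    @property
    def inclination_angle(self) -> float:
        return self.true_paths["right"].inclination_angle


@dataclass(frozen=True)
class MovementRecording:
    """Output of one simulated movement: trajectories plus the true poses."""

    movement: str
    working_side: str
    incisal: Trajectory
    condyle_right: Trajectory
    condyle_left: Trajectory
    poses: tuple  # ground-truth JawPose per sample
    noise_sigma: float


def _true_path(side: str, width: float, bennett_deg: float, inclination_deg: float,
               curvature: float, y_max: float) -> CondylarPathModel:
    """Analytic condylar path through the rest condyle (+/- w/2, 0, 0)."""
    x_rest = width / 2.0 if side == "right" else -width / 2.0
    m = np.tan(np.radians(bennett_deg)) * (1.0 if side == "right" else -1.0)
    b = -np.tan(np.radians(inclination_deg))
    a = curvature
    # rest at y = 0: c = x_rest - m*0, z(0) = 0
    model = CondylarPathModel(
        side=side,
        sagittal_coeffs=(a, b, 0.0),
        horizontal_coeffs=(m, x_rest),
        bennett_angle=bennett_deg,
        inclination_angle=inclination_deg,
        y_domain=(0.0, y_max),
    )
    ys = np.linspace(0.0, y_max, 40)
    pts = np.column_stack([m * ys + x_rest, ys, a * ys**2 + b * ys])
    nurbs = fit_nurbs(pts, n_ctrl=8)
    return CondylarPathModel(
        side=model.side,
        sagittal_coeffs=model.sagittal_coeffs,
        horizontal_coeffs=model.horizontal_coeffs,
        bennett_angle=model.bennett_angle,
        inclination_angle=model.inclination_angle,
        y_domain=model.y_domain,
        nurbs=nurbs,
    )


def generate_patient(seed: int, overrides: dict | None = None) -> VirtualPatient:
    """Draw an anatomically plausible virtual patient from a seeded RNG.

    Defaults: intercondylar width 100–120 mm, Bennett angle 5–20 deg,
    condylar inclination 25–50 deg, condyle radius 8–12 mm, incisal point
    at x = 0, y 90–105 mm anterior, z 35–45 mm inferior.  ``overrides``
    pins any of: ``intercondylar_width``, ``bennett_angle``,
    ``inclination_angle``, ``condyle_radius``, ``incisal_point``,
    ``sagittal_curvature``, ``anterior_point``.
    """
    rng = np.random.default_rng(seed)
    draws = {
        "intercondylar_width": rng.uniform(100.0, 120.0),
        "bennett_angle": rng.uniform(5.0, 20.0),
        "inclination_angle": rng.uniform(25.0, 50.0),
        "condyle_radius": rng.uniform(8.0, 12.0),
        "incisal_point": np.array([0.0, rng.uniform(90.0, 105.0), -rng.uniform(35.0, 45.0)]),
        "sagittal_curvature": rng.uniform(-0.015, -0.005),
        "anterior_point": None,
    }
    if overrides:
        unknown = set(overrides) - set(draws)
        if unknown:
            raise InvalidArgumentError(f"unknown patient overrides: {sorted(unknown)}")
        draws.update(overrides)
    width = float(draws["intercondylar_width"])
    if draws["anterior_point"] is None:
        draws["anterior_point"] = np.array([0.0, 80.0, 0.0])
    landmarks = AnatomicalLandmarks(
        condyle_right=np.array([width / 2.0, 0.0, 0.0]),
        condyle_left=np.array([-width / 2.0, 0.0, 0.0]),
        anterior_point=draws["anterior_point"],
        incisal_point=draws["incisal_point"],
        anterior_point_kind="infraorbital",
        frame=ARTICULATOR_FRAME,
    )
    params = ArticulatorParameters.symmetric(
        theta_sag=np.radians(float(draws["inclination_angle"])),
        theta1=np.radians(float(draws["bennett_angle"])),
        theta2=0.0,
        intercondylar_width=width,
    )
    y_max = max(s[1] for s in _SCHEDULES.values())
    paths = {
        side: _true_path(
            side, width,
            float(draws["bennett_angle"]), float(draws["inclination_angle"]),
            float(draws["sagittal_curvature"]), y_max,
        )
        for side in ("right", "left")
    }
    return VirtualPatient(
        seed=int(seed),
        landmarks=landmarks,
        params=params,
        true_paths=paths,
        condyle_radius=float(draws["condyle_radius"]),
    )


def _solve_roll(theta_x: float, theta_z: float, t: np.ndarray,
                c_work: np.ndarray, c_other: np.ndarray,
                work_is_right: bool) -> float:
    """Fixed point of the condyle-height roll constraint."""
    theta_y = 0.0
    for _ in range(100):
        pose = JawPose(theta_x=theta_x, theta_y=theta_y, theta_z=theta_z,
                       t_x=t[0], t_y=t[1], t_z=t[2], angle_bound=np.pi)
        posed_other = jaw_pose_transform(pose, c_work).apply(c_other)
        posed_work = c_work + t
        if work_is_right:
            target = condyle_height_rotation(posed_work, posed_other)
        else:
            target = condyle_height_rotation(posed_other, posed_work)
        if abs(target - theta_y) < 1e-14:
            return target
        theta_y = target
    return theta_y


def _advance_profile(s_max: float, n_samples: int, cycles: int) -> np.ndarray:
    """Triangular out-and-back advance: 0 -> s_max -> 0, repeated."""
    half = np.linspace(0.0, s_max, n_samples)
    cycle = np.concatenate([half, half[::-1][1:]])
    out = [np.array([0.0])]
    for _ in range(cycles):
        out.append(cycle[1:])
    return np.concatenate(out)


def simulate_movement(
    patient: VirtualPatient,
    movement: str,
    n_samples: int = 12,
    cycles: int = 2,
    noise_sigma: float = 0.0,
) -> MovementRecording:
    """Simulate one border movement from centric occlusion.

    The movement runs from CO to the extreme position and back,
    ``cycles`` times, with ``n_samples`` samples per half-cycle.  The
    working condyle advances along the patient's true path; pitch/yaw
    follow the movement schedule; roll satisfies the condyle-height
    constraint.  Gaussian noise of ``noise_sigma`` mm (seeded from the
    patient seed and the movement) is added independently to every
    emitted point of all three trajectories.
    """
    if movement not in _SCHEDULES:
        raise InvalidArgumentError(f"unknown movement {movement!r}; one of {MOVEMENTS}")
    if n_samples < 4:
        raise InvalidArgumentError("need n_samples >= 4 per half-cycle")
    if cycles < 1:
        raise InvalidArgumentError("cycles must be >= 1")
    side, s_max, pitch_rate, yaw_rate = _SCHEDULES[movement]
    lm = patient.landmarks
    c_work = lm.condyle(side)
    c_other = lm.condyle("left" if side == "right" else "right")
    path = patient.true_paths[side]
    x0, y0, z0 = c_work

    advances = _advance_profile(s_max, n_samples, cycles)
    n = advances.size
    times = np.arange(n) / _SAMPLE_RATE
    poses = []
    incisal = np.empty((n, 3))
    cond_r = np.empty((n, 3))
    cond_l = np.empty((n, 3))
    for i, s in enumerate(advances):
        fx, gz = path.evaluate(y0 + s)
        t = np.array([fx - x0, s, gz - z0])
        theta_x = pitch_rate * s
        theta_z = yaw_rate * s
        theta_y = _solve_roll(theta_x, theta_z, t, c_work, c_other, side == "right")
        pose = JawPose(theta_x=theta_x, theta_y=theta_y, theta_z=theta_z,
                       t_x=t[0], t_y=t[1], t_z=t[2], reference_side=side,
                       angle_bound=np.pi)
        poses.append(pose)
        transform = jaw_pose_transform(pose, c_work)
        incisal[i] = transform.apply(lm.incisal_point)
        posed_work = c_work + t
        posed_other = transform.apply(c_other)
        if side == "right":
            cond_r[i], cond_l[i] = posed_work, posed_other
        else:
            cond_l[i], cond_r[i] = posed_work, posed_other

    if noise_sigma > 0:
        rng = np.random.default_rng([patient.seed, _MOVEMENT_INDEX[movement], 1])
        incisal = incisal + rng.normal(0.0, noise_sigma, incisal.shape)
        cond_r = cond_r + rng.normal(0.0, noise_sigma, cond_r.shape)
        cond_l = cond_l + rng.normal(0.0, noise_sigma, cond_l.shape)

    def _traj(pts, what):
        return Trajectory(times, pts, frame=ARTICULATOR_FRAME, label=f"{what}/{movement}")

    return MovementRecording(
        movement=movement,
        working_side=side,
        incisal=_traj(incisal, "incisal"),
        condyle_right=_traj(cond_r, "right_condyle"),
        condyle_left=_traj(cond_l, "left_condyle"),
        poses=tuple(poses),
        noise_sigma=float(noise_sigma),
    )


def run_verification_study(
    patient: VirtualPatient,
    noise_sigma: float = 0.0,
    n_samples: int = 12,
    cycles: int = 2,
    movements: tuple = ("protrusion", "right_excursion"),
):
    """Tracked-versus-simulated condylar trajectory comparison protocol.

    For every movement in ``movements`` (each run CO -> extreme -> CO,
    ``cycles`` times): the mandibular motion is emitted as a synthetic
    dual-marker camera stream, the incisal point and both condyles are
    tracked back through the relative marker chain, and Gaussian noise of
    ``noise_sigma`` mm is added to every tracked point — these play the
    role of the optical measurement.  Per-side condylar-path models are
    fitted from the noisy condyle tracks (the lateral excursions are
    always simulated, since each side's Bennett line needs its own
    working-side data); inverse kinematics of the tracked incisal
    trajectory produces the simulated condyle trajectories; each movement
    is segmented into forward/backward repetitions (same sample
    boundaries for tracked and simulated); and every tracked/simulated
    segment pair is scored with the discrete Fréchet distance.

    Returns the :class:`~artikin.metrics.TrajectoryComparison` — per
    segment, per direction, and the grand mean, mirroring a
    movement-by-movement similarity table.
    """
    from .condylar_path import fit_condylar_path
    from .ik import trajectory_ik
    from .metrics import compare_movement, repetition_boundaries
    from .registration import track_landmark_trajectory

    lm_points = {
        "incisal": patient.landmarks.incisal_point,
        "right_condyle": patient.landmarks.condyle_right,
        "left_condyle": patient.landmarks.condyle_left,
    }

    def measure(mv: str) -> MovementRecording:
        rec = simulate_movement(patient, mv, n_samples=n_samples, cycles=cycles)
        ss = emit_marker_stream(patient, rec)
        rng = np.random.default_rng([patient.seed, _MOVEMENT_INDEX[mv], 2])
        tracked = {}
        for name, point in lm_points.items():
            traj = track_landmark_trajectory(
                ss.marker_point(point), ss.stream, ss.t_0_up,
                label=f"{name}/{mv}",
            )
            pts = traj.points
            if noise_sigma > 0:
                pts = pts + rng.normal(0.0, noise_sigma, pts.shape)
            tracked[name] = Trajectory(traj.t, pts, traj.frame, traj.label)
        return MovementRecording(
            movement=mv,
            working_side=rec.working_side,
            incisal=tracked["incisal"],
            condyle_right=tracked["right_condyle"],
            condyle_left=tracked["left_condyle"],
            poses=rec.poses,
            noise_sigma=float(noise_sigma),
        )

    needed = set(movements) | {"protrusion", "right_excursion", "left_excursion"}
    recordings = {mv: measure(mv) for mv in sorted(needed, key=MOVEMENTS.index)}
    paths = {
        "right": fit_condylar_path(
            recordings["protrusion"].condyle_right,
            recordings["right_excursion"].condyle_right,
            "right", rest_y=0.0,
        ),
        "left": fit_condylar_path(
            recordings["protrusion"].condyle_left,
            recordings["left_excursion"].condyle_left,
            "left", rest_y=0.0,
        ),
    }
    lm = patient.landmarks
    tracked: dict = {}
    simulated: dict = {}
    tol = max(1.0, 6.0 * noise_sigma)
    for mv in movements:
        rec = recordings[mv]
        sim_r, sim_l, sols = trajectory_ik(
            rec.incisal, lm, paths["right"], paths["left"], rec.working_side
        )
        segments = repetition_boundaries(
            rec.incisal, lm.incisal_point,
            start_tolerance=tol,
            smooth_window=3 if noise_sigma > 0 else 1,
            min_peak_distance=max(1, n_samples // 2),
        )
        for cond, meas, sim in (("right_condyle", rec.condyle_right, sim_r),
                                ("left_condyle", rec.condyle_left, sim_l)):
            for key, a, b in segments:
                label = f"{mv}/{cond}/{key}"
                t_seg = meas.slice(a, b, label=label)
                s_seg = sim.slice(a, b, label=label)
                if s_seg.has_gaps:
                    keep = ~np.isnan(s_seg.points).any(axis=1)
                    t_seg = Trajectory(t_seg.t[keep], t_seg.points[keep],
                                       t_seg.frame, label)
                    s_seg = Trajectory(s_seg.t[keep], s_seg.points[keep],
                                       s_seg.frame, label)
                tracked[label] = t_seg
                simulated[label] = s_seg
    return compare_movement(tracked, simulated)


# ---------------------------------------------------------------------------
# synthetic optical tracking


@dataclass(frozen=True)
class SyntheticMarkerStream:
    """Marker stream plus the registrations needed to consume it."""

    stream: MarkerPoseStream
    t_0_up: FramedTransform  # upper marker -> articulator
    t_low0: FramedTransform  # lower marker -> articulator (at rest)

    def marker_point(self, p_articulator) -> np.ndarray:
        """Lower-marker-frame coordinates of a mandible point given at rest."""
        return invert(self.t_low0).apply(np.asarray(p_articulator, dtype=float))


def _random_rigid(rng: np.random.Generator, max_angle: float, max_shift: float,
                  from_frame=None, to_frame=None) -> FramedTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle, max_angle)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    r = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    m = np.eye(4)
    m[:3, :3] = r
    m[:3, 3] = rng.uniform(-max_shift, max_shift, size=3)
    return FramedTransform(m, from_frame, to_frame)


def emit_marker_stream(
    patient: VirtualPatient,
    recording: MovementRecording,
    camera_wobble: str = "none",
) -> SyntheticMarkerStream:
    """Synthesize the dual-marker camera stream for a recorded movement.

    The upper marker is rigid with the skull, the lower marker rigid with
    the mandible; per-frame camera->marker transforms are emitted such
    that the relative chain ``T_0_up * inv(T_cam_up) * T_cam_low``
    reproduces the recording's mandibular motion exactly (the trajectories
    as emitted are noise-free; tracking noise belongs to the recording).
    ``camera_wobble='random_walk'`` superimposes a drifting camera pose,
    which the relative chain must cancel.
    """
    if camera_wobble not in ("none", "random_walk"):
        raise InvalidArgumentError(f"camera_wobble must be 'none' or 'random_walk', got {camera_wobble!r}")
    rng = np.random.default_rng([patient.seed, 7])
    t_0_up = _random_rigid(rng, np.radians(25.0), 60.0,
                           from_frame="marker_up", to_frame=ARTICULATOR_FRAME)
    t_low0 = _random_rigid(rng, np.radians(25.0), 60.0,
                           from_frame="marker_low", to_frame=ARTICULATOR_FRAME)
    c_work = patient.landmarks.condyle(recording.working_side)
    wob_rng = np.random.default_rng([patient.seed, 8])
    cam = FramedTransform(np.eye(4), ARTICULATOR_FRAME, "camera")
    samples = []
    for i, pose in enumerate(recording.poses):
        if camera_wobble == "random_walk":
            step = _random_rigid(wob_rng, np.radians(0.2), 0.5,
                                 from_frame="camera", to_frame="camera")
            cam = FramedTransform((step.matrix @ cam.matrix),
                                  ARTICULATOR_FRAME, "camera")
        t_mand = jaw_pose_transform(pose, c_work)  # articulator -> articulator (posed)
        t_cam_up = FramedTransform(cam.matrix @ t_0_up.matrix, "marker_up", "camera")
        # lower marker -> camera: marker -> rest articulator -> posed -> camera
        low_chain = cam.matrix @ t_mand.matrix @ t_low0.matrix
        t_cam_low = FramedTransform(low_chain, "marker_low", "camera")
        samples.append((float(recording.incisal.t[i]), t_cam_up, t_cam_low))
    return SyntheticMarkerStream(
        stream=MarkerPoseStream(tuple(samples)),
        t_0_up=t_0_up,
        t_low0=t_low0,
    )


# ---------------------------------------------------------------------------
# synthetic geometry


def sample_condyle_surface(
    patient: VirtualPatient, side: str, n_points: int, noise_sigma: float = 0.0
) -> np.ndarray:
    """Seeded samples on the superior hemisphere of a condyle sphere."""
    if n_points < 4:
        raise InvalidArgumentError("need n_points >= 4 for a sphere fit")
    if side not in ("right", "left"):
        raise InvalidArgumentError(f"side must be 'right' or 'left', got {side!r}")
    rng = np.random.default_rng([patient.seed, 11, 0 if side == "right" else 1])
    center = patient.landmarks.condyle(side)
    dirs = rng.normal(size=(n_points, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs[:, 2] = np.abs(dirs[:, 2])  # superior hemisphere
    pts = center + patient.condyle_radius * dirs
    if noise_sigma > 0:
        pts = pts + rng.normal(0.0, noise_sigma, pts.shape)
    return pts


def sample_skin_clouds(
    patient: VirtualPatient,
    n_points: int,
    true_transform: FramedTransform,
    noise_sigma: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A face-like source cloud and its transformed, noisy copy.

    The surface is an anterior ellipsoid patch with a nose-ridge bump —
    enough non-symmetric relief for ICP to lock onto.  ``dst`` is
    ``true_transform`` applied to ``src`` plus Gaussian noise.
    """
    if n_points < 10:
        raise InvalidArgumentError("need n_points >= 10")
    rng = np.random.default_rng([patient.seed, 13])
    a, b, c = 65.0, 90.0, 85.0  # face ellipsoid semi-axes (mm)
    theta = rng.uniform(-1.1, 1.1, n_points)  # azimuth off the facial midline
    phi = rng.uniform(-0.9, 1.0, n_points)  # elevation
    x = a * np.cos(phi) * np.sin(theta)
    y = b * np.cos(phi) * np.cos(theta)  # anterior
    z = c * np.sin(phi)
    src = np.column_stack([x, y, z])
    # nose ridge along the midline
    bump = 12.0 * np.exp(-((x / 9.0) ** 2) - (((z + 10.0) / 16.0) ** 2))
    src[:, 1] += bump
    dst = true_transform.apply(src)
    if noise_sigma > 0:
        dst = dst + rng.normal(0.0, noise_sigma, dst.shape)
    return src, dst
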