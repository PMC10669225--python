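"""6-DOF mandibular inverse kinematics under condylar-path constraints.

Given a measured incisal-edge point, the mandible's pose
(theta_x, theta_y, theta_z, t_x, t_y, t_z) about the working-side condyle
is found from six constraints:

* three place the posed incisal point at the target;
* two tie the translation to the personalized condylar path,
  ``t_x = f(y0 + t_y) - x0`` and ``t_z = g(y0 + t_y) - z0`` where
  (x0, y0, z0) is the rest position of the working condyle;
* one couples the roll angle theta_y to the height difference of the two
  posed condyles.

The square system is solved by damped Newton–Raphson with a
finite-difference Jacobian.  Running the solver over a whole incisal
trajectory (warm-starting each sample from the previous solution) yields
the simulated trajectories of both condyles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .articulator import AnatomicalLandmarks, JawPose, apply_jaw_pose
from .condylar_path import CondylarPathModel, evaluate_path
from .errors import DegenerateGeometryError, InvalidArgumentError, SolverFailure
from .trajectory import Trajectory

#: convergence tolerance on the max-abs residual (mm and rad component-wise)
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 100
_FD_STEP = 1e-6


@dataclass(frozen=True)
class IKSolution:
    """Solver outcome for one incisal target."""

    pose: JawPose
    residual_norm: float
    iterations: int
    converged: bool


def condyle_height_rotation(right_condyle_after, left_condyle_after) -> float:
    """Roll angle implied by the posed condyle positions.

    ``atan2(zL' - zR', xL' - xR')`` wrapped into (-pi/2, pi/2] — the angle
    of the intercondylar axis against the horizontal plane, insensitive to
    which way the axis is traversed.
    """
    r = np.asarray(right_condyle_after, dtype=float)
    l = np.asarray(left_condyle_after, dtype=float)
    dx = l[0] - r[0]
    dz = l[2] - r[2]
    if abs(dx) <= 1e-6:
        raise DegenerateGeometryError(
            f"condyles coincide in x (|dx| = {abs(dx):.2e} mm); roll undefined"
        )
    theta = np.arctan2(dz, dx)
    # wrap to (-pi/2, pi/2]
    while theta <= -np.pi / 2:
        theta += np.pi
    while theta > np.pi / 2:
        theta -= np.pi
    return float(theta)


def ik_residuals(
    pose: JawPose,
    incisal_target,
    landmarks: AnatomicalLandmarks,
    path_right: CondylarPathModel,
    path_left: CondylarPathModel,
    working_side: str,
) -> np.ndarray:
    """Six-component constraint residual at a candidate pose.

    Components 0-2: posed incisal point minus target (mm); 3-4: condylar
    path constraints on t_x and t_z (mm); 5: theta_y minus the roll implied
    by the posed condyles (rad).
    """
    target = np.asarray(incisal_target, dtype=float)
    if target.shape != (3,) or not np.all(np.isfinite(target)):
        raise InvalidArgumentError(f"incisal target must be a finite 3-vector, got {incisal_target}")
    c_work = landmarks.condyle(working_side)
    path = path_right if working_side == "right" else path_left
    x0, y0, z0 = c_work

    q = apply_jaw_pose(pose, c_work, landmarks.incisal_point)
    r = np.empty(6)
    r[0:3] = q - target

    fx, gz = evaluate_path(path, y0 + pose.t_y)
    r[3] = pose.t_x - (fx - x0)
    r[4] = pose.t_z - (gz - z0)

    t = np.array([pose.t_x, pose.t_y, pose.t_z])
    posed_work = c_work + t  # the reference condyle only translates
    other_side = "left" if working_side == "right" else "right"
    posed_other = apply_jaw_pose(pose, c_work, landmarks.condyle(other_side))
    posed = {working_side: posed_work, other_side: posed_other}
    r[5] = pose.theta_y - condyle_height_rotation(posed["right"], posed["left"])
    return r


def solve_pose(
    incisal_target,
    landmarks: AnatomicalLandmarks,
    path_right: CondylarPathModel,
    path_left: CondylarPathModel,
    working_side: str,
    initial_guess: JawPose | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> IKSolution:
    """Damped Newton–Raphson solve of the six IK constraints.

    The Jacobian is formed by central finite differences (step 1e-6 per
    component); a full Newton step that increases the residual norm is
    halved until it does not (or the step becomes negligible).  Raises
    :class:`SolverFailure` (carrying the last iterate) on non-convergence.
    """
    if initial_guess is None:
        initial_guess = JawPose(reference_side=working_side)

    def residual(x: np.ndarray) -> np.ndarray:
        # interior iterates may wander beyond physiological angles;
        # only the final pose is bound-checked
        pose = JawPose.from_vector(x, reference_side=working_side, angle_bound=np.inf)
        return ik_residuals(pose, incisal_target, landmarks, path_right, path_left, working_side)

    def jacobian(x: np.ndarray) -> np.ndarray:
        jac = np.empty((6, 6))
        for col in range(6):
            dx = np.zeros(6)
            dx[col] = _FD_STEP
            jac[:, col] = (residual(x + dx) - residual(x - dx)) / (2 * _FD_STEP)
        return jac

    def newton_step(x: np.ndarray, r: np.ndarray) -> np.ndarray:
        jac = jacobian(x)
        try:
            return np.linalg.solve(jac, -r)
        except np.linalg.LinAlgError:
            return np.linalg.lstsq(jac, -r, rcond=None)[0]

    x = initial_guess.vector
    r = residual(x)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        if np.max(np.abs(r)) < tol:
            # one polishing Newton step: quadratic convergence takes the
            # iterate to machine precision, so warm- and cold-started
            # solves agree far below the tolerance
            x_pol = x + newton_step(x, r)
            r_pol = residual(x_pol)
            if np.linalg.norm(r_pol) < np.linalg.norm(r):
                x, r = x_pol, r_pol
            break
        step = newton_step(x, r)
        # damping by step-halving
        alpha = 1.0
        base = np.linalg.norm(r)
        while alpha > 1e-6:
            r_new = residual(x + alpha * step)
            if np.linalg.norm(r_new) < base or np.max(np.abs(r_new)) < tol:
                break
            alpha /= 2.0
        x = x + alpha * step
        r = residual(x)
    norm = float(np.max(np.abs(r)))
    converged = norm < tol
    if not converged:
        raise SolverFailure(
            f"IK did not converge in {iterations} iterations "
            f"(max-abs residual {norm:.3e})",
            last_pose=JawPose.from_vector(x, reference_side=working_side,
                                          angle_bound=np.inf),
            residual=r,
            iterations=iterations,
        )
    # pitch and yaw are only defined modulo a full turn; theta_y is already
    # pinned to (-pi/2, pi/2] by the roll constraint
    x[0] = np.arctan2(np.sin(x[0]), np.cos(x[0]))
    x[2] = np.arctan2(np.sin(x[2]), np.cos(x[2]))
    pose = JawPose.from_vector(x, reference_side=working_side, angle_bound=np.pi)
    return IKSolution(pose=pose, residual_norm=norm, iterations=iterations, converged=True)


def trajectory_ik(
    incisal_traj: Trajectory,
    landmarks: AnatomicalLandmarks,
    path_right: CondylarPathModel,
    path_left: CondylarPathModel,
    working_side: str,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[Trajectory, Trajectory, list[IKSolution | None]]:
    """Per-sample IK over a whole incisal trajectory.

    Each sample is warm-started from the previous solution; the solved
    poses are applied to the rest condyle centers to produce the simulated
    right and left condyle trajectories.  A per-sample solver failure is
    recorded as ``None`` in the solutions list and a NaN gap marker in the
    trajectories.
    """
    if incisal_traj.frame != landmarks.frame:
        raise InvalidArgumentError(
            f"incisal trajectory frame {incisal_traj.frame!r} does not match "
            f"landmarks frame {landmarks.frame!r}"
        )
    n = len(incisal_traj)
    right = np.full((n, 3), np.nan)
    left = np.full((n, 3), np.nan)
    solutions: list[IKSolution | None] = []
    guess: JawPose | None = None
    c_work = landmarks.condyle(working_side)
    for i in range(n):
        target = incisal_traj.points[i]
        if np.isnan(target).any():
            solutions.append(None)
            guess = None
            continue
        try:
            sol = solve_pose(
                target, landmarks, path_right, path_left, working_side,
                initial_guess=guess, tol=tol, max_iter=max_iter,
            )
        except SolverFailure:
            solutions.append(None)
            guess = None
            continue
        solutions.append(sol)
        guess = sol.pose
        right[i] = apply_jaw_pose(sol.pose, c_work, landmarks.condyle_right)
        left[i] = apply_jaw_pose(sol.pose, c_work, landmarks.condyle_left)
    gaps = any(s is None for s in solutions)
    label = incisal_traj.label
    traj_r = Trajectory(incisal_traj.t.copy(), right, incisal_traj.frame,
                        label=_relabel(label, "right_condyle"), allow_gaps=gaps)
    traj_l = Trajectory(incisal_traj.t.copy(), left, incisal_traj.frame,
                        label=_relabel(label, "left_condyle"), allow_gaps=gaps)
    return traj_r, traj_l, solutions


def _relabel(label: str, prefix: str) -> str:
    return f"{prefix}/{label}" if label else prefix
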