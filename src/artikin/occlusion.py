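"""Dynamic occlusion playback with sphere-proxy collision handling.

Tooth surfaces are approximated by clouds of small spheres (one per
voxel-downsampled mesh vertex).  During playback the incisal point is
driven along a guidance path, the mandibular pose is solved by inverse
kinematics at every sample, the posed lower proxies are tested against
the upper proxies, and any interference beyond a clearance threshold is
resolved by translating the mandible inferiorly (a hinge-opening proxy)
just far enough to clear.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .articulator import AnatomicalLandmarks, JawPose, apply_jaw_pose
from .condylar_path import CondylarPathModel
from .errors import (
    InvalidArgumentError,
    SolverFailure,
    UnresolvableInterferenceError,
)
from .ik import IKSolution, solve_pose
from .trajectory import Trajectory

DEFAULT_CLEARANCE = 0.01  # mm
MAX_ADJUSTMENT = 1.0  # mm of inferior translation before giving up
DEFAULT_PROXY_RADIUS = 0.3  # mm
DEFAULT_PROXY_SPACING = 0.5  # mm


@dataclass(frozen=True)
class SphereCloud:
    """Collision proxy: sphere centers (mm) with per-sphere radii."""

    centers: np.ndarray
    radii: np.ndarray
    source: str = "upper"

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        r = np.asarray(self.radii, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3 or not np.all(np.isfinite(c)):
            raise InvalidArgumentError("centers must be finite (N,3)")
        if r.ndim == 0:
            r = np.full(c.shape[0], float(r))
        if r.shape != (c.shape[0],) or np.any(r <= 0) or not np.all(np.isfinite(r)):
            raise InvalidArgumentError("radii must be positive, one per sphere (or scalar)")
        if self.source not in ("upper", "lower"):
            raise InvalidArgumentError(f"source must be 'upper' or 'lower', got {self.source!r}")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "radii", r)

    def __len__(self):
        return self.centers.shape[0]


@dataclass(frozen=True)
class ContactReport:
    """Colliding sphere pairs at one playback frame."""

    frame_index: int
    pairs: tuple  # (upper_index, lower_index, penetration_mm)
    max_penetration: float

    def __post_init__(self):
        for _, _, pen in self.pairs:
            if pen <= 0:
                raise InvalidArgumentError("reported pairs must have positive penetration")

    @property
    def n_contacts(self) -> int:
        return len(self.pairs)


def mesh_to_sphere_proxies(
    mesh,
    spacing: float = DEFAULT_PROXY_SPACING,
    radius: float = DEFAULT_PROXY_RADIUS,
    source: str = "upper",
) -> SphereCloud:
    """Voxel-downsample mesh vertices into a sphere cloud.

    One sphere of the given radius is placed at the centroid of the
    vertices in each occupied cell of a cubic grid with the given spacing.
    """
    if spacing <= 0 or radius <= 0:
        raise InvalidArgumentError("spacing and radius must be > 0")
    verts = np.asarray(getattr(mesh, "vertices", mesh), dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 3 or verts.shape[0] == 0:
        raise InvalidArgumentError("mesh has no vertices")
    cells = np.floor(verts / spacing).astype(np.int64)
    _, inverse = np.unique(cells, axis=0, return_inverse=True)
    n_cells = inverse.max() + 1
    sums = np.zeros((n_cells, 3))
    counts = np.zeros(n_cells)
    np.add.at(sums, inverse, verts)
    np.add.at(counts, inverse, 1.0)
    centers = sums / counts[:, None]
    return SphereCloud(centers=centers, radii=np.full(n_cells, float(radius)), source=source)


def _posed_lower(lower: SphereCloud, pose: JawPose | None, ref_condyle) -> np.ndarray:
    if pose is None:
        return lower.centers
    if pose.translation_only():
        return lower.centers + np.array([pose.t_x, pose.t_y, pose.t_z])
    if ref_condyle is None:
        raise InvalidArgumentError("ref_condyle required to apply a rotating lower pose")
    return apply_jaw_pose(pose, ref_condyle, lower.centers)


def _spatial_hash(centers: np.ndarray, cell: float) -> dict:
    grid: dict[tuple, list[int]] = {}
    keys = np.floor(centers / cell).astype(np.int64)
    for i, key in enumerate(map(tuple, keys)):
        grid.setdefault(key, []).append(i)
    return grid


def detect_collisions(
    upper: SphereCloud,
    lower: SphereCloud,
    lower_pose: JawPose | None = None,
    ref_condyle=None,
    frame_index: int = 0,
) -> ContactReport:
    """All interfering sphere pairs between the upper cloud and the posed
    lower cloud.

    The lower centers are mapped through ``lower_pose`` about
    ``ref_condyle`` (identity if omitted); a pair is reported when the
    center distance falls below the radius sum, with penetration depth
    ``(r_u + r_l) - distance``.  Candidate pairs come from a uniform
    spatial hash with cell size twice the largest radius; the output is
    identical to the all-pairs test.
    """
    centers_l = _posed_lower(lower, lower_pose, ref_condyle)
    r_max = float(max(upper.radii.max(), lower.radii.max()))
    cell = 2.0 * r_max
    grid = _spatial_hash(upper.centers, cell)
    pairs = []
    max_pen = 0.0
    keys_l = np.floor(centers_l / cell).astype(np.int64)
    for li in range(centers_l.shape[0]):
        kx, ky, kz = keys_l[li]
        cl = centers_l[li]
        rl = lower.radii[li]
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    bucket = grid.get((kx + dx, ky + dy, kz + dz))
                    if not bucket:
                        continue
                    for ui in bucket:
                        d = np.linalg.norm(upper.centers[ui] - cl)
                        pen = (upper.radii[ui] + rl) - d
                        if pen > 0:
                            pairs.append((ui, li, float(pen)))
                            if pen > max_pen:
                                max_pen = float(pen)
    pairs.sort(key=lambda p: (p[0], p[1]))
    return ContactReport(frame_index=frame_index, pairs=tuple(pairs), max_penetration=max_pen)


def detect_collisions_bruteforce(
    upper: SphereCloud, lower: SphereCloud,
    lower_pose: JawPose | None = None, ref_condyle=None, frame_index: int = 0,
) -> ContactReport:
    """All-pairs O(n^2) reference implementation of :func:`detect_collisions`."""
    centers_l = _posed_lower(lower, lower_pose, ref_condyle)
    diff = upper.centers[:, None, :] - centers_l[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    pen = (upper.radii[:, None] + lower.radii[None, :]) - dist
    ui, li = np.where(pen > 0)
    pairs = tuple(sorted((int(u), int(l), float(pen[u, l])) for u, l in zip(ui, li)))
    max_pen = float(max((p[2] for p in pairs), default=0.0))
    return ContactReport(frame_index=frame_index, pairs=pairs, max_penetration=max_pen)


def adjust_motion_path(
    pose: JawPose,
    contacts: ContactReport,
    upper: SphereCloud,
    lower: SphereCloud,
    ref_condyle,
    clearance: float = DEFAULT_CLEARANCE,
    max_adjustment: float = MAX_ADJUSTMENT,
    tol: float = 1e-4,
) -> JawPose:
    """Clear interference by adding inferior (-Z) translation to the pose.

    Bisection finds the smallest extra drop (within ``max_adjustment`` mm)
    at which the maximum penetration falls to the clearance; the returned
    pose carries the applied drop in its ``adjustment`` field.  Raises
    :class:`UnresolvableInterferenceError` if even the full budget cannot
    clear the contact.
    """
    if contacts.n_contacts == 0:
        raise InvalidArgumentError("adjust_motion_path requires a non-empty contact report")
    if contacts.max_penetration <= clearance:
        return replace(pose, adjustment=0.0)

    def max_pen(drop: float) -> float:
        adjusted = replace(pose, t_z=pose.t_z - drop)
        rep = detect_collisions(upper, lower, adjusted, ref_condyle,
                                frame_index=contacts.frame_index)
        return rep.max_penetration

    lo, hi = 0.0, max_adjustment
    if max_pen(hi) > clearance:
        raise UnresolvableInterferenceError(
            f"interference of {contacts.max_penetration:.3f} mm not cleared by "
            f"{max_adjustment:.2f} mm of inferior adjustment",
            report=contacts,
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if max_pen(mid) > clearance:
            lo = mid
        else:
            hi = mid
    return replace(pose, t_z=pose.t_z - hi, adjustment=hi)


def playback(
    incisal_guidance: Trajectory,
    landmarks: AnatomicalLandmarks,
    path_right: CondylarPathModel,
    path_left: CondylarPathModel,
    working_side: str,
    upper: SphereCloud | None = None,
    lower: SphereCloud | None = None,
    clearance: float = DEFAULT_CLEARANCE,
) -> tuple[list[JawPose | None], list[ContactReport | None]]:
    """Occlusal playback along an incisal guidance path.

    For every guidance sample the mandibular pose is solved by IK
    (warm-started), collisions between the proxy clouds are detected, and
    interference beyond the clearance is resolved with
    :func:`adjust_motion_path` before the frame is recorded.  With no
    proxy clouds the result degenerates to plain trajectory IK (empty
    contact reports).  A per-sample IK failure is recorded as ``None`` in
    both outputs.
    """
    c_work = landmarks.condyle(working_side)
    poses: list[JawPose | None] = []
    contacts: list[ContactReport | None] = []
    guess: JawPose | None = None
    for i in range(len(incisal_guidance)):
        target = incisal_guidance.points[i]
        try:
            sol: IKSolution = solve_pose(
                target, landmarks, path_right, path_left, working_side,
                initial_guess=guess,
            )
        except SolverFailure:
            poses.append(None)
            contacts.append(None)
            guess = None
            continue
        pose = sol.pose
        guess = pose
        if upper is None or lower is None:
            poses.append(pose)
            contacts.append(ContactReport(frame_index=i, pairs=(), max_penetration=0.0))
            continue
        report = detect_collisions(upper, lower, pose, c_work, frame_index=i)
        if report.max_penetration > clearance:
            pose = adjust_motion_path(pose, report, upper, lower, c_work,
                                      clearance=clearance)
            report = detect_collisions(upper, lower, pose, c_work, frame_index=i)
        poses.append(pose)
        contacts.append(report)  # contacts are reported even after adjustment
    return poses, contacts
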