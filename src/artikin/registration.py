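"""Virtual facebow and rigid registration.

This module replaces the mechanical facebow transfer: the articulator
frame is derived from three CT landmarks (the two condyle centers —
obtained by sphere-fitting the near-spherical condyle surfaces — and an
anterior point selecting the Frankfurt or Camper reference plane), and
tracked marker data is brought into that frame by composing the
camera/marker transform chain.  Point-cloud alignment (face scan to CT
skin) uses Kabsch for corresponded sets and trimmed point-to-point ICP
for raw clouds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .articulator import ARTICULATOR_FRAME
from .errors import (
    DegenerateGeometryError,
    FrameMismatchError,
    InvalidArgumentError,
    RegistrationQualityWarning,
)
from .trajectory import Trajectory
from .transforms import FramedTransform, compose, invert

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# condyle sphere fitting


@dataclass(frozen=True)
class SphereFitResult:
    """Least-squares sphere: center (mm), radius (mm), RMS of |dist - r|."""

    center: np.ndarray
    radius: float
    rms_error: float
    n_points: int

    def __post_init__(self):
        if self.radius <= 0 or self.rms_error < 0:
            raise InvalidArgumentError("sphere fit requires radius > 0 and rms >= 0")


def fit_sphere(points) -> SphereFitResult:
    """Fit a sphere to >= 4 non-coplanar points.

    An algebraic (linearized) least-squares solution provides the start;
    Gauss–Newton on the geometric residual ``|p - c| - r`` refines it.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidArgumentError(f"points must be (N,3), got {pts.shape}")
    if pts.shape[0] < 4:
        raise DegenerateGeometryError(f"sphere fit needs >= 4 points, got {pts.shape[0]}")
    # |p|^2 = 2 c.p + (r^2 - |c|^2): linear in (c, k)
    design = np.column_stack([2 * pts, np.ones(pts.shape[0])])
    rhs = np.sum(pts**2, axis=1)
    # coplanar points leave the center unconstrained along the plane normal
    sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("points are coplanar or otherwise degenerate for a sphere fit")
    sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    c0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + c0 @ c0, 1e-12)))

    def geom_residual(x):
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    refined = least_squares(geom_residual, np.r_[c0, r0], method="lm")
    c, r = refined.x[:3], float(refined.x[3])
    rms = float(np.sqrt(np.mean(geom_residual(refined.x) ** 2)))
    if r <= 0:
        raise DegenerateGeometryError("sphere fit collapsed to non-positive radius")
    return SphereFitResult(center=c, radius=r, rms_error=rms, n_points=pts.shape[0])


# ---------------------------------------------------------------------------
# reference plane / articulator frame


@dataclass(frozen=True)
class ReferencePlane:
    """Cranial reference plane (Frankfurt or Camper) in the source frame."""

    kind: str
    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        if self.kind not in ("frankfurt", "camper"):
            raise InvalidArgumentError(f"plane kind must be 'frankfurt' or 'camper', got {self.kind!r}")
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-12:
            raise InvalidArgumentError("plane normal must be a unit vector")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "normal", n)

    def signed_distance(self, p) -> float:
        return float((np.asarray(p, dtype=float) - self.origin) @ self.normal)


def build_articulator_frame(
    condyle_right,
    condyle_left,
    anterior_point,
    kind: str = "frankfurt",
    source_frame: str = "ct",
    up_hint=(0.0, 0.0, 1.0),
) -> tuple[FramedTransform, ReferencePlane]:
    """Articulator frame from the three facebow reference points.

    The hinge axis through the two condyle centers becomes +X (toward the
    right condyle) with the origin at its midpoint; the reference plane
    through all three landmarks becomes z = 0 with +Z chosen so the
    anterior landmark lies at positive y (anterior).  Returns the rigid
    transform mapping source (CT) coordinates into the articulator frame,
    plus the plane in source coordinates.
    """
    cr = np.asarray(condyle_right, dtype=float)
    cl = np.asarray(condyle_left, dtype=float)
    ant = np.asarray(anterior_point, dtype=float)
    axis = cr - cl
    width = np.linalg.norm(axis)
    if width < 1.0:
        raise DegenerateGeometryError("condyle centers coincide; hinge axis undefined")
    x_hat = axis / width
    mid = 0.5 * (cr + cl)
    in_plane = ant - mid
    normal = np.cross(x_hat, in_plane)
    nn = np.linalg.norm(normal)
    if nn < 1e-9 or 0.5 * nn * width <= 1.0:
        raise DegenerateGeometryError("anterior point collinear with the condyles")
    z_hat = normal / nn
    y_hat = np.cross(z_hat, x_hat)
    if y_hat @ in_plane < 0:  # anterior must have positive y
        z_hat = -z_hat
        y_hat = -y_hat
    if z_hat @ np.asarray(up_hint, dtype=float) < 0:
        logger.warning(
            "articulator +Z (superior, from the anterior-point convention) "
            "opposes the provided up-hint; check landmark left/right labels"
        )
    rot = np.vstack([x_hat, y_hat, z_hat])
    m = np.eye(4)
    m[:3, :3] = rot
    m[:3, 3] = -rot @ mid
    t = FramedTransform(m, from_frame=source_frame, to_frame=ARTICULATOR_FRAME)
    plane = ReferencePlane(kind=kind, origin=mid, normal=z_hat)
    return t, plane


# ---------------------------------------------------------------------------
# Kabsch + ICP


def kabsch_align(src, dst, source_frame: str | None = None, target_frame: str | None = None) -> FramedTransform:
    """Least-squares rigid transform mapping corresponded ``src`` onto ``dst``.

    SVD-based with the determinant sign corrected, so the result is always
    a proper rotation even for reflection-like correspondences.
    """
    s = np.asarray(src, dtype=float)
    d = np.asarray(dst, dtype=float)
    if s.shape != d.shape or s.ndim != 2 or s.shape[1] != 3:
        raise InvalidArgumentError(f"src and dst must be equal-shaped (N,3), got {s.shape} vs {d.shape}")
    if s.shape[0] < 3:
        raise DegenerateGeometryError("Kabsch needs >= 3 point pairs")
    sc = s - s.mean(axis=0)
    dc = d - d.mean(axis=0)
    sv = np.linalg.svd(sc, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError("source points are collinear; rotation underdetermined")
    h = sc.T @ dc
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, sign]) @ u.T
    t = d.mean(axis=0) - r @ s.mean(axis=0)
    m = np.eye(4)
    m[:3, :3] = r
    m[:3, 3] = t
    return FramedTransform(m, from_frame=source_frame, to_frame=target_frame)


@dataclass(frozen=True)
class ICPResult:
    transform: FramedTransform
    rms: float
    iterations: int
    rms_history: tuple[float, ...]
    quality_ok: bool

    def __iter__(self):
        # allow (transform, rms, iterations) unpacking
        return iter((self.transform, self.rms, self.iterations))


def icp_register(
    src_cloud,
    dst_cloud,
    init: FramedTransform | None = None,
    max_iterations: int = 50,
    tol: float = 1e-6,
    trim_fraction: float = 0.10,
    quality_threshold: float = 5.0,
) -> ICPResult:
    """Trimmed point-to-point ICP from ``src_cloud`` onto ``dst_cloud``.

    Each iteration finds exact Euclidean nearest neighbours (k-d tree),
    drops the worst ``trim_fraction`` of pairs and realigns with Kabsch;
    iteration stops when the trimmed RMS improves by less than ``tol`` mm.
    The reported RMS sequence is non-increasing (a step that would raise
    it keeps the previous transform and stops).  A final RMS above
    ``quality_threshold`` raises a :class:`RegistrationQualityWarning`
    (warning, not an exception) and sets ``quality_ok=False``.
    """
    s = np.asarray(src_cloud, dtype=float)
    d = np.asarray(dst_cloud, dtype=float)
    if s.shape[0] < 10 or d.shape[0] < 10:
        raise InvalidArgumentError("ICP needs both clouds to have >= 10 points")
    current = init if init is not None else FramedTransform(np.eye(4))
    tree = cKDTree(d)
    n_keep = max(3, int(np.ceil(s.shape[0] * (1.0 - trim_fraction))))

    def trimmed_rms(transform):
        moved = transform.apply(s)
        dist, idx = tree.query(moved)
        order = np.argsort(dist)[:n_keep]
        return float(np.sqrt(np.mean(dist[order] ** 2))), moved, idx, order

    best_rms, moved, idx, order = trimmed_rms(current)
    history = [best_rms]
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        step = kabsch_align(moved[order], d[idx[order]])
        candidate = compose(step, current)
        rms, m2, i2, o2 = trimmed_rms(candidate)
        if rms >= best_rms:  # would not improve: keep the best-so-far
            break
        improved = best_rms - rms
        current, best_rms, moved, idx, order = candidate, rms, m2, i2, o2
        history.append(best_rms)
        if improved < tol:
            break
    quality_ok = best_rms <= quality_threshold
    if not quality_ok:
        warnings.warn(
            f"ICP finished with RMS {best_rms:.3f} mm above the quality "
            f"threshold {quality_threshold:.3f} mm; clouds may not overlap",
            RegistrationQualityWarning,
            stacklevel=2,
        )
    current = FramedTransform(current.matrix, init.from_frame if init else None,
                              init.to_frame if init else None)
    return ICPResult(current, best_rms, iterations, tuple(history), quality_ok)


# ---------------------------------------------------------------------------
# marker / camera transform chain


@dataclass(frozen=True)
class MarkerPoseStream:
    """Time series of camera->marker transforms for the two trackers.

    ``samples`` is a sequence of ``(t, T_cam_up, T_cam_low)`` with strictly
    increasing timestamps; each transform maps marker coordinates into the
    camera frame.
    """

    samples: tuple

    def __post_init__(self):
        samples = tuple(self.samples)
        times = [s[0] for s in samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidArgumentError("marker stream timestamps must be strictly increasing")
        for _, t_up, t_low in samples:
            if not isinstance(t_up, FramedTransform) or not isinstance(t_low, FramedTransform):
                raise InvalidArgumentError("marker stream entries must be FramedTransforms")
        object.__setattr__(self, "samples", samples)

    def __len__(self):
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.array([s[0] for s in self.samples])

    def nearest(self, t: float):
        """Nearest-sample lookup (rotation interpolation is out of scope)."""
        if not self.samples:
            raise InvalidArgumentError("empty marker stream")
        times = self.times
        if t < times[0] - 1e-9 or t > times[-1] + 1e-9:
            raise InvalidArgumentError(
                f"t={t} outside stream time range [{times[0]}, {times[-1]}]"
            )
        return self.samples[int(np.argmin(np.abs(times - t)))]


def lower_point_in_articulator(
    p_low,
    t: float,
    stream: MarkerPoseStream,
    t_0_up: FramedTransform,
) -> np.ndarray:
    """Articulator-frame position of a lower-marker-frame point at time t.

    Composes ``T_0_up * inv(T_cam_up) * T_cam_low`` — the relative pose of
    the lower marker w.r.t. the upper one, mapped through the upper
    marker's (static) registration to the articulator.  Any common camera
    motion cancels in the chain.
    """
    _, t_cam_up, t_cam_low = stream.nearest(t)
    chain = compose(t_0_up, compose(invert(t_cam_up), t_cam_low))
    return chain.apply(np.asarray(p_low, dtype=float))


def track_landmark_trajectory(
    landmark_low,
    stream: MarkerPoseStream,
    t_0_up: FramedTransform,
    label: str = "",
) -> Trajectory:
    """Trajectory of a mandible-fixed point over a whole marker stream."""
    if len(stream) == 0:
        raise InvalidArgumentError("empty marker stream")
    p = np.asarray(landmark_low, dtype=float)
    times = stream.times
    pts = np.empty((len(stream), 3))
    for i, (t, t_cam_up, t_cam_low) in enumerate(stream.samples):
        chain = compose(t_0_up, compose(invert(t_cam_up), t_cam_low))
        pts[i] = chain.apply(p)
    return Trajectory(times, pts, frame=ARTICULATOR_FRAME, label=label)
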