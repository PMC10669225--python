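"""Personalized condylar-path models fitted from tracked condyle motion.

The condylar path — the trajectory of a condyle during protrusion and
lateral excursion — replaces the fixed mechanical guidance of a
conventional articulator.  It is personalized from tracked data in three
pieces, all in the articulator frame (condyles at z = 0 on the reference
plane, mid-sagittal plane at x = 0):

* sagittal projection (y, z) of the protrusive path, fitted with a
  quadratic ``z = a y^2 + b y + c``; the condylar-inclination angle is the
  slope angle at the rest position;
* horizontal projection (y, x) of the working-side lateral path, fitted
  with a straight line ``x = m y + k``; the Bennett angle is ``atan(|m|)``;
* a clamped cubic NURBS curve through the 3D protrusion samples, the
  export/visualization representation of the combined path.

The scalar functions ``x = f(y)``, ``z = g(y)`` that the inverse
kinematics consumes come from the two planar fits, so the path constraint
stays a scalar function of the antero-posterior coordinate.  Outside the
fitted y-domain both are continued linearly from the nearest endpoint
(tracked motion only reaches the patient's extreme position; the solver
may probe slightly beyond it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DomainExtrapolationWarning,
    InsufficientDataError,
    InvalidArgumentError,
    InvalidStateError,
)
from .trajectory import Trajectory

_DEF_DEGREE = 3


# ---------------------------------------------------------------------------
# NURBS primitives (Cox–de Boor)


def nurbs_basis(u: float, j: int, p: int, knots) -> float:
    """B-spline basis function N_{j,p}(u) by the Cox–de Boor recursion.

    The 0/0 convention resolves to 0; at the right end of a clamped knot
    vector the last basis function evaluates to 1 (closed last span).
    """
    knots = np.asarray(knots, dtype=float)
    if not (knots[p] <= u <= knots[len(knots) - 1 - p]):
        raise InvalidArgumentError(
            f"u={u} outside knot range [{knots[p]}, {knots[len(knots) - 1 - p]}]"
        )
    if j < 0 or j + p + 1 >= len(knots):
        raise InvalidArgumentError(f"basis index {j} out of range for {len(knots)} knots")
    return _basis_rec(u, j, p, knots)


def _basis_rec(u: float, j: int, p: int, knots: np.ndarray) -> float:
    if p == 0:
        last = len(knots) - 1
        if knots[j] <= u < knots[j + 1]:
            return 1.0
        # close the final non-empty span so u == knots[-1] is representable
        if u == knots[last] and knots[j] < knots[j + 1] <= knots[last] and u == knots[j + 1]:
            return 1.0
        return 0.0
    left = 0.0
    denom = knots[j + p] - knots[j]
    if denom > 0.0:
        left = (u - knots[j]) / denom * _basis_rec(u, j, p - 1, knots)
    right = 0.0
    denom = knots[j + p + 1] - knots[j + 1]
    if denom > 0.0:
        right = (knots[j + p + 1] - u) / denom * _basis_rec(u, j + 1, p - 1, knots)
    return left + right


@dataclass(frozen=True)
class NurbsCurve:
    """Rational B-spline curve: degree, control points (mm), weights, knots."""

    degree: int
    control_points: np.ndarray  # (n+1, 3)
    weights: np.ndarray  # (n+1,)
    knots: np.ndarray  # (n + degree + 2,), clamped

    def __post_init__(self):
        cp = np.asarray(self.control_points, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        k = np.asarray(self.knots, dtype=float)
        p = self.degree
        if cp.ndim != 2 or cp.shape[1] != 3:
            raise InvalidArgumentError("control_points must be (n+1, 3)")
        if w.shape != (cp.shape[0],):
            raise InvalidArgumentError("weights must match control point count")
        if np.any(w <= 0):
            raise InvalidArgumentError("all NURBS weights must be > 0")
        if k.shape != (cp.shape[0] + p + 1,):
            raise InvalidArgumentError("knot vector length must be n + p + 2")
        if np.any(np.diff(k) < 0):
            raise InvalidArgumentError("knot vector must be non-decreasing")
        if not (np.all(k[: p + 1] == k[0]) and np.all(k[-p - 1:] == k[-1])):
            raise InvalidArgumentError("knot vector must be clamped (end multiplicity p+1)")
        object.__setattr__(self, "control_points", cp)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "knots", k)

    def evaluate(self, u: float) -> np.ndarray:
        if not (0.0 <= u <= 1.0):
            raise InvalidArgumentError(f"NURBS parameter u must be in [0, 1], got {u}")
        n1 = self.control_points.shape[0]
        basis = np.array([nurbs_basis(u, j, self.degree, self.knots) for j in range(n1)])
        wb = basis * self.weights
        return (wb @ self.control_points) / wb.sum()


def _approximation_knots(ubar: np.ndarray, n_ctrl: int, p: int) -> np.ndarray:
    """Clamped knot vector for least-squares approximation, by averaging
    the chord-length parameters over interior spans (de Boor style)."""
    m = len(ubar) - 1
    n = n_ctrl - 1
    knots = np.empty(n + p + 2)
    knots[: p + 1] = 0.0
    knots[-p - 1:] = 1.0
    d = (m + 1) / (n - p + 1)
    for j in range(1, n - p + 1):
        i = int(np.floor(j * d))
        alpha = j * d - i
        knots[p + j] = (1.0 - alpha) * ubar[i - 1] + alpha * ubar[i]
    return knots


def fit_nurbs(points: np.ndarray, n_ctrl: int, degree: int = _DEF_DEGREE) -> NurbsCurve:
    """Least-squares clamped B-spline (uniform weights) through 3D samples.

    Chord-length parameterization; control points solve the linear
    least-squares system of the basis design matrix.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < n_ctrl:
        n_ctrl = pts.shape[0]
    if n_ctrl < degree + 1:
        raise InsufficientDataError(
            f"need at least {degree + 1} control points, got {n_ctrl}"
        )
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = chord.sum()
    if total == 0:
        raise InsufficientDataError("all samples coincide; cannot parameterize")
    ubar = np.clip(np.concatenate([[0.0], np.cumsum(chord) / total]), 0.0, 1.0)
    ubar[-1] = 1.0
    # collapse duplicate parameters from repeated points
    knots = _approximation_knots(ubar, n_ctrl, degree)
    design = np.array(
        [[nurbs_basis(u, j, degree, knots) for j in range(n_ctrl)] for u in ubar]
    )
    ctrl, *_ = np.linalg.lstsq(design, pts, rcond=None)
    return NurbsCurve(degree, ctrl, np.ones(n_ctrl), knots)


# ---------------------------------------------------------------------------
# planar fits


def fit_sagittal_quadratic(points, rest_y: float | None = None):
    """Quadratic fit of the sagittal (y, z) projection of a condyle path.

    Returns ``(a, b, c, rms, inclination_deg)`` for ``z = a y^2 + b y + c``;
    the condylar inclination is the slope angle ``atan(|dz/dy|)`` at the
    rest position (the first sample's y unless ``rest_y`` is given),
    measured against the z = 0 reference plane.
    """
    pts = _points_of(points)
    y, z = pts[:, 1], pts[:, 2]
    if np.unique(np.round(y, 9)).size < 3:
        raise InsufficientDataError("sagittal quadratic fit needs >= 3 distinct y values")
    design = np.column_stack([y**2, y, np.ones_like(y)])
    coeffs, *_ = np.linalg.lstsq(design, z, rcond=None)
    a, b, c = coeffs
    rms = float(np.sqrt(np.mean((design @ coeffs - z) ** 2)))
    y0 = float(y[0]) if rest_y is None else float(rest_y)
    inclination = float(np.degrees(np.arctan(abs(2 * a * y0 + b))))
    return float(a), float(b), float(c), rms, inclination


def fit_horizontal_line(points):
    """Line fit of the horizontal (y, x) projection of the working-side
    lateral path.  Returns ``(m, k, rms, bennett_deg)`` for ``x = m y + k``;
    the Bennett angle is ``atan(|m|)`` against the sagittal direction."""
    pts = _points_of(points)
    y, x = pts[:, 1], pts[:, 0]
    if np.unique(np.round(y, 9)).size < 2:
        raise InsufficientDataError("horizontal line fit needs >= 2 distinct y values")
    design = np.column_stack([y, np.ones_like(y)])
    coeffs, *_ = np.linalg.lstsq(design, x, rcond=None)
    m, k = coeffs
    rms = float(np.sqrt(np.mean((design @ coeffs - x) ** 2)))
    bennett = float(np.degrees(np.arctan(abs(m))))
    return float(m), float(k), rms, bennett


def _points_of(points) -> np.ndarray:
    if isinstance(points, Trajectory):
        if points.has_gaps:
            points = points.valid()
        return points.points
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidArgumentError(f"points must be (N,3), got {pts.shape}")
    return pts


# ---------------------------------------------------------------------------
# path model


@dataclass(frozen=True)
class CondylarPathModel:
    """One side's personalized condylar path.

    ``sagittal_coeffs`` (a, b, c) give z = a y^2 + b y + c; the
    ``horizontal_coeffs`` (m, k) give x = m y + k; angles are degrees;
    ``y_domain`` is the antero-posterior extent (mm) covered by data.
    """

    side: str
    sagittal_coeffs: tuple[float, float, float]
    horizontal_coeffs: tuple[float, float]
    bennett_angle: float
    inclination_angle: float
    y_domain: tuple[float, float]
    sagittal_rms: float = 0.0
    horizontal_rms: float = 0.0
    nurbs: NurbsCurve | None = None

    def __post_init__(self):
        if self.side not in ("right", "left"):
            raise InvalidArgumentError(f"side must be 'right' or 'left', got {self.side!r}")
        lo, hi = self.y_domain
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise InvalidArgumentError(f"y_domain must satisfy y_min < y_max, got {self.y_domain}")

    # IK-facing scalar functions f(y), g(y)
    def evaluate(self, y: float) -> tuple[float, float]:
        return evaluate_path(self, y)

    def to_dict(self) -> dict:
        d = {
            "side": self.side,
            "unit": "mm",
            "sagittal_coeffs": list(self.sagittal_coeffs),
            "horizontal_coeffs": list(self.horizontal_coeffs),
            "bennett_angle_deg": self.bennett_angle,
            "inclination_angle_deg": self.inclination_angle,
            "y_domain": list(self.y_domain),
            "sagittal_rms": self.sagittal_rms,
            "horizontal_rms": self.horizontal_rms,
        }
        if self.nurbs is not None:
            d["nurbs"] = {
                "degree": self.nurbs.degree,
                "control_points": self.nurbs.control_points.tolist(),
                "weights": self.nurbs.weights.tolist(),
                "knot_vector": self.nurbs.knots.tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CondylarPathModel":
        nurbs = None
        if d.get("nurbs"):
            n = d["nurbs"]
            nurbs = NurbsCurve(
                n["degree"],
                np.asarray(n["control_points"], dtype=float),
                np.asarray(n["weights"], dtype=float),
                np.asarray(n["knot_vector"], dtype=float),
            )
        return cls(
            side=d["side"],
            sagittal_coeffs=tuple(d["sagittal_coeffs"]),
            horizontal_coeffs=tuple(d["horizontal_coeffs"]),
            bennett_angle=d["bennett_angle_deg"],
            inclination_angle=d["inclination_angle_deg"],
            y_domain=tuple(d["y_domain"]),
            sagittal_rms=d.get("sagittal_rms", 0.0),
            horizontal_rms=d.get("horizontal_rms", 0.0),
            nurbs=nurbs,
        )


def fit_condylar_path(
    condyle_traj_protrusion: Trajectory,
    condyle_traj_lateral: Trajectory,
    side: str,
    rest_y: float | None = None,
    n_ctrl: int | None = None,
) -> CondylarPathModel:
    """Fit a full condylar-path model from tracked condyle trajectories.

    ``condyle_traj_protrusion`` drives the sagittal quadratic and the
    NURBS; ``condyle_traj_lateral`` (the lateral excursion toward this
    model's side, i.e. the working side) drives the Bennett line.
    """
    prot = _points_of(condyle_traj_protrusion)
    if prot.shape[0] < 4:
        raise InsufficientDataError(
            f"protrusion trajectory needs >= 4 samples, got {prot.shape[0]}"
        )
    a, b, c, s_rms, inclination = fit_sagittal_quadratic(prot, rest_y=rest_y)
    m, k, h_rms, bennett = fit_horizontal_line(_points_of(condyle_traj_lateral))
    y = prot[:, 1]
    if n_ctrl is None:
        n_ctrl = min(25, max(4, int(np.ceil(prot.shape[0] / 5))))
    nurbs = fit_nurbs(prot, n_ctrl)
    return CondylarPathModel(
        side=side,
        sagittal_coeffs=(a, b, c),
        horizontal_coeffs=(m, k),
        bennett_angle=bennett,
        inclination_angle=inclination,
        y_domain=(float(y.min()), float(y.max())),
        sagittal_rms=s_rms,
        horizontal_rms=h_rms,
        nurbs=nurbs,
    )


def evaluate_path(model: CondylarPathModel, y: float) -> tuple[float, float]:
    """IK-facing path functions: ``(x, z) = (f(y), g(y))``.

    Inside ``y_domain`` these are the planar polynomial fits; outside, the
    value is continued linearly from the nearest endpoint with the
    endpoint slope (a :class:`DomainExtrapolationWarning` is emitted).
    """
    if model is None:
        raise InvalidStateError("path model is not fitted")
    a, b, c = model.sagittal_coeffs
    m, k = model.horizontal_coeffs
    lo, hi = model.y_domain
    if y < lo or y > hi:
        edge = lo if y < lo else hi
        warnings.warn(
            "condylar path evaluated outside its fitted y-domain; "
            "using linear extension from the nearest endpoint",
            DomainExtrapolationWarning,
            stacklevel=2,
        )
        z_edge = a * edge**2 + b * edge + c
        dz = 2 * a * edge + b
        z = z_edge + dz * (y - edge)
    else:
        z = a * y**2 + b * y + c
    x = m * y + k  # the line extends linearly by itself
    return float(x), float(z)


def evaluate_nurbs(model: CondylarPathModel, u: float) -> np.ndarray:
    """Point on the model's 3D NURBS curve at parameter ``u`` in [0, 1]."""
    if model.nurbs is None:
        raise InvalidStateError("model has no fitted NURBS curve")
    return model.nurbs.evaluate(u)
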