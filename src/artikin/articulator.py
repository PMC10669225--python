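"""Articulator anatomy types and the forward mandibular motion model.

The articulator (world) frame follows the facebow convention used
throughout the package: origin at the midpoint of the intercondylar axis,
+X toward the patient's right condyle along the hinge axis, +Z normal to
the chosen cranial reference plane pointing superiorly, +Y = Z x X
(anterior).  With condyles on the reference plane this puts them at
(+/- w/2, 0, 0), the mid-sagittal plane at x = 0 and the horizontal
(reference) plane at z = 0.

Two kinematic descriptions live here:

* the articulator *joint chain* — joint 0 at the world origin, joint 1 the
  Bennett-angle joint, joint 2 the condylar-inclination joint, each a
  translation followed by elementary rotations; and
* the 6-DOF *jaw pose* — a rotation (Rz*Ry*Rx) and translation of the
  mandible expressed about a reference condyle, the unknown the inverse
  kinematics solves for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FrameMismatchError, InvalidArgumentError
from .transforms import (
    FramedTransform,
    compose,
    invert,
    make_rotation,
    make_translation,
)

ARTICULATOR_FRAME = "articulator"

_SIDES = ("right", "left")


def _check_side(side: str) -> str:
    if side not in _SIDES:
        raise InvalidArgumentError(f"side must be 'right' or 'left', got {side!r}")
    return side


def _as_vec3(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,) or not np.all(np.isfinite(a)):
        raise InvalidArgumentError(f"{name} must be a finite 3-vector, got {v!r}")
    return a


@dataclass(frozen=True)
class JointChainParameters:
    """One side's joint-chain settings (angles rad, offsets mm)."""

    theta_sag: float  # reference plane vs condylar-inclination plane
    theta1: float  # Bennett-angle joint
    theta2: float  # condylar-inclination adjuster
    p01: np.ndarray  # offset world origin -> joint 1
    p12: np.ndarray  # offset joint 1 -> joint 2

    def __post_init__(self):
        for name in ("theta_sag", "theta1", "theta2"):
            v = getattr(self, name)
            if not np.isfinite(v) or abs(v) >= np.pi / 2:
                raise InvalidArgumentError(f"|{name}| must be < pi/2, got {v}")
        object.__setattr__(self, "p01", _as_vec3(self.p01, "p01"))
        object.__setattr__(self, "p12", _as_vec3(self.p12, "p12"))

    def mirrored(self) -> "JointChainParameters":
        """The x -> -x mirror of this chain (right <-> left)."""
        flip = np.array([-1.0, 1.0, 1.0])
        return JointChainParameters(
            theta_sag=self.theta_sag,
            theta1=-self.theta1,
            theta2=self.theta2,
            p01=self.p01 * flip,
            p12=self.p12 * flip,
        )


@dataclass(frozen=True)
class ArticulatorParameters:
    """Per-side joint chains plus the intercondylar width (mm)."""

    right: JointChainParameters
    left: JointChainParameters
    intercondylar_width: float

    def __post_init__(self):
        if not np.isfinite(self.intercondylar_width) or self.intercondylar_width <= 0:
            raise InvalidArgumentError(
                f"intercondylar_width must be > 0, got {self.intercondylar_width}"
            )

    @classmethod
    def symmetric(
        cls,
        theta_sag: float,
        theta1: float,
        theta2: float,
        intercondylar_width: float,
        p12=(0.0, 0.0, 0.0),
    ) -> "ArticulatorParameters":
        """Build a bilaterally symmetric articulator.

        The right joint-1 offset is the right condyle position
        (+w/2, 0, 0); the left chain is its sagittal mirror.
        """
        right = JointChainParameters(
            theta_sag=theta_sag,
            theta1=theta1,
            theta2=theta2,
            p01=np.array([intercondylar_width / 2.0, 0.0, 0.0]),
            p12=np.asarray(p12, dtype=float),
        )
        return cls(right=right, left=right.mirrored(), intercondylar_width=intercondylar_width)

    def side(self, side: str) -> JointChainParameters:
        return getattr(self, _check_side(side))


@dataclass(frozen=True)
class AnatomicalLandmarks:
    """CT-derived reference points expressed in a named frame.

    ``anterior_point`` is the infraorbital point (Frankfurt plane) or the
    nasal alar point (Camper's plane); ``incisal_point`` is the lower
    incisal edge midpoint, the kinematic end-effector.
    """

    condyle_right: np.ndarray
    condyle_left: np.ndarray
    anterior_point: np.ndarray
    incisal_point: np.ndarray
    anterior_point_kind: str = "infraorbital"
    frame: str = ARTICULATOR_FRAME

    def __post_init__(self):
        for name in ("condyle_right", "condyle_left", "anterior_point", "incisal_point"):
            object.__setattr__(self, name, _as_vec3(getattr(self, name), name))
        if self.anterior_point_kind not in ("infraorbital", "nasal_alar"):
            raise InvalidArgumentError(
                f"anterior_point_kind must be 'infraorbital' or 'nasal_alar',"
                f" got {self.anterior_point_kind!r}"
            )
        if np.linalg.norm(self.condyle_right - self.condyle_left) <= 1.0:
            raise InvalidArgumentError("condyle centers closer than 1 mm")
        # triangle area with the anterior point must exceed 1 mm^2
        area = 0.5 * np.linalg.norm(
            np.cross(
                self.condyle_left - self.condyle_right,
                self.anterior_point - self.condyle_right,
            )
        )
        if area <= 1.0:
            raise InvalidArgumentError(
                f"anterior point nearly collinear with condyles (area {area:.3g} mm^2)"
            )

    def condyle(self, side: str) -> np.ndarray:
        return self.condyle_right if _check_side(side) == "right" else self.condyle_left

    def to_dict(self) -> dict:
        return {
            "unit": "mm",
            "frame": self.frame,
            "condyle_right": self.condyle_right.tolist(),
            "condyle_left": self.condyle_left.tolist(),
            "anterior_point": self.anterior_point.tolist(),
            "anterior_point_kind": self.anterior_point_kind,
            "incisal_point": self.incisal_point.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnatomicalLandmarks":
        return cls(
            condyle_right=d["condyle_right"],
            condyle_left=d["condyle_left"],
            anterior_point=d["anterior_point"],
            incisal_point=d["incisal_point"],
            anterior_point_kind=d.get("anterior_point_kind", "infraorbital"),
            frame=d.get("frame", ARTICULATOR_FRAME),
        )


@dataclass(frozen=True)
class JawPose:
    """6-DOF mandibular pose about a reference condyle.

    Rotation angles (rad) compose as Rz*Ry*Rx; translation (mm) is applied
    after the rotation.  ``adjustment`` records any inferior translation
    added by collision resolution (0 for raw kinematic poses).
    """

    theta_x: float = 0.0
    theta_y: float = 0.0
    theta_z: float = 0.0
    t_x: float = 0.0
    t_y: float = 0.0
    t_z: float = 0.0
    reference_side: str = "right"
    adjustment: float = 0.0
    angle_bound: float = field(default=np.pi / 2, repr=False)

    def __post_init__(self):
        vals = (self.theta_x, self.theta_y, self.theta_z, self.t_x, self.t_y, self.t_z)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidArgumentError(f"pose components must be finite, got {vals}")
        for a in (self.theta_x, self.theta_y, self.theta_z):
            if abs(a) >= self.angle_bound:
                raise InvalidArgumentError(
                    f"|angle| {abs(a):.4f} exceeds physiological bound {self.angle_bound:.4f}"
                )
        _check_side(self.reference_side)

    @property
    def vector(self) -> np.ndarray:
        """(theta_x, theta_y, theta_z, t_x, t_y, t_z) as an array."""
        return np.array(
            [self.theta_x, self.theta_y, self.theta_z, self.t_x, self.t_y, self.t_z]
        )

    @classmethod
    def from_vector(cls, v, reference_side: str = "right", **kw) -> "JawPose":
        v = np.asarray(v, dtype=float)
        return cls(
            theta_x=v[0], theta_y=v[1], theta_z=v[2],
            t_x=v[3], t_y=v[4], t_z=v[5],
            reference_side=reference_side, **kw,
        )

    def translation_only(self) -> bool:
        return self.theta_x == self.theta_y == self.theta_z == 0.0


# ---------------------------------------------------------------------------
# forward joint chain


def articulator_joint_chain(
    params: ArticulatorParameters, side: str
) -> tuple[FramedTransform, FramedTransform]:
    """Forward transforms of one side's joint chain.

    Returns ``(T01, T12)``: joint-1 (Bennett) frame -> world, and joint-2
    (condylar inclination) frame -> joint 1.  Each is a translation
    followed by elementary rotations:
    ``T01 = Trans(p01) * Rx(theta_sag) * Rz(theta1)`` and
    ``T12 = Trans(p12) * Rx(theta2)``.
    """
    p = params.side(side)
    t01 = compose(
        compose(make_translation(p.p01), make_rotation("x", p.theta_sag)),
        make_rotation("z", p.theta1),
    )
    t12 = compose(make_translation(p.p12), make_rotation("x", p.theta2))
    joint1 = f"joint1_{side}"
    joint2 = f"joint2_{side}"
    t01 = FramedTransform(t01.matrix, from_frame=joint1, to_frame=ARTICULATOR_FRAME)
    t12 = FramedTransform(t12.matrix, from_frame=joint2, to_frame=joint1)
    return t01, t12


def map_joint2_point_to_world(
    p, t01: FramedTransform, t12: FramedTransform
) -> np.ndarray:
    """World coordinates of a point given in the joint-2 frame: (T01*T12)*p."""
    return compose(t01, t12).apply(_as_vec3(p, "point"))


def world_to_condyle_frame(landmarks: AnatomicalLandmarks, side: str) -> FramedTransform:
    """Translation taking the chosen condyle center to the origin (axes kept
    parallel to the world axes) — the T0R / T0L of the pose decomposition."""
    if landmarks.frame != ARTICULATOR_FRAME:
        raise FrameMismatchError(ARTICULATOR_FRAME, landmarks.frame, "landmarks")
    c = landmarks.condyle(side)
    m = np.eye(4)
    m[:3, 3] = -c
    return FramedTransform(m, from_frame=ARTICULATOR_FRAME, to_frame=f"condyle_{side}")


def jaw_pose_transform(pose: JawPose, ref_condyle) -> FramedTransform:
    """World-frame rigid transform realized by a jaw pose about ``ref_condyle``.

    Expanded about the reference condyle c:
    ``p' = R (p - c) + c + t`` with ``R = Rz(theta_z) Ry(theta_y) Rx(theta_x)``
    — i.e. invert(T0R) * Trant * Rz * Ry * Rx * T0R.
    """
    c = _as_vec3(ref_condyle, "ref_condyle")
    trr = compose(
        compose(
            make_translation([pose.t_x, pose.t_y, pose.t_z]),
            make_rotation("z", pose.theta_z),
        ),
        compose(make_rotation("y", pose.theta_y), make_rotation("x", pose.theta_x)),
    )
    m = make_translation(c).matrix @ trr.matrix @ make_translation(-c).matrix
    return FramedTransform(m, from_frame=ARTICULATOR_FRAME, to_frame=ARTICULATOR_FRAME)


def apply_jaw_pose(pose: JawPose, ref_condyle, p) -> np.ndarray:
    """Map a world-frame point through a jaw pose about the reference condyle."""
    return jaw_pose_transform(pose, ref_condyle).apply(np.asarray(p, dtype=float))
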