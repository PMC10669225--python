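"""Rigid homogeneous-transform algebra with coordinate-frame bookkeeping.

Every rigid map in the articulator pipeline — joint chains, marker/camera
chains, CT-to-articulator registration — is a :class:`FramedTransform`: a
4x4 homogeneous matrix tagged with the names of its source and target
frames.  Compositions check that frames chain correctly, which catches the
classic "multiplied in the wrong order" bug at the point of the mistake
rather than three modules downstream.

Conventions: lengths in mm, angles in radians, right-handed frames,
points are column vectors acted on from the left (p' = R p + t).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import FrameMismatchError, InvalidArgumentError

logger = logging.getLogger(__name__)

_LAST_ROW = np.array([0.0, 0.0, 0.0, 1.0])

#: tolerance for rotation-block orthonormality checks
ORTHONORMAL_TOL = 1e-9


@dataclass(frozen=True)
class FramedTransform:
    """A rigid 4x4 homogeneous transform from ``from_frame`` to ``to_frame``.

    Parameters
    ----------
    matrix
        4x4 homogeneous matrix; rotation block must be orthonormal with
        determinant +1 and the last row exactly ``[0, 0, 0, 1]``.
    from_frame, to_frame
        Optional frame names.  ``None`` marks a frameless building block
        (elementary rotations/translations before they are placed in a
        chain); composing frameless transforms is allowed but logged.
    """

    matrix: np.ndarray
    from_frame: str | None = None
    to_frame: str | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise InvalidArgumentError(f"transform matrix must be 4x4, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise InvalidArgumentError("transform matrix has non-finite entries")
        if not np.array_equal(m[3], _LAST_ROW):
            raise InvalidArgumentError(f"last row must be [0,0,0,1], got {m[3]}")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=ORTHONORMAL_TOL):
            raise InvalidArgumentError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise InvalidArgumentError("rotation block has determinant -1 (reflection)")
        object.__setattr__(self, "matrix", m)

    # -- accessors ---------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        """3x3 rotation block."""
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        """3-vector translation (mm)."""
        return self.matrix[:3, 3]

    # -- behaviour ---------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to a single 3-vector or an (N, 3) array of points."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        if p.shape[1] != 3:
            raise InvalidArgumentError(f"points must be (N,3) or (3,), got {p.shape}")
        out = p @ self.rotation.T + self.translation
        return out[0] if single else out

    def __matmul__(self, other: "FramedTransform") -> "FramedTransform":
        return compose(self, other)

    def almost_equal(self, other: "FramedTransform", atol: float = 1e-9) -> bool:
        return np.allclose(self.matrix, other.matrix, atol=atol)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "from": self.from_frame,
            "to": self.to_frame,
            "matrix": [float(v) for v in self.matrix.ravel()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FramedTransform":
        m = np.asarray(d["matrix"], dtype=float).reshape(4, 4)
        return cls(m, d.get("from"), d.get("to"))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "FramedTransform":
        return cls.from_dict(json.loads(s))


def identity(from_frame: str | None = None, to_frame: str | None = None) -> FramedTransform:
    """Identity transform (optionally renaming a frame)."""
    return FramedTransform(np.eye(4), from_frame, to_frame or from_frame)


def make_rotation(axis: str, angle: float) -> FramedTransform:
    """Elementary rotation about the ``x``, ``y`` or ``z`` axis.

    The returned transform is frameless: it is a building block for joint
    chains and the mandibular pose Rz*Ry*Rx product.
    """
    if not np.isfinite(angle):
        raise InvalidArgumentError(f"rotation angle must be finite, got {angle}")
    c, s = np.cos(angle), np.sin(angle)
    m = np.eye(4)
    if axis == "x":
        m[1:3, 1:3] = [[c, -s], [s, c]]
    elif axis == "y":
        m[0, 0], m[0, 2], m[2, 0], m[2, 2] = c, s, -s, c
    elif axis == "z":
        m[0:2, 0:2] = [[c, -s], [s, c]]
    else:
        raise InvalidArgumentError(f"axis must be one of 'x','y','z', got {axis!r}")
    return FramedTransform(m)


def make_translation(t) -> FramedTransform:
    """Pure translation by the 3-vector ``t`` (mm)."""
    t = np.asarray(t, dtype=float)
    if t.shape != (3,) or not np.all(np.isfinite(t)):
        raise InvalidArgumentError(f"translation must be a finite 3-vector, got {t}")
    m = np.eye(4)
    m[:3, 3] = t
    return FramedTransform(m)


def compose(a: FramedTransform, b: FramedTransform) -> FramedTransform:
    """Compose two transforms: the result applies ``b`` first, then ``a``.

    Frame contract: when both tags are present, ``b.to_frame`` must equal
    ``a.from_frame``; the result maps ``b.from_frame -> a.to_frame``.
    """
    if a.from_frame is not None and b.to_frame is not None:
        if a.from_frame != b.to_frame:
            raise FrameMismatchError(a.from_frame, b.to_frame, "compose(A, B)")
    elif a.from_frame is None and b.to_frame is None:
        logger.debug("composing untagged transforms")
    m = a.matrix @ b.matrix
    # re-orthonormalize drift from long chains
    u, _, vt = np.linalg.svd(m[:3, :3])
    m[:3, :3] = u @ vt
    m[3] = _LAST_ROW
    return FramedTransform(m, b.from_frame, a.to_frame)


def invert(t: FramedTransform) -> FramedTransform:
    """Rigid inverse [R^T | -R^T t]; source and target frames swap."""
    r = t.rotation.T
    m = np.eye(4)
    m[:3, :3] = r
    m[:3, 3] = -r @ t.translation
    return FramedTransform(m, t.to_frame, t.from_frame)
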