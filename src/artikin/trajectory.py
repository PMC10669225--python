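"""Timestamped 3D point sequences in a named coordinate frame."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError


@dataclass(frozen=True)
class Trajectory:
    """Ordered timestamped 3D samples (seconds, mm) in a named frame.

    ``label`` is free text used by comparison protocols, conventionally
    slash-separated, e.g. ``"right_condyle/protrusion/forward/rep1"``.
    Rows of NaN are *gap markers* (a per-sample solver failure) and are
    only admitted when constructed with ``allow_gaps=True``; infinities
    are never allowed.
    """

    t: np.ndarray
    points: np.ndarray
    frame: str = "articulator"
    label: str = ""
    allow_gaps: bool = field(default=False, repr=False)

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        p = np.asarray(self.points, dtype=float)
        if t.ndim != 1 or p.ndim != 2 or p.shape != (t.shape[0], 3):
            raise InvalidArgumentError(
                f"need t:(N,) and points:(N,3), got {t.shape} and {p.shape}"
            )
        if t.size == 0:
            raise InvalidArgumentError("trajectory must have at least one sample")
        if not np.all(np.isfinite(t)):
            raise InvalidArgumentError("timestamps must be finite")
        if np.any(np.diff(t) < 0):
            raise InvalidArgumentError("timestamps must be non-decreasing")
        if np.any(np.isinf(p)):
            raise InvalidArgumentError("points contain infinities")
        nan_rows = np.isnan(p).any(axis=1)
        if nan_rows.any() and not self.allow_gaps:
            raise InvalidArgumentError(
                f"{int(nan_rows.sum())} NaN rows present; pass allow_gaps=True "
                "to mark solver gaps explicitly"
            )
        t.flags.writeable = False
        p.flags.writeable = False
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "points", p)

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def has_gaps(self) -> bool:
        return bool(np.isnan(self.points).any())

    def valid(self) -> "Trajectory":
        """Drop gap rows."""
        keep = ~np.isnan(self.points).any(axis=1)
        return Trajectory(self.t[keep].copy(), self.points[keep].copy(),
                          self.frame, self.label)

    def with_label(self, label: str) -> "Trajectory":
        return replace(self, label=label)

    def slice(self, start: int, stop: int, label: str | None = None) -> "Trajectory":
        return Trajectory(
            self.t[start:stop].copy(),
            self.points[start:stop].copy(),
            self.frame,
            self.label if label is None else label,
            allow_gaps=self.allow_gaps,
        )
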