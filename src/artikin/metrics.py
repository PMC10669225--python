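"""Agreement metrics between tracked and simulated condylar trajectories.

Two metrics quantify how well the personalized articulation model
reproduces measured condyle motion:

* **ATE** (average trajectory error): the mean Euclidean distance between
  index-aligned measured and simulated points — appropriate when both
  trajectories were sampled at the same instants;
* **discrete Fréchet distance**: the minimum over monotone couplings of
  the maximum pairwise distance between two polygonal chains — robust to
  unequal sampling, and the metric used for the per-movement comparison
  protocol (each movement runs from centric occlusion to the extreme
  position and back, twice; each forward/backward repetition is compared
  separately and averaged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import InvalidArgumentError
from .trajectory import Trajectory


def _points(traj) -> np.ndarray:
    if isinstance(traj, Trajectory):
        pts = traj.points
    else:
        pts = np.asarray(traj, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InvalidArgumentError(f"trajectory must be (N,3), got {pts.shape}")
    if np.isnan(pts).any():
        raise InvalidArgumentError("trajectory contains gap markers; drop them first (.valid())")
    return pts


def average_trajectory_error(measured, simulated, squared: bool = False) -> float:
    """Mean point-wise distance between index-aligned trajectories (mm).

    Both trajectories must have the same length; no resampling is done
    (silently resampling would hide a protocol error).  ``squared=True``
    averages squared distances instead.
    """
    p = _points(measured)
    q = _points(simulated)
    if p.shape[0] != q.shape[0]:
        raise InvalidArgumentError(
            f"ATE requires index-aligned trajectories of equal length, "
            f"got {p.shape[0]} vs {q.shape[0]}"
        )
    if p.shape[0] < 1:
        raise InvalidArgumentError("ATE requires at least one sample")
    d = np.linalg.norm(p - q, axis=1)
    return float(np.mean(d**2 if squared else d))


def discrete_frechet(p, q) -> float:
    """Discrete Fréchet distance between two polygonal chains (mm).

    Iterative dynamic program (Eiter–Mannila):
    ``c(i,j) = max(d(P_i, Q_j), min(c(i-1,j), c(i-1,j-1), c(i,j-1)))``
    with Euclidean ``d``; memory O(M), no recursion.
    """
    pp = _points(p)
    qq = _points(q)
    if pp.shape[0] == 0 or qq.shape[0] == 0:
        raise InvalidArgumentError("discrete Fréchet distance needs non-empty chains")
    n, m = pp.shape[0], qq.shape[0]
    # distances row by row to keep memory at O(M)
    prev = np.empty(m)
    d0 = np.linalg.norm(qq - pp[0], axis=1)
    prev[0] = d0[0]
    for j in range(1, m):
        prev[j] = max(prev[j - 1], d0[j])
    cur = np.empty(m)
    for i in range(1, n):
        di = np.linalg.norm(qq - pp[i], axis=1)
        cur[0] = max(prev[0], di[0])
        for j in range(1, m):
            cur[j] = max(di[j], min(prev[j], prev[j - 1], cur[j - 1]))
        prev, cur = cur, prev
    return float(prev[m - 1])


@dataclass(frozen=True)
class TrajectoryComparison:
    """Per-segment Fréchet distances plus the protocol averages."""

    per_segment: dict  # full label -> frechet mm
    direction_averages: dict  # (group, direction) -> mean over repetitions
    grand_mean: float
    table: pd.DataFrame
    ate: float | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.2f")


def _parse_label(label: str) -> tuple[str, str, str]:
    parts = label.split("/")
    if len(parts) < 2:
        raise InvalidArgumentError(
            f"label {label!r} must be '<group...>/<direction>/<repN>' "
            "or '<group...>/<direction>'"
        )
    if parts[-1].startswith("rep"):
        rep = parts[-1]
        direction = parts[-2]
        group = "/".join(parts[:-2]) or "all"
    else:
        rep = "rep1"
        direction = parts[-1]
        group = "/".join(parts[:-1]) or "all"
    return group, direction, rep


def compare_movement(tracked: dict, simulated: dict) -> TrajectoryComparison:
    """Run the per-movement comparison protocol.

    ``tracked`` and ``simulated`` map segment labels (e.g.
    ``"protrusion/right_condyle/forward/rep1"``) to trajectories; labels
    must match exactly between the two sides.  Returns the per-segment
    discrete Fréchet distances, the per-direction averages over
    repetitions, and the grand mean over all segments, plus a tidy table
    (mm, rendered at 2 decimals on CSV export).
    """
    missing = set(tracked) ^ set(simulated)
    if missing:
        raise InvalidArgumentError(f"unmatched trajectory labels: {sorted(missing)}")
    if not tracked:
        raise InvalidArgumentError("no trajectories to compare")
    per_segment: dict[str, float] = {}
    rows = []
    for label in tracked:
        dist = discrete_frechet(tracked[label], simulated[label])
        per_segment[label] = dist
        group, direction, rep = _parse_label(label)
        rows.append({"group": group, "direction": direction, "repetition": rep,
                     "frechet_mm": dist})
    df = pd.DataFrame(rows).sort_values(["group", "direction", "repetition"]).reset_index(drop=True)
    direction_averages = {
        (g, d): float(sub["frechet_mm"].mean())
        for (g, d), sub in df.groupby(["group", "direction"], sort=True)
    }
    avg_rows = [
        {"group": g, "direction": d, "repetition": "average", "frechet_mm": v}
        for (g, d), v in direction_averages.items()
    ]
    grand = float(df["frechet_mm"].mean())
    table = pd.concat(
        [df, pd.DataFrame(avg_rows),
         pd.DataFrame([{"group": "all", "direction": "all",
                        "repetition": "grand_mean", "frechet_mm": grand}])],
        ignore_index=True,
    )
    return TrajectoryComparison(
        per_segment=per_segment,
        direction_averages=direction_averages,
        grand_mean=grand,
        table=table,
    )


def repetition_boundaries(
    traj: Trajectory,
    rest_point,
    start_tolerance: float = 1.0,
    min_prominence_fraction: float = 0.25,
    smooth_window: int = 1,
    min_peak_distance: int = 1,
) -> list[tuple[str, int, int]]:
    """Segment an out-and-back movement into forward/backward repetitions.

    The trajectory must start near the rest (centric occlusion) point.
    Boundaries are local extrema of the distance-from-rest profile
    (optionally smoothed by a short moving average for noisy tracking):
    rest -> extreme segments are labeled ``forward/repK``, extreme -> rest
    segments ``backward/repK``.  Returns ``(label, start, stop)`` index
    ranges (stop exclusive) so the same segmentation can be applied to a
    paired trajectory.  If no extremum is found, the whole range is a
    single forward segment.
    """
    rest = np.asarray(rest_point, dtype=float)
    pts = _points(traj)
    d = np.linalg.norm(pts - rest, axis=1)
    if d[0] > start_tolerance:
        raise InvalidArgumentError(
            f"trajectory starts {d[0]:.2f} mm from the rest point "
            f"(tolerance {start_tolerance} mm)"
        )
    if smooth_window > 1 and d.size > smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        d = np.convolve(np.pad(d, smooth_window // 2, mode="edge"), kernel, mode="valid")[: pts.shape[0]]
    span = float(d.max() - d.min())
    prom = min_prominence_fraction * span if span > 0 else 0.0
    peaks, _ = find_peaks(d, prominence=prom, distance=max(1, min_peak_distance))
    valleys, _ = find_peaks(-d, prominence=prom, distance=max(1, min_peak_distance))
    if peaks.size == 0:
        return [("forward/rep1", 0, len(traj))]
    boundaries = np.unique(np.concatenate([[0], peaks, valleys, [len(d) - 1]]))
    out: list[tuple[str, int, int]] = []
    n_fwd = n_bwd = 0
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        if b - a < 1:
            continue
        if d[b] >= d[a]:
            n_fwd += 1
            key = f"forward/rep{n_fwd}"
        else:
            n_bwd += 1
            key = f"backward/rep{n_bwd}"
        out.append((key, int(a), int(b) + 1))
    return out


def split_repetitions(
    traj: Trajectory,
    rest_point,
    start_tolerance: float = 1.0,
    min_prominence_fraction: float = 0.25,
    smooth_window: int = 1,
    min_peak_distance: int = 1,
) -> dict[str, Trajectory]:
    """Split a trajectory at the :func:`repetition_boundaries` segments."""
    segments = repetition_boundaries(
        traj, rest_point, start_tolerance, min_prominence_fraction,
        smooth_window, min_peak_distance,
    )
    return {
        key: traj.slice(a, b, label=_join(traj.label, key))
        for key, a, b in segments
    }


def _join(prefix: str, suffix: str) -> str:
    return f"{prefix}/{suffix}" if prefix else suffix
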