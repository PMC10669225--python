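"""Readers and writers for the on-disk formats.

All formats are plain text: trajectories and marker streams as CSV (with
``# key=value`` header lines naming frame and unit) or JSON; landmarks,
transforms and path models as JSON; meshes as STL/PLY via trimesh with
duplicate vertices welded.  Numeric CSV output is fixed at 6 decimals
(micrometre level); comparison reports print at 2 decimals.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .articulator import AnatomicalLandmarks
from .condylar_path import CondylarPathModel
from .errors import FormatError, InvalidArgumentError
from .registration import MarkerPoseStream
from .trajectory import Trajectory
from .transforms import FramedTransform

_FLOAT_FMT = "%.6f"


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Tunable tolerances and defaults shared by the CLI subcommands."""

    ik_tolerance: float = 1e-8
    icp_tolerance: float = 1e-6
    bisection_tolerance: float = 1e-4
    clearance: float = 0.01
    proxy_radius: float = 0.3
    proxy_spacing: float = 0.5
    nurbs_degree: int = 3
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self):
        for name in ("ik_tolerance", "icp_tolerance", "bisection_tolerance",
                     "clearance", "proxy_radius", "proxy_spacing"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                fh.write(f"{key}={value}\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: type(f.default) for f in cls.__dataclass_fields__.values()}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise FormatError(f"{path}:{lineno}: expected key=value, got {line!r}")
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in types:
                    raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
                kwargs[key] = types[key](value.strip())
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# trajectories


def write_trajectory(traj: Trajectory, path, fmt: str | None = None) -> None:
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            fh.write(f"# frame={traj.frame}\n# unit=mm\n")
            if traj.label:
                fh.write(f"# label={traj.label}\n")
            writer = csv.writer(fh)
            writer.writerow(["t", "x", "y", "z"])
            for t, p in zip(traj.t, traj.points):
                writer.writerow(["%.12g" % t] + ["%.12g" % v for v in p])
    else:
        payload = {
            "frame": traj.frame,
            "unit": "mm",
            "label": traj.label,
            "t": traj.t.tolist(),
            "points": traj.points.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def read_trajectory(path, fmt: str | None = None) -> Trajectory:
    """Read a trajectory; malformed rows are reported with line numbers."""
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        d = json.loads(Path(path).read_text())
        try:
            return Trajectory(np.asarray(d["t"], dtype=float),
                              np.asarray(d["points"], dtype=float),
                              frame=d.get("frame", "articulator"),
                              label=d.get("label", ""))
        except (KeyError, InvalidArgumentError) as exc:
            raise FormatError(f"{path}: {exc}") from exc
    meta = {"frame": "articulator", "unit": "mm", "label": ""}
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        header_seen = False
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                if value:
                    meta[key.strip()] = value.strip()
                continue
            cells = next(csv.reader([line]))
            if not header_seen:
                if [c.strip().lower() for c in cells] != ["t", "x", "y", "z"]:
                    raise FormatError(
                        f"{path}:{lineno}: expected header 't,x,y,z', got {line!r}"
                    )
                header_seen = True
                continue
            if len(cells) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(cells)}")
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
    if meta.get("unit", "mm") != "mm":
        raise FormatError(f"{path}: unit {meta['unit']!r} unsupported (expected mm)")
    if not rows:
        raise FormatError(f"{path}: no data rows")
    arr = np.asarray(rows)
    try:
        return Trajectory(arr[:, 0], arr[:, 1:4], frame=meta["frame"], label=meta["label"])
    except InvalidArgumentError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# landmarks / transforms / path models


def write_landmarks(lm: AnatomicalLandmarks, path) -> None:
    Path(path).write_text(json.dumps(lm.to_dict(), indent=2))


def read_landmarks(path) -> AnatomicalLandmarks:
    try:
        return AnatomicalLandmarks.from_dict(json.loads(Path(path).read_text()))
    except (KeyError, json.JSONDecodeError, InvalidArgumentError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_transform(t: FramedTransform, path) -> None:
    Path(path).write_text(json.dumps(t.to_dict(), indent=2))


def read_transform(path) -> FramedTransform:
    try:
        return FramedTransform.from_dict(json.loads(Path(path).read_text()))
    except (KeyError, json.JSONDecodeError, InvalidArgumentError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_path_model(model: CondylarPathModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def read_path_model(path) -> CondylarPathModel:
    try:
        return CondylarPathModel.from_dict(json.loads(Path(path).read_text()))
    except (KeyError, json.JSONDecodeError, InvalidArgumentError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# marker pose streams


def write_marker_stream(stream: MarkerPoseStream, path, fmt: str | None = None) -> None:
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        payload = [
            {"t": t, "T_cam_up": up.to_dict(), "T_cam_low": low.to_dict()}
            for t, up, low in stream.samples
        ]
        Path(path).write_text(json.dumps(payload))
        return
    with open(path, "w", newline="") as fh:
        fh.write("# unit=mm\n")
        writer = csv.writer(fh)
        header = (["t"] + [f"up_{i}{j}" for i in range(4) for j in range(4)]
                  + [f"low_{i}{j}" for i in range(4) for j in range(4)])
        writer.writerow(header)
        for t, up, low in stream.samples:
            row = (["%.12g" % t] + ["%.17g" % v for v in up.matrix.ravel()]
                   + ["%.17g" % v for v in low.matrix.ravel()])
            writer.writerow(row)


def read_marker_stream(path, fmt: str | None = None) -> MarkerPoseStream:
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        payload = json.loads(Path(path).read_text())
        samples = tuple(
            (float(e["t"]),
             FramedTransform.from_dict(e["T_cam_up"]),
             FramedTransform.from_dict(e["T_cam_low"]))
            for e in payload
        )
        return MarkerPoseStream(samples)
    samples = []
    with open(path, newline="") as fh:
        header_seen = False
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = next(csv.reader([line]))
            if not header_seen:
                header_seen = True
                continue
            if len(cells) != 33:
                raise FormatError(f"{path}:{lineno}: expected 33 columns, got {len(cells)}")
            try:
                vals = [float(c) for c in cells]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
            up = FramedTransform(np.asarray(vals[1:17]).reshape(4, 4), "marker_up", "camera")
            low = FramedTransform(np.asarray(vals[17:33]).reshape(4, 4), "marker_low", "camera")
            samples.append((vals[0], up, low))
    try:
        return MarkerPoseStream(tuple(samples))
    except InvalidArgumentError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# meshes


def read_mesh(path, fmt: str | None = None):
    """Load an STL (ASCII or binary) or PLY mesh with duplicate vertices
    welded (1e-6 mm tolerance) — STL carries no vertex indexing, so
    welding is required before proxy generation."""
    import trimesh

    p = Path(path)
    if not p.exists():
        raise FormatError(f"{path}: no such file")
    if p.stat().st_size == 0:
        raise FormatError(f"{path}: empty file")
    try:
        mesh = trimesh.load(str(p), file_type=fmt or p.suffix.lstrip(".").lower(),
                            force="mesh", process=False)
    except Exception as exc:  # trimesh raises various types on truncation
        raise FormatError(f"{path}: unreadable mesh ({exc})") from exc
    if mesh.vertices.shape[0] == 0:
        raise FormatError(f"{path}: mesh has no vertices")
    mesh.merge_vertices(digits_vertex=6)
    return mesh


def _infer_format(path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise InvalidArgumentError(f"format must be 'csv' or 'json', got {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower().lstrip(".")
    return "json" if suffix == "json" else "csv"
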