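"""Surface and annotation I/O: STL meshes, landmark JSON, colored PLY maps.

Coordinates are millimetres; STL carries no unit metadata, so files are
taken as stored (a ``scale`` argument is exposed for scans exported in other
units).  Landmarks use a small JSON dialect with fixed keys::

    {
      "right_alare": [x, y, z], "left_alare": [...], "subnasale": [...],
      "right_cheilion": [...], "left_cheilion": [...],
      "vermilion_border": [[x, y, z], ...]   # ordered right -> left, >= 3
    }
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

from .geometry import face_areas, weld_vertices

log = logging.getLogger(__name__)

WELD_TOL = 1e-6  # mm; below scanner precision, merges STL facet duplication

LANDMARK_NAMES = (
    "right_alare",
    "left_alare",
    "subnasale",
    "right_cheilion",
    "left_cheilion",
)


class MeshFormatError(ValueError):
    """Raised for unreadable or truncated mesh files."""


class MeshValidationError(ValueError):
    """Raised when a mesh violates structural invariants."""


class SchemaError(ValueError):
    """Raised for malformed landmark / trace JSON documents."""


@dataclass
class TriangleMesh:
    """A triangle surface mesh: ``vertices`` (n, 3) mm, ``faces`` (m, 3)."""

    vertices: np.ndarray
    faces: np.ndarray
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def area(self) -> float:
        """Total surface area in mm^2."""
        return float(face_areas(self.vertices, self.faces).sum())

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices, self.faces, process=False)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(),
                            dict(self.attributes))


@dataclass
class LandmarkSet:
    """The five named nasolabial landmarks plus the vermilion-border curve.

    The five points bound the upper lip superolaterally; the vermilion
    border (an ordered right-to-left curve of at least three points) closes
    the region inferiorly.
    """

    right_alare: np.ndarray
    left_alare: np.ndarray
    subnasale: np.ndarray
    right_cheilion: np.ndarray
    left_cheilion: np.ndarray
    vermilion_border: np.ndarray

    def __post_init__(self):
        for name in LANDMARK_NAMES:
            p = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise SchemaError(f"landmark {name} has non-finite coordinates")
            setattr(self, name, p)
        vb = np.asarray(self.vermilion_border, dtype=float).reshape(-1, 3)
        if len(vb) < 3:
            raise SchemaError(
                f"vermilion_border needs >= 3 points, got {len(vb)}"
            )
        if not np.all(np.isfinite(vb)):
            raise SchemaError("vermilion_border has non-finite coordinates")
        # ordered right -> left: monotone along the cheilion axis
        axis = self.left_cheilion - self.right_cheilion
        n = np.linalg.norm(axis)
        if n > 0:
            proj = vb @ (axis / n)
            if np.any(np.diff(proj) < -1e-9):
                raise SchemaError(
                    "vermilion_border points are not ordered right -> left"
                )
        self.vermilion_border = vb

    def named_points(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in LANDMARK_NAMES}

    def to_dict(self) -> dict:
        d = {name: getattr(self, name).tolist() for name in LANDMARK_NAMES}
        d["vermilion_border"] = self.vermilion_border.tolist()
        return d


@dataclass
class ValidationReport:
    degenerate_faces: np.ndarray
    unreferenced_vertices: np.ndarray
    out_of_range_faces: np.ndarray

    @property
    def ok(self) -> bool:
        return (
            len(self.degenerate_faces) == 0
            and len(self.unreferenced_vertices) == 0
            and len(self.out_of_range_faces) == 0
        )


def read_stl(path, scale: float = 1.0, weld_tol: float = WELD_TOL) -> TriangleMesh:
    """Read a binary or ASCII STL file, welding duplicated facet vertices.

    ``scale`` multiplies coordinates (STL stores no units; default assumes
    millimetres as stored).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tm = _trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # truncated / corrupt files
        raise MeshFormatError(f"cannot parse STL file {path}: {exc}") from exc
    if not isinstance(tm, _trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshValidationError(f"STL file {path} contains no triangles")
    v, f = weld_vertices(np.asarray(tm.vertices) * scale, np.asarray(tm.faces),
                         tol=weld_tol)
    if len(f) == 0:
        raise MeshValidationError(f"STL file {path} has only degenerate faces")
    return TriangleMesh(v, f)


def write_stl(mesh: TriangleMesh, path, binary: bool = True) -> None:
    """Write ``mesh`` as STL.  Vertex attributes (e.g. colors) are dropped
    with a warning: STL has no portable attribute channel."""
    if mesh.n_faces == 0 or mesh.n_vertices == 0:
        raise MeshValidationError("refusing to write an empty mesh")
    if mesh.attributes:
        warnings.warn(
            "STL cannot store vertex attributes; "
            f"dropping {sorted(mesh.attributes)}",
            stacklevel=2,
        )
        log.warning("STL export drops attributes %s", sorted(mesh.attributes))
    path = Path(path)
    tm = mesh.to_trimesh()
    data = tm.export(file_type="stl" if binary else "stl_ascii")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def read_landmarks(path) -> LandmarkSet:
    """Read the landmark JSON dialect (see module docstring)."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"landmark file {path} is not valid JSON: {exc}")
    return landmarks_from_dict(doc)


def landmarks_from_dict(doc: dict) -> LandmarkSet:
    missing = [n for n in LANDMARK_NAMES if n not in doc]
    if missing:
        raise SchemaError(f"landmark document missing required keys: {missing}")
    if "vermilion_border" not in doc:
        raise SchemaError("landmark document missing required key: "
                          "['vermilion_border']")
    return LandmarkSet(
        **{n: doc[n] for n in LANDMARK_NAMES},
        vermilion_border=doc["vermilion_border"],
    )


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(landmarks.to_dict(), fh, indent=1)
        fh.write("\n")


def validate_mesh(mesh: TriangleMesh, area_tol: float = 1e-12) -> ValidationReport:
    """Report degenerate faces, unreferenced vertices and out-of-range
    indices.  Report-only; downstream stages refuse meshes whose report
    contains out-of-range indices."""
    f = mesh.faces
    out_of_range = np.where(
        np.any((f < 0) | (f >= mesh.n_vertices), axis=1)
    )[0]
    in_range = np.setdiff1d(np.arange(len(f)), out_of_range)
    areas = face_areas(mesh.vertices, f[in_range])
    repeated = (
        (f[in_range, 0] == f[in_range, 1])
        | (f[in_range, 1] == f[in_range, 2])
        | (f[in_range, 0] == f[in_range, 2])
    )
    degenerate = in_range[(areas <= area_tol) | repeated]
    referenced = np.zeros(mesh.n_vertices, dtype=bool)
    if len(in_range):
        referenced[f[in_range].ravel()] = True
    unreferenced = np.where(~referenced)[0]
    return ValidationReport(degenerate, unreferenced, out_of_range)


def require_valid(mesh: TriangleMesh) -> ValidationReport:
    """Validate and raise on out-of-range face indices."""
    report = validate_mesh(mesh)
    if len(report.out_of_range_faces):
        raise MeshValidationError(
            f"faces {report.out_of_range_faces.tolist()} reference "
            "vertex indices outside the mesh"
        )
    return report


def _diverging_colors(scalar: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    """Map scalars to a fixed blue-white-red diverging scale (uchar RGB).

    The scale midpoint sits at (vmin+vmax)/2; values are clamped to the
    range so maps stay comparable across cases.
    """
    t = np.clip((np.asarray(scalar, float) - vmin) / (vmax - vmin), 0.0, 1.0)
    low = np.array([59, 76, 192], float)     # blue
    mid = np.array([245, 245, 245], float)   # near-white
    high = np.array([180, 4, 38], float)     # red
    rgb = np.empty((len(t), 3))
    lo = t <= 0.5
    rgb[lo] = low + (mid - low) * (t[lo, None] * 2.0)
    rgb[~lo] = mid + (high - mid) * ((t[~lo, None] - 0.5) * 2.0)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def export_colored_ply(
    mesh: TriangleMesh,
    scalar: np.ndarray,
    path,
    vmin: float = 0.0,
    vmax: float = 2.0,
) -> None:
    """Write an ASCII PLY with per-vertex RGB mapped from ``scalar``.

    Default range 0-2 mm: disparity maps from different cases share one
    scale.  Values beyond the range are clamped to the end colors.
    """
    scalar = np.asarray(scalar, dtype=float).ravel()
    if len(scalar) != mesh.n_vertices:
        raise ValueError(
            f"scalar length {len(scalar)} != vertex count {mesh.n_vertices}"
        )
    rgb = _diverging_colors(scalar, vmin, vmax)
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property float x",
        "property float y",
        "property float z",
        "property uchar red",
        "property uchar green",
        "property uchar blue",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v, c in zip(mesh.vertices, rgb):
        lines.append(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g} {c[0]} {c[1]} {c[2]}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    Path(path).write_text("\n".join(lines) + "\n")
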