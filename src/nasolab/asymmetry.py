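"""Mirror-based asymmetry measurement of an extracted upper-lip region.

The region is reflected through the mid-sagittal plane, the mirror is
superimposed on the original by rigid Procrustes surface registration
(trimmed iterative closest point with closed-form orthogonal-Procrustes
inner solves, no scaling), and the residual disparity between the two
surfaces is resolved along anatomical axes:

* X — mediolateral (right cheilion to left cheilion),
* Y — vertical (mid-cheilion toward subnasale),
* Z — depth (X cross Y).

Registration is rigid because the disparities are reported in millimetres;
a scale component would distort them.  The reported disparity is the raw
original-to-mirror distance (not halved): for an ideal mid-plane it is
about twice the one-sided deviation from symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SurfaceLocator, face_areas, face_normals
from .mesh_io import LandmarkSet, TriangleMesh


@dataclass
class AnatomicalFrame:
    """Right-handed orthonormal frame anchored at the subnasale."""

    origin: np.ndarray
    axes: np.ndarray  # rows are X, Y, Z unit vectors

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise ValueError("frame axes are not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("frame is left-handed")

    @property
    def X(self) -> np.ndarray:
        return self.axes[0]

    @property
    def Y(self) -> np.ndarray:
        return self.axes[1]

    @property
    def Z(self) -> np.ndarray:
        return self.axes[2]

    def to_frame(self, vectors: np.ndarray) -> np.ndarray:
        """Express world-space vectors in frame components."""
        return np.asarray(vectors, dtype=float) @ self.axes.T


@dataclass
class RigidTransform:
    """Rotation + translation, no scale.  ``apply`` maps points."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has a reflection component")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class DisplacementField:
    """Per-vertex disparity vectors, expressed in the anatomical frame."""

    vectors: np.ndarray  # (n, 3), frame components, mm
    frame: AnatomicalFrame
    weights: np.ndarray | None = None  # per-vertex area weights, mm^2

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float).reshape(-1, 3)
        if len(self.vectors) == 0:
            raise ValueError("displacement field is empty")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field has non-finite entries")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float).ravel()
            if len(self.weights) != len(self.vectors):
                raise ValueError("weights length does not match field length")

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)


@dataclass
class AsymmetrySummary:
    """Per-axis mean absolute disparity and total-disparity statistics (mm)."""

    mean_abs_x: float
    mean_abs_y: float
    mean_abs_z: float
    mean_total: float
    max_total: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_abs_x": self.mean_abs_x,
            "mean_abs_y": self.mean_abs_y,
            "mean_abs_z": self.mean_abs_z,
            "mean_total": self.mean_total,
            "max_total": self.max_total,
        }

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mean_abs_x, self.mean_abs_y, self.mean_abs_z,
             self.mean_total, self.max_total]
        )


@dataclass
class ICPResult:
    transform: RigidTransform
    rms: float                 # final untrimmed RMS over all correspondences
    iterations: int
    history: list = field(default_factory=list)  # trimmed RMS per iteration
    failed: bool = False
    trim_fraction: float = 0.9
    refine_iterations: int = 0  # point-to-plane polish steps


def anatomical_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Build the anatomical frame from snapped landmarks.

    X = unit(left_cheilion - right_cheilion); Y = component of
    (subnasale - mid-cheilion) orthogonal to X, normalised; Z = X x Y;
    origin at the subnasale.
    """
    r, l = landmarks.right_cheilion, landmarks.left_cheilion
    sn = landmarks.subnasale
    dx = l - r
    nx = np.linalg.norm(dx)
    if nx < 1e-9:
        raise ValueError("cheilions coincide; cannot define mediolateral axis")
    X = dx / nx
    mid = 0.5 * (l + r)
    t = sn - mid
    t_perp = t - (t @ X) * X
    ny = np.linalg.norm(t_perp)
    if ny < 1e-9:
        raise ValueError(
            "subnasale lies on the cheilion line; cannot define vertical axis"
        )
    Y = t_perp / ny
    Z = np.cross(X, Y)
    return AnatomicalFrame(sn, np.vstack([X, Y, Z]))


def mirror_about(mesh: TriangleMesh, origin: np.ndarray,
                 normal: np.ndarray) -> TriangleMesh:
    """Reflect ``mesh`` through the plane (origin, normal), reversing face
    winding so the surface orientation is preserved."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    o = np.asarray(origin, dtype=float)
    d = (mesh.vertices - o) @ n
    v = mesh.vertices - 2.0 * d[:, None] * n
    return TriangleMesh(v, mesh.faces[:, ::-1].copy())


def mirror_region(region, frame: AnatomicalFrame) -> TriangleMesh:
    """Mirror an extracted region through the mid-sagittal plane (the plane
    through the frame origin with normal X)."""
    mesh = region.mesh if hasattr(region, "mesh") else region
    return mirror_about(mesh, frame.origin, frame.X)


def _kabsch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form orthogonal Procrustes: rigid R, t minimising ||Ra+t-b||."""
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    H = (a - ca).T @ (b - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    return R, t


def _rodrigues(omega: np.ndarray) -> np.ndarray:
    """Exact rotation matrix for a rotation vector (axis * angle)."""
    theta = np.linalg.norm(omega)
    if theta < 1e-15:
        return np.eye(3)
    k = omega / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def icp_register(
    source: TriangleMesh,
    target: TriangleMesh,
    init: RigidTransform | None = None,
    trim: float = 0.9,
    tol: float = 1e-9,
    max_iter: int = 100,
    refine_iter: int = 60,
    fail_gate_mm: float = 5.0,
) -> ICPResult:
    """Rigid trimmed ICP aligning ``source`` onto ``target``.

    Coarse phase: each iteration matches transformed source vertices to
    their closest points on the target surface, keeps the best ``trim``
    fraction (90th-percentile gating reduces boundary/edge bias on open
    regions), and solves the orthogonal Procrustes problem on the kept
    pairs; the recorded trimmed RMS is non-increasing.  It stops when the
    trimmed-RMS change falls below ``tol`` mm or after ``max_iter``
    iterations.

    Refinement phase: up to ``refine_iter`` trimmed point-to-plane
    Gauss-Newton steps polish the weakly constrained motion components
    (near-tangential slides on smooth surfaces converge far too slowly
    under point-to-point steps).  The returned ``rms`` is the final
    untrimmed RMS, reported for transparency.

    The registration is flagged ``failed`` when fewer than half of the
    correspondences end up within ``fail_gate_mm`` of the target.
    """
    if not 0.0 < trim <= 1.0:
        raise ValueError("trim must be in (0, 1]")
    xf = init if init is not None else RigidTransform.identity()
    src = source.vertices
    if len(src) == 0 or len(target.vertices) == 0:
        raise ValueError("cannot register empty meshes")
    loc = SurfaceLocator(target.vertices, target.faces)
    tgt_normals = face_normals(target.vertices, target.faces)
    m = max(3, int(np.ceil(trim * len(src))))

    def match(p):
        closest, d, fid = loc.query_fast(p, k_faces=10)
        if m < len(d):
            keep = np.argpartition(d, m - 1)[:m]
        else:
            keep = np.arange(len(d))
        return closest, d, fid, keep

    history: list[float] = []
    prev = None
    iterations = 0
    for iterations in range(1, max_iter + 1):
        p = xf.apply(src)
        closest, d, _, keep = match(p)
        trimmed_rms = float(np.sqrt(np.mean(d[keep] ** 2)))
        history.append(trimmed_rms)
        R, t = _kabsch(src[keep], closest[keep])
        xf = RigidTransform(R, t)
        if prev is not None and abs(prev - trimmed_rms) < tol:
            break
        prev = trimmed_rms

    refine_iterations = 0
    for refine_iterations in range(1, refine_iter + 1):
        p = xf.apply(src)
        closest, d, fid, keep = match(p)
        pk = p[keep]
        qk = closest[keep]
        nk = tgt_normals[fid[keep]]
        c = pk.mean(axis=0)
        r = np.einsum("ij,ij->i", pk - qk, nk)
        J = np.hstack([np.cross(pk - c, nk), nk])
        A = J.T @ J
        b = -J.T @ r
        try:
            delta = np.linalg.solve(A + 1e-12 * np.eye(6), b)
        except np.linalg.LinAlgError:
            break
        Rd = _rodrigues(delta[:3])
        td = delta[3:]
        xf = RigidTransform(
            Rd @ xf.rotation, c + Rd @ (xf.translation - c) + td
        )
        if np.linalg.norm(delta) < 1e-13:
            break

    p = xf.apply(src)
    _, d, _ = loc.query_fast(p, k_faces=10)
    rms = float(np.sqrt(np.mean(d**2)))
    failed = bool(np.median(d) > fail_gate_mm)
    return ICPResult(xf, rms, iterations, history, failed, trim,
                     refine_iterations)


def displacement_field(
    region, registered_mirror: TriangleMesh, frame: AnatomicalFrame
) -> DisplacementField:
    """Vector from each region vertex to its closest point on the registered
    mirror surface (point-to-triangle), expressed in the anatomical frame."""
    mesh = region.mesh if hasattr(region, "mesh") else region
    if mesh.n_vertices == 0:
        raise ValueError("region is empty")
    loc = SurfaceLocator(registered_mirror.vertices, registered_mirror.faces)
    closest, _, _ = loc.query_fast(mesh.vertices, k_faces=32)
    vec_world = closest - mesh.vertices
    # barycentric vertex areas: the weighted vertex mean then approximates
    # the surface-integral mean, removing boundary over-counting
    fa = face_areas(mesh.vertices, mesh.faces)
    w = np.zeros(mesh.n_vertices)
    np.add.at(w, mesh.faces.ravel(), np.repeat(fa / 3.0, 3))
    return DisplacementField(frame.to_frame(vec_world), frame, weights=w)


def asymmetry_summary(fld: DisplacementField) -> AsymmetrySummary:
    """Mean of |component| per anatomical axis; mean and max disparity norm.

    When the field carries per-vertex area weights the means are
    area-weighted (the surface-integral estimate); otherwise plain means."""
    v = fld.vectors
    norms = np.linalg.norm(v, axis=1)
    w = fld.weights
    if w is not None and w.sum() > 0:
        ax, ay, az = (np.abs(v) * w[:, None]).sum(axis=0) / w.sum()
        mean_norm = float((norms * w).sum() / w.sum())
    else:
        ax, ay, az = np.mean(np.abs(v), axis=0)
        mean_norm = float(norms.mean())
    return AsymmetrySummary(
        float(ax), float(ay), float(az), mean_norm, float(norms.max()),
    )
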