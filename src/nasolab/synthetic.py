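"""Synthetic nasolabial surfaces with known ground truth.

The generator stands in for clinical intraoral-scanner captures, which are
not publicly available.  The base surface is a developable "lip barrel": a
circular-arc cylinder sheet whose axis runs mediolaterally, sweeping from a
curl below the vermilion up past the nasal sill.  A developable base was
chosen deliberately:

* on-surface geodesics are straight lines in the unrolled (u, s) plane, so
  region boundaries and their enclosed areas have exact closed forms;
* the flat area of the scar band is exactly width x centerline length;
* the default asymmetry-patch site (phi = 90 deg) has its surface normal
  aligned with the anatomical Y axis, so a Y-directed displacement is fully
  visible to closest-point disparity measurement.  (A displacement
  component tangent to the surface is invisible to surface-to-surface
  distance; aligning the normal with the injected direction is what makes
  exact parameter recovery possible.)

Injected features:

* an asymmetry patch — a C^1 cosine-tapered bump of peak ``delta_mm``
  displacing one side of the lip along a chosen anatomical axis;
* a scar band — a narrow ridge raised along the surface normal inside a
  closed rectangular (in the unrolled plane) boundary of known flat area;
* optional i.i.d. Gaussian vertex noise and a rigid pose perturbation.

All randomness is driven by ``SyntheticSpec.seed``; identical specs produce
bit-identical meshes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon

from .asymmetry import (
    AnatomicalFrame,
    AsymmetrySummary,
    RigidTransform,
    anatomical_frame,
)
from .mesh_io import LandmarkSet, TriangleMesh


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic case.  Lengths in mm, angles in degrees.

    Defaults describe a mild residual deformity on the patient's right:
    a 1 mm vertical patch displacement (the order of the residual
    asymmetries reported for repaired clefts), a 0.3 mm raised scar ridge,
    and 0.05 mm vertex noise (the accuracy class of intraoral scanners).
    """

    n: int = 96                     # grid cells per side
    width_mm: float = 76.0          # mediolateral extent (with cheek margin)
    radius_mm: float = 24.0         # barrel radius
    phi_min_deg: float = -145.0     # arc start (well below the vermilion curl)
    phi_max_deg: float = 145.0      # arc end (past the nasal sill)

    # landmarks (parametric positions on the base surface)
    cheilion_u_mm: float = 24.0
    cheilion_phi_deg: float = -111.0
    alare_u_mm: float = 22.0
    nasal_phi_deg: float = 111.0    # alares and subnasale
    n_vermilion: int = 5            # interior vermilion-border points

    # asymmetry patch (wide and gentle so closest-point disparity sees the
    # full injected displacement even at 2 mm magnitude)
    patch_center_u_mm: float = 12.0   # positive u = patient's right
    patch_phi_deg: float = 90.0
    patch_radius_mm: float = 9.0
    delta_mm: float = 1.0
    direction: str = "y"              # anatomical axis: "x", "y" or "z"

    # scar band (paramedian, on the cleft side, clear of the patch)
    scar_u_mm: float = 1.5
    scar_phi_deg: tuple = (-85.0, 75.0)
    scar_width_mm: float = 2.0
    ridge_height_mm: float = 0.3
    ridge_end_taper_mm: float = 2.0

    # mirror-symmetric surface relief over the lip band (philtrum/vermilion
    # texture stand-in; also removes the slide symmetry a pure surface of
    # revolution would have, which no real face has and which surface
    # registration could not pin).  Confined below the nasal sill so the
    # asymmetry patch sits on smooth surface.
    relief_amplitude_mm: float = 0.8
    relief_wavelength_u_mm: float = 12.9
    relief_wavelength_s_mm: float = 14.7
    relief_phi_deg: tuple = (-95.0, 45.0)
    relief_ramp_deg: float = 15.0

    # nuisance
    noise_sigma_mm: float = 0.05
    perturb_axis: tuple = (0.0, 0.0, 1.0)
    perturb_angle_deg: float = 0.0
    perturb_translation_mm: tuple = (0.0, 0.0, 0.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 8:
            raise ValueError("grid resolution n must be >= 8")
        if self.patch_radius_mm <= 0:
            raise ValueError("patch radius must be positive")
        if self.scar_width_mm <= 0:
            raise ValueError("scar width must be positive")
        if self.noise_sigma_mm < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.direction not in ("x", "y", "z"):
            raise ValueError("direction must be one of 'x', 'y', 'z'")
        if self.radius_mm <= 0 or self.width_mm <= 0:
            raise ValueError("extent parameters must be positive")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    landmarks: LandmarkSet
    frame: AnatomicalFrame
    scar_trace: np.ndarray          # closed polyline on the surface (k, 3)
    scar_area_flat_mm2: float       # exact: width x centerline length
    scar_area_mm2: float            # ridged 3D area (10x brute-force mesh)
    region_polygon_us: np.ndarray   # region boundary in unrolled (u, s), mm
    patch_center_us: tuple
    patch_radius_mm: float
    delta_mm: float
    direction: str
    scar_anchors: np.ndarray = None  # the 4 band corners (anchor points)
    spec: SyntheticSpec = field(repr=False, default=None)


def _surface(u: np.ndarray, phi: np.ndarray, R: float,
             spec: "SyntheticSpec | None" = None) -> np.ndarray:
    """Map unrolled coordinates (u, phi) to 3D points: a circular-arc barrel
    with an optional radial relief pattern, symmetric about u = 0."""
    r_eff = R
    if spec is not None and spec.relief_amplitude_mm:
        s = R * phi
        phi_deg = np.degrees(phi)
        lo, hi = spec.relief_phi_deg
        ramp0 = np.clip((phi_deg - lo) / spec.relief_ramp_deg, 0.0, 1.0)
        ramp1 = np.clip((hi - phi_deg) / spec.relief_ramp_deg, 0.0, 1.0)
        window = (0.5 - 0.5 * np.cos(np.pi * ramp0)) * (
            0.5 - 0.5 * np.cos(np.pi * ramp1))
        r_eff = R + spec.relief_amplitude_mm * window * (
            np.cos(2 * np.pi * u / spec.relief_wavelength_u_mm)
            * np.cos(2 * np.pi * s / spec.relief_wavelength_s_mm)
        )
    return np.stack(
        [u, r_eff * np.sin(phi), r_eff * np.cos(phi)], axis=-1
    )


def _bump(rho: np.ndarray, radius: float) -> np.ndarray:
    """C^1 cosine taper: 1 at the centre, 0 at and beyond ``radius``."""
    out = np.zeros_like(rho)
    inside = rho < radius
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * rho[inside] / radius))
    return out


def _ridge_profile(du: np.ndarray, s: np.ndarray, spec: SyntheticSpec,
                   R: float) -> np.ndarray:
    """Scar ridge height at transverse offset ``du`` and arc position ``s``.

    cos^2 across the width (zero at the band edges) times a cosine ramp
    over ``ridge_end_taper_mm`` inside each end, so the closed ground-truth
    boundary lies on undisplaced surface."""
    w = spec.scar_width_mm
    s0 = R * np.deg2rad(spec.scar_phi_deg[0])
    s1 = R * np.deg2rad(spec.scar_phi_deg[1])
    across = np.where(np.abs(du) < w / 2, np.cos(np.pi * du / w) ** 2, 0.0)
    m = spec.ridge_end_taper_mm
    ramp0 = np.clip((s - s0) / m, 0.0, 1.0)
    ramp1 = np.clip((s1 - s) / m, 0.0, 1.0)
    taper = (0.5 - 0.5 * np.cos(np.pi * ramp0)) * (0.5 - 0.5 * np.cos(np.pi * ramp1))
    inside_s = (s > s0) & (s < s1)
    return spec.ridge_height_mm * across * taper * inside_s


def _landmarks(spec: SyntheticSpec) -> LandmarkSet:
    R = spec.radius_mm
    phi_v = np.deg2rad(spec.cheilion_phi_deg)
    phi_n = np.deg2rad(spec.nasal_phi_deg)
    u_verm = np.linspace(
        spec.cheilion_u_mm * 0.75, -spec.cheilion_u_mm * 0.75,
        spec.n_vermilion,
    )
    vb = _surface(u_verm, np.full_like(u_verm, phi_v), R, spec)
    return LandmarkSet(
        right_alare=_surface(np.array(spec.alare_u_mm), np.array(phi_n), R, spec),
        left_alare=_surface(np.array(-spec.alare_u_mm), np.array(phi_n), R, spec),
        subnasale=_surface(np.array(0.0), np.array(phi_n), R, spec),
        right_cheilion=_surface(
            np.array(spec.cheilion_u_mm), np.array(phi_v), R, spec),
        left_cheilion=_surface(
            np.array(-spec.cheilion_u_mm), np.array(phi_v), R, spec),
        vermilion_border=vb,
    )


def _region_polygon(spec: SyntheticSpec) -> np.ndarray:
    """Region boundary in the unrolled plane: straight geodesics between
    the landmark anchors (exact on a developable surface)."""
    R = spec.radius_mm
    s_v = R * np.deg2rad(spec.cheilion_phi_deg)
    s_n = R * np.deg2rad(spec.nasal_phi_deg)
    return np.array(
        [
            [spec.cheilion_u_mm, s_v],
            [spec.alare_u_mm, s_n],
            [0.0, s_n],
            [-spec.alare_u_mm, s_n],
            [-spec.cheilion_u_mm, s_v],
        ]
    )


def _scar_trace_us(spec: SyntheticSpec, step: float = 1.0) -> np.ndarray:
    """Closed ground-truth scar boundary, densified, in unrolled coords."""
    R = spec.radius_mm
    w2 = spec.scar_width_mm / 2.0
    s0 = R * np.deg2rad(spec.scar_phi_deg[0])
    s1 = R * np.deg2rad(spec.scar_phi_deg[1])
    uL, uR = spec.scar_u_mm - w2, spec.scar_u_mm + w2
    corners = [(uL, s0), (uR, s0), (uR, s1), (uL, s1)]
    pts = []
    for (a, b), (c, d) in zip(corners, corners[1:] + corners[:1]):
        length = float(np.hypot(c - a, d - b))
        k = max(1, int(np.ceil(length / step)))
        t = np.linspace(0.0, 1.0, k, endpoint=False)
        pts.append(np.stack([a + t * (c - a), b + t * (d - b)], axis=1))
    return np.concatenate(pts)


def _displace(points_us: np.ndarray, spec: SyntheticSpec,
              frame: AnatomicalFrame) -> np.ndarray:
    """Map unrolled points through base surface + patch + ridge."""
    R = spec.radius_mm
    u = points_us[..., 0]
    s = points_us[..., 1]
    phi = s / R
    xyz = _surface(u, phi, R, spec)
    # asymmetry patch: axis-directed cosine bump
    rho = np.hypot(u - spec.patch_center_u_mm,
                   s - R * np.deg2rad(spec.patch_phi_deg))
    b = _bump(rho, spec.patch_radius_mm)
    axis_vec = {"x": frame.X, "y": frame.Y, "z": frame.Z}[spec.direction]
    xyz = xyz + spec.delta_mm * b[..., None] * axis_vec
    # scar ridge along the base surface normal
    h = _ridge_profile(u - spec.scar_u_mm, s, spec, R)
    normal = np.stack([np.zeros_like(phi), np.sin(phi), np.cos(phi)], axis=-1)
    return xyz + h[..., None] * normal


def _ridged_scar_area(spec: SyntheticSpec, frame: AnatomicalFrame,
                      oversample: int = 10) -> float:
    """Brute-force 3D area of the displaced scar band at ``oversample``-times
    the base grid resolution."""
    R = spec.radius_mm
    w2 = spec.scar_width_mm / 2.0
    s0 = R * np.deg2rad(spec.scar_phi_deg[0])
    s1 = R * np.deg2rad(spec.scar_phi_deg[1])
    base_step = max(spec.width_mm,
                    R * np.deg2rad(spec.phi_max_deg - spec.phi_min_deg)) / spec.n
    step = base_step / oversample
    nu = max(2, int(np.ceil(spec.scar_width_mm / step)))
    ns = max(2, int(np.ceil((s1 - s0) / step)))
    u = np.linspace(spec.scar_u_mm - w2, spec.scar_u_mm + w2, nu + 1)
    s = np.linspace(s0, s1, ns + 1)
    uu, ss = np.meshgrid(u, s, indexing="ij")
    pts = _displace(np.stack([uu, ss], axis=-1), spec, frame)
    a = pts[:-1, :-1]
    b = pts[1:, :-1]
    c = pts[1:, 1:]
    d = pts[:-1, 1:]
    area = 0.5 * (
        np.linalg.norm(np.cross(b - a, c - a), axis=-1)
        + np.linalg.norm(np.cross(c - a, d - a), axis=-1)
    )
    return float(area.sum())


def generate_case(spec: SyntheticSpec) -> tuple[TriangleMesh, GroundTruth]:
    """Generate one synthetic case: the scan mesh plus its ground truth.

    The mesh is an (n+1) x (n+1) vertex grid over the barrel, with the
    asymmetry patch and scar ridge applied, then Gaussian noise and the
    rigid pose perturbation.  Ground-truth landmarks and scar trace are
    carried through the pose perturbation (they are 'digitized' on the
    delivered scan) but not the noise."""
    spec.validate()
    if abs(spec.patch_center_u_mm) < spec.patch_radius_mm and spec.delta_mm != 0:
        warnings.warn(
            "asymmetry patch overlaps the mid-plane; the injected asymmetry "
            "is partially self-cancelling",
            stacklevel=2,
        )
    n = spec.n
    R = spec.radius_mm
    landmarks = _landmarks(spec)
    frame = anatomical_frame(landmarks)

    u = np.linspace(-spec.width_mm / 2, spec.width_mm / 2, n + 1)
    s = R * np.deg2rad(np.linspace(spec.phi_min_deg, spec.phi_max_deg, n + 1))
    uu, ss = np.meshgrid(u, s, indexing="ij")
    vertices = _displace(np.stack([uu, ss], axis=-1), spec, frame).reshape(-1, 3)

    idx = np.arange((n + 1) * (n + 1)).reshape(n + 1, n + 1)
    v00 = idx[:-1, :-1]
    v10 = idx[1:, :-1]
    v01 = idx[:-1, 1:]
    v11 = idx[1:, 1:]
    # cell diagonals flip across the mid-plane so the triangulation is
    # exactly mirror-symmetric (n is even-split by u = 0 when symmetric)
    right = (np.arange(n) >= n // 2)[:, None] & np.ones(n, dtype=bool)[None, :]
    tri1 = np.where(right[..., None],
                    np.stack([v00, v10, v11], axis=-1),
                    np.stack([v00, v10, v01], axis=-1))
    tri2 = np.where(right[..., None],
                    np.stack([v00, v11, v01], axis=-1),
                    np.stack([v10, v11, v01], axis=-1))
    faces = np.concatenate([tri1.reshape(-1, 3), tri2.reshape(-1, 3)])

    trace_us = _scar_trace_us(spec)
    trace_xyz = _displace(trace_us, spec, frame)
    anchors_xyz = _displace(_scar_trace_us(spec, step=np.inf), spec, frame)
    s_lo = R * np.deg2rad(spec.scar_phi_deg[0])
    s_hi = R * np.deg2rad(spec.scar_phi_deg[1])
    flat_area = spec.scar_width_mm * (s_hi - s_lo)
    ridged_area = _ridged_scar_area(spec, frame)

    mesh = TriangleMesh(vertices, faces)
    if spec.noise_sigma_mm > 0:
        mesh = add_noise(mesh, spec.noise_sigma_mm, spec.seed)
    if spec.perturb_angle_deg != 0 or any(spec.perturb_translation_mm):
        mesh = apply_rigid(mesh, spec.perturb_axis, spec.perturb_angle_deg,
                           spec.perturb_translation_mm)
        xf = _axis_angle_transform(spec.perturb_axis, spec.perturb_angle_deg,
                                   spec.perturb_translation_mm)
        trace_xyz = xf.apply(trace_xyz)
        anchors_xyz = xf.apply(anchors_xyz)
        lm = landmarks.to_dict()
        for k, v in lm.items():
            lm[k] = xf.apply(np.atleast_2d(v)).squeeze().tolist()
        landmarks = LandmarkSet(**lm)
        frame = anatomical_frame(landmarks)

    truth = GroundTruth(
        landmarks=landmarks,
        frame=frame,
        scar_trace=trace_xyz,
        scar_anchors=anchors_xyz,
        scar_area_flat_mm2=float(flat_area),
        scar_area_mm2=ridged_area,
        region_polygon_us=_region_polygon(spec),
        patch_center_us=(spec.patch_center_u_mm,
                         R * np.deg2rad(spec.patch_phi_deg)),
        patch_radius_mm=spec.patch_radius_mm,
        delta_mm=spec.delta_mm,
        direction=spec.direction,
        spec=spec,
    )
    return mesh, truth


def _axis_angle_transform(axis, angle_deg: float, translation) -> RigidTransform:
    axis = np.asarray(axis, dtype=float)
    na = np.linalg.norm(axis)
    angle = np.deg2rad(angle_deg)
    if na < 1e-12:
        if angle != 0:
            raise ValueError("zero rotation axis with nonzero angle")
        return RigidTransform(np.eye(3), np.asarray(translation, float))
    k = axis / na  # non-unit axes are normalised silently
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    return RigidTransform(R, np.asarray(translation, dtype=float))


def apply_rigid(mesh: TriangleMesh, axis, angle_deg: float,
                translation) -> TriangleMesh:
    """Rigidly move a mesh: v -> R v + t (axis-angle rotation, degrees)."""
    xf = _axis_angle_transform(axis, angle_deg, translation)
    return TriangleMesh(xf.apply(mesh.vertices), mesh.faces.copy())


def add_noise(mesh: TriangleMesh, sigma: float, seed: int) -> TriangleMesh:
    """Add i.i.d. Gaussian noise (0, sigma^2) per coordinate, seeded."""
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    if sigma == 0:
        return mesh.copy()
    rng = np.random.default_rng(seed)
    return TriangleMesh(
        mesh.vertices + rng.normal(0.0, sigma, size=mesh.vertices.shape),
        mesh.faces.copy(),
    )


def oracle_asymmetry(truth: GroundTruth, sample_step: float = 0.15) -> AsymmetrySummary:
    """Brute-force expected asymmetry summary from the stored analytic
    displacement field, by dense sampling of the unrolled region polygon.

    No registration or meshing is involved: at each sample the disparity
    magnitude is delta * (b(u, s) + b(-u, s)) — the patch is seen once where
    the original surface is displaced and once where the mirror is — and the
    direction is the injected anatomical axis.  Exact up to quadrature."""
    poly = Polygon(truth.region_polygon_us)
    u_min, s_min, u_max, s_max = poly.bounds
    nu = int(np.ceil((u_max - u_min) / sample_step))
    ns = int(np.ceil((s_max - s_min) / sample_step))
    u = u_min + (np.arange(nu) + 0.5) * (u_max - u_min) / nu
    s = s_min + (np.arange(ns) + 0.5) * (s_max - s_min) / ns
    uu, ss = np.meshgrid(u, s, indexing="ij")
    mask = contains_xy(poly, uu.ravel(), ss.ravel()).reshape(uu.shape)
    if not mask.any():
        raise ValueError("region polygon is degenerate")
    uc, sc = truth.patch_center_us
    rho_o = np.hypot(uu - uc, ss - sc)
    rho_m = np.hypot(-uu - uc, ss - sc)
    mag = truth.delta_mm * (
        _bump(rho_o, truth.patch_radius_mm) + _bump(rho_m, truth.patch_radius_mm)
    )
    mag = mag[mask]
    mean = float(mag.mean())
    peak = float(mag.max())
    per_axis = {"x": 0.0, "y": 0.0, "z": 0.0}
    per_axis[truth.direction] = mean
    return AsymmetrySummary(
        per_axis["x"], per_axis["y"], per_axis["z"], mean, peak
    )
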