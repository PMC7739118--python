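"""Per-case and cohort orchestration of the measurement pipeline.

A case runs: snap landmarks -> anatomical frame -> upper-lip boundary ->
region extraction -> mirror -> rigid registration -> displacement field ->
asymmetry summary, plus scar trace -> clip -> surface area when a trace is
supplied.  Reports record the conventions that matter for interpreting the
numbers (disparity is the raw original-to-mirror distance, axes are the
landmark-derived anatomical frame) because different choices exist in the
literature.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import asymmetry as asy
from . import region as reg
from . import scar as scr
from . import stats as st
from .mesh_io import (
    LandmarkSet,
    TriangleMesh,
    export_colored_ply,
    read_landmarks,
    read_stl,
    require_valid,
)

log = logging.getLogger(__name__)

REPORT_HEADER = {
    "disparity_convention": "raw original-to-mirror closest-point distance, "
                            "unsigned, not halved",
    "area_convention": "true 3D surface area of the clipped patch",
    "frame": "X mediolateral (right->left cheilion), Y vertical "
             "(mid-cheilion->subnasale, orthogonalised), Z = X x Y, "
             "origin at subnasale",
    "units": "mm / mm^2",
}


@dataclass
class Config:
    """Every tolerance and convention of the pipeline, with defaults."""

    snap_tolerance_mm: float = 1.0
    weld_tolerance_mm: float = 1e-6
    stl_scale: float = 1.0
    icp_trim: float = 0.9
    icp_tol_mm: float = 1e-9
    icp_max_iter: int = 100
    icp_fail_gate_mm: float = 5.0
    colormap_max_mm: float = 2.0
    trace_bridge_factor: float = 2.5

    @classmethod
    def from_file(cls, path) -> "Config":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class CaseResult:
    """One case's objective measurements and diagnostics."""

    case_id: str
    summary: asy.AsymmetrySummary | None = None
    scar_area_mm2: float | None = None
    scar_trace_length_mm: float | None = None
    icp_rms_mm: float | None = None
    icp_iterations: int | None = None
    icp_trim_fraction: float | None = None
    registration_failed: bool = False
    landmark_repeat_mm: dict | None = None
    warnings: list = field(default_factory=list)
    error: str | None = None

    def as_dict(self) -> dict:
        d = {
            "case_id": self.case_id,
            "scar_area_mm2": self.scar_area_mm2,
            "scar_trace_length_mm": self.scar_trace_length_mm,
            "icp_rms_mm": self.icp_rms_mm,
            "icp_iterations": self.icp_iterations,
            "icp_trim_fraction": self.icp_trim_fraction,
            "registration_failed": self.registration_failed,
            "landmark_repeat_mm": self.landmark_repeat_mm,
            "warnings": list(self.warnings),
            "error": self.error,
        }
        if self.summary is not None:
            d.update({f"{k}_mm": v for k, v in self.summary.as_dict().items()})
        return d


def _jsonify(obj):
    """json.dump default hook for numpy scalar types."""
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc
        return wrapper
    return deco


def read_trace_json(path) -> dict:
    """Read the scar-trace JSON dialect: {"anchors": [[x,y,z] x4],
    "polyline": [[x,y,z], ...] (optional full loop)}."""
    with open(path) as fh:
        doc = json.load(fh)
    if "anchors" not in doc:
        raise ValueError(f"trace file {path} lacks 'anchors'")
    anchors = np.asarray(doc["anchors"], dtype=float)
    polyline = np.asarray(doc["polyline"], dtype=float) if doc.get("polyline") else None
    return {"anchors": anchors, "polyline": polyline}


def write_trace_json(anchors: np.ndarray, polyline: np.ndarray | None, path) -> None:
    doc = {"anchors": np.asarray(anchors, float).tolist()}
    if polyline is not None:
        doc["polyline"] = np.asarray(polyline, float).tolist()
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def measure_asymmetry(
    mesh: TriangleMesh, landmarks: LandmarkSet, config: Config | None = None
) -> tuple[asy.AsymmetrySummary, asy.DisplacementField, reg.RegionMesh,
           asy.ICPResult, asy.AnatomicalFrame]:
    """The asymmetry half of the pipeline on in-memory objects."""
    cfg = config or Config()
    snapped = _stage("snap_landmarks")(reg.snap_landmarks)(
        mesh, landmarks, cfg.snap_tolerance_mm)
    frame = _stage("anatomical_frame")(asy.anatomical_frame)(snapped)
    boundary = _stage("boundary")(reg.boundary_from_landmarks)(
        mesh, snapped, cfg.snap_tolerance_mm)
    region = _stage("extract_region")(reg.extract_region)(mesh, boundary)
    mirror = _stage("mirror")(asy.mirror_region)(region, frame)
    icp = _stage("register")(asy.icp_register)(
        mirror, region.mesh, trim=cfg.icp_trim, tol=cfg.icp_tol_mm,
        max_iter=cfg.icp_max_iter, fail_gate_mm=cfg.icp_fail_gate_mm)
    registered = TriangleMesh(icp.transform.apply(mirror.vertices), mirror.faces)
    fld = _stage("displacement_field")(asy.displacement_field)(
        region, registered, frame)
    summary = asy.asymmetry_summary(fld)
    return summary, fld, region, icp, frame


def measure_scar(
    mesh: TriangleMesh, anchors: np.ndarray, polyline: np.ndarray | None,
    config: Config | None = None,
) -> tuple[float, scr.ScarTrace]:
    """The scar half of the pipeline: trace, clip, measure area."""
    cfg = config or Config()
    trace = _stage("build_trace")(scr.build_trace)(
        mesh, anchors, polyline, snap_tol=cfg.snap_tolerance_mm,
        bridge_factor=cfg.trace_bridge_factor)
    seed = scr.trace_interior_seed(trace)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # side check below
        clipped = _stage("enclosed_faces")(scr.enclosed_faces)(trace, seed)
    if clipped.area_inside > clipped.area_outside:
        # the seed heuristic landed outside; a scar patch is by definition
        # the smaller side of its trace, so re-seed from the complement
        out_face = clipped.refined.faces[clipped.outside_faces[0]]
        seed2 = clipped.refined.vertices[out_face].mean(axis=0)
        clipped = _stage("enclosed_faces")(scr.enclosed_faces)(trace, seed2)
    return scr.surface_area(clipped), trace


def landmark_reproducibility(a, b) -> dict:
    """Euclidean distance (mm) between two digitizations of each named
    landmark, with mean and max — the repeat-digitization check."""
    def named(x):
        if isinstance(x, LandmarkSet):
            return x.named_points()
        return {k: np.asarray(v, dtype=float) for k, v in x.items()
                if k != "vermilion_border"}

    da, db = named(a), named(b)
    if set(da) != set(db):
        missing = sorted(set(da) ^ set(db))
        raise ValueError(f"landmark sets do not match; differing: {missing}")
    per = {k: float(np.linalg.norm(da[k] - db[k])) for k in sorted(da)}
    vals = list(per.values())
    return {"per_landmark": per, "mean": float(np.mean(vals)),
            "max": float(np.max(vals))}


def run_case(
    mesh_path,
    landmarks_path,
    trace_path=None,
    config: Config | None = None,
    case_id: str | None = None,
    out_dir=None,
    landmarks_repeat_path=None,
) -> CaseResult:
    """Run the full objective measurement on one case's files."""
    cfg = config or Config()
    case_id = case_id or Path(mesh_path).stem
    result = CaseResult(case_id=case_id)
    mesh = _stage("read_mesh")(read_stl)(
        mesh_path, scale=cfg.stl_scale, weld_tol=cfg.weld_tolerance_mm)
    report = _stage("validate_mesh")(require_valid)(mesh)
    if len(report.degenerate_faces):
        result.warnings.append(
            f"{len(report.degenerate_faces)} degenerate faces in the scan")
    landmarks = _stage("read_landmarks")(read_landmarks)(landmarks_path)

    summary, fld, region, icp, frame = measure_asymmetry(mesh, landmarks, cfg)
    result.summary = summary
    result.icp_rms_mm = icp.rms
    result.icp_iterations = icp.iterations
    result.icp_trim_fraction = icp.trim_fraction
    result.registration_failed = icp.failed
    if icp.failed:
        result.warnings.append("registration flagged as failed; asymmetry "
                               "values are unreliable")

    if trace_path is not None and Path(trace_path).exists():
        tr = _stage("read_trace")(read_trace_json)(trace_path)
        area, trace = measure_scar(mesh, tr["anchors"], tr["polyline"], cfg)
        result.scar_area_mm2 = area
        result.scar_trace_length_mm = trace.length()
    elif trace_path is not None:
        result.warnings.append(f"trace file {trace_path} not found; "
                               "scar area not measured")

    if landmarks_repeat_path is not None:
        repeat = _stage("read_landmarks_repeat")(read_landmarks)(
            landmarks_repeat_path)
        result.landmark_repeat_mm = landmark_reproducibility(landmarks, repeat)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        export_colored_ply(
            region.mesh, fld.magnitudes(), out_dir / f"{case_id}_disparity.ply",
            vmin=0.0, vmax=cfg.colormap_max_mm)
        with open(out_dir / f"{case_id}_result.json", "w") as fh:
            json.dump({"header": REPORT_HEADER, **result.as_dict()}, fh,
                      indent=1, sort_keys=True, default=_jsonify)
            fh.write("\n")
    return result


def run_cohort(
    manifest_path,
    ratings_path=None,
    config: Config | None = None,
    out_dir=None,
) -> dict:
    """Run every case of a manifest CSV and assemble the cohort report.

    Manifest columns: case, mesh, landmarks[, trace, landmarks_repeat];
    paths are taken relative to the manifest file.  Per-case failures are
    recorded and the cohort continues."""
    cfg = config or Config()
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, dtype=str)
    if manifest.empty:
        raise ValueError(f"manifest {manifest_path} has no cases")
    for col in ("case", "mesh", "landmarks"):
        if col not in manifest.columns:
            raise ValueError(f"manifest missing column {col!r}")
    base = manifest_path.parent

    def respath(v):
        return None if (v is None or (isinstance(v, float) and np.isnan(v))
                        or v == "") else base / v

    results: list[CaseResult] = []
    for _, row in manifest.iterrows():
        cid = str(row["case"])
        try:
            res = run_case(
                respath(row["mesh"]), respath(row["landmarks"]),
                trace_path=respath(row.get("trace")),
                config=cfg, case_id=cid,
                out_dir=None if out_dir is None else Path(out_dir) / "cases",
                landmarks_repeat_path=respath(row.get("landmarks_repeat")),
            )
        except Exception as exc:
            log.error("case %s failed: %s", cid, exc)
            res = CaseResult(case_id=cid, error=str(exc))
        results.append(res)

    rows = [r.as_dict() for r in results]
    measurements = pd.DataFrame(
        [
            {"case": r.case_id, "scar_area_mm2": r.scar_area_mm2,
             "mean_total_mm": None if r.summary is None
             else r.summary.mean_total}
            for r in results if r.error is None
        ]
    )
    report: dict = {
        "header": REPORT_HEADER,
        "config": cfg.as_dict(),
        "cases": rows,
        "n_cases": len(rows),
        "n_failed": int(sum(r.error is not None for r in results)),
    }
    if ratings_path is not None:
        ratings = st.read_ratings_csv(ratings_path)
        tables = st.reliability_tables(ratings)
        report["intra_rater"] = tables["intra"].to_dict(orient="records")
        report["inter_panel"] = tables["inter"].to_dict(orient="records")
        usable = measurements.dropna()
        if not usable.empty:
            corr = st.subjective_objective_correlation(ratings, usable)
            report["subjective_objective"] = corr.to_dict(orient="records")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "cohort_report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=_jsonify)
            fh.write("\n")
        pd.DataFrame(rows).to_csv(out_dir / "cases.csv", index=False)
        if not measurements.empty:
            measurements.to_csv(out_dir / "measurements.csv", index=False)
    return report
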