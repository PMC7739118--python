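"""Shared fixtures: small analytic meshes and pre-computed synthetic-case
pipeline runs (session-scoped; the full measurement takes seconds)."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from nasolab import asymmetry as asy
from nasolab import pipeline
from nasolab import region as reg
from nasolab import synthetic
from nasolab.mesh_io import TriangleMesh


def make_plane_grid(n: int, size: float = 1.0, z: float = 0.0,
                    jitter: float = 0.0, seed: int = 0) -> TriangleMesh:
    """A triangulated square grid in the z-plane (optionally jittered)."""
    xs = np.linspace(0.0, size, n + 1)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    zz = np.full(xx.size, float(z))
    v = np.stack([xx.ravel(), yy.ravel(), zz], axis=1)
    if jitter:
        rng = np.random.default_rng(seed)
        v[:, 2] += rng.normal(0.0, jitter, size=len(v))
    idx = np.arange((n + 1) * (n + 1)).reshape(n + 1, n + 1)
    a = idx[:-1, :-1]
    b = idx[1:, :-1]
    c = idx[1:, 1:]
    d = idx[:-1, 1:]
    # alternate cell diagonals (checkerboard) so both diagonal directions
    # exist and the edge-graph metric is direction-symmetric
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    even = ((ii + jj) % 2 == 0)[..., None]
    tri1 = np.where(even, np.stack([a, b, c], -1), np.stack([a, b, d], -1))
    tri2 = np.where(even, np.stack([a, c, d], -1), np.stack([b, c, d], -1))
    faces = np.concatenate([tri1.reshape(-1, 3), tri2.reshape(-1, 3)])
    return TriangleMesh(v, faces)


def densify_loop(loop: np.ndarray, step: float) -> np.ndarray:
    """Closed polygon -> dense point loop with roughly ``step`` spacing."""
    pts = []
    for p, q in zip(loop, np.roll(loop, -1, axis=0)):
        length = np.linalg.norm(q - p)
        k = max(1, int(round(length / step)))
        for t in np.arange(k) / k:
            pts.append(p + t * (q - p))
    return np.array(pts)


UNIT_CUBE_ASCII_STL = "solid cube\n" + "".join(
    "facet normal 0 0 0\nouter loop\n"
    + "".join(f"vertex {v[0]} {v[1]} {v[2]}\n" for v in tri)
    + "endloop\nendfacet\n"
    for tri in [
        # -z
        [(0, 0, 0), (1, 1, 0), (1, 0, 0)], [(0, 0, 0), (0, 1, 0), (1, 1, 0)],
        # +z
        [(0, 0, 1), (1, 0, 1), (1, 1, 1)], [(0, 0, 1), (1, 1, 1), (0, 1, 1)],
        # -y
        [(0, 0, 0), (1, 0, 0), (1, 0, 1)], [(0, 0, 0), (1, 0, 1), (0, 0, 1)],
        # +y
        [(0, 1, 0), (1, 1, 1), (1, 1, 0)], [(0, 1, 0), (0, 1, 1), (1, 1, 1)],
        # -x
        [(0, 0, 0), (0, 0, 1), (0, 1, 1)], [(0, 0, 0), (0, 1, 1), (0, 1, 0)],
        # +x
        [(1, 0, 0), (1, 1, 1), (1, 0, 1)], [(1, 0, 0), (1, 1, 0), (1, 1, 1)],
    ]
) + "endsolid cube\n"


@pytest.fixture
def cube_stl(tmp_path):
    path = tmp_path / "cube.stl"
    path.write_text(UNIT_CUBE_ASCII_STL)
    return path


def clean_case(**kwargs) -> synthetic.SyntheticSpec:
    """A noiseless, ridge-free, patch-controlled synthetic spec."""
    base = dict(delta_mm=0.0, noise_sigma_mm=0.0, ridge_height_mm=0.0)
    base.update(kwargs)
    return synthetic.SyntheticSpec(**base)


class CaseAnalysis:
    """One synthetic case run through the asymmetry half of the pipeline."""

    def __init__(self, spec: synthetic.SyntheticSpec):
        self.spec = spec
        self.mesh, self.truth = synthetic.generate_case(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.landmarks = reg.snap_landmarks(self.mesh, self.truth.landmarks)
            self.frame = asy.anatomical_frame(self.landmarks)
            self.boundary = reg.boundary_from_landmarks(self.mesh, self.landmarks)
            self.region = reg.extract_region(self.mesh, self.boundary)
            self.mirror = asy.mirror_region(self.region, self.frame)
            self.icp = asy.icp_register(self.mirror, self.region.mesh)
            registered = TriangleMesh(
                self.icp.transform.apply(self.mirror.vertices), self.mirror.faces)
            self.field = asy.displacement_field(self.region, registered, self.frame)
            self.summary = asy.asymmetry_summary(self.field)
        self.oracle = synthetic.oracle_asymmetry(self.truth)


@pytest.fixture(scope="session")
def null_case():
    """Noiseless perfectly symmetric case, fully analysed."""
    return CaseAnalysis(clean_case())


@pytest.fixture(scope="session")
def delta1_case():
    """Noiseless case with a 1 mm vertical patch, fully analysed."""
    return CaseAnalysis(clean_case(delta_mm=1.0))


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """A 3-case synthetic cohort written to disk (deltas 0, 1, 2 mm)."""
    import pandas as pd

    from nasolab.mesh_io import write_landmarks, write_stl

    root = tmp_path_factory.mktemp("cohort")
    rows = []
    for i, d in enumerate((0.0, 1.0, 2.0)):
        spec = synthetic.SyntheticSpec(delta_mm=d, seed=100 + i)
        mesh, truth = synthetic.generate_case(spec)
        cdir = root / f"case{i}"
        cdir.mkdir()
        write_stl(mesh, cdir / "mesh.stl")
        write_landmarks(truth.landmarks, cdir / "landmarks.json")
        pipeline.write_trace_json(truth.scar_anchors, truth.scar_trace,
                                  cdir / "trace.json")
        rows.append({"case": f"case{i}", "mesh": f"case{i}/mesh.stl",
                     "landmarks": f"case{i}/landmarks.json",
                     "trace": f"case{i}/trace.json"})
    pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)
    # panel ratings driven by the injected severities
    from nasolab import stats as st

    severities = pd.DataFrame({
        "case": [r["case"] for r in rows],
        "scar_area_mm2": [140.0, 150.0, 160.0],
        "mean_total_mm": [0.05, 0.09, 0.13],
    })
    ratings = st.simulate_ratings(severities, seed=11)
    ratings[["case", "rater", "panel", "occasion", *st.SCORE_COLUMNS]].to_csv(
        root / "ratings.csv", index=False)
    return root
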