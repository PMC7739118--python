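import numpy as np
import pytest
import trimesh

from nasolab import pipeline, scar, synthetic
from nasolab.geometry import weld_vertices
from nasolab.mesh_io import TriangleMesh
from nasolab.synthetic import generate_case

from .conftest import clean_case, densify_loop, make_plane_grid

UNIT_SQUARE = np.array([[0.5, 0.5, 0], [1.5, 0.5, 0],
                        [1.5, 1.5, 0], [0.5, 1.5, 0]])


@pytest.fixture(scope="module")
def grid2mm():
    return make_plane_grid(20, 2.0)


class TestBuildTrace:
    def test_too_few_points_rejected(self, grid2mm):
        with pytest.raises(ValueError, match=">= 4|4 anchor"):
            scar.build_trace(grid2mm, UNIT_SQUARE[:3])

    def test_duplicate_points_rejected(self, grid2mm):
        loop = np.vstack([UNIT_SQUARE, UNIT_SQUARE[-1]])
        with pytest.raises(ValueError, match="duplicate"):
            scar.build_trace(grid2mm, UNIT_SQUARE, loop)

    def test_off_surface_point_rejected(self, grid2mm):
        bad = UNIT_SQUARE + np.array([0, 0, 5.0])
        with pytest.raises(ValueError, match="off the surface"):
            scar.build_trace(grid2mm, bad)

    def test_anchor_must_lie_on_polyline(self, grid2mm):
        loop = densify_loop(UNIT_SQUARE, 0.1)
        far_anchor = UNIT_SQUARE.copy()
        # an anchor > snap_tol from every polyline point
        with pytest.raises(ValueError, match="anchor"):
            scar.build_trace(grid2mm, far_anchor + np.array([0.3, 0.35, 0]),
                             loop, snap_tol=0.2)

    def test_sparse_corners_bridged_to_closed_loop(self, grid2mm):
        """Four corner clicks alone are bridged by on-surface shortest
        paths into a closed trace whose length is close to the perimeter."""
        tr = scar.build_trace(grid2mm, UNIT_SQUARE)
        perim = 4.0
        assert perim <= tr.length() <= 1.08 * perim

    def test_synthetic_trace_follows_ground_truth(self):
        mesh, truth = generate_case(clean_case(ridge_height_mm=0.3))
        tr = scar.build_trace(mesh, truth.scar_anchors, truth.scar_trace)
        # mean deviation from the analytic boundary below one grid cell
        from scipy.spatial import cKDTree

        d, _ = cKDTree(truth.scar_trace).query(tr.points)
        cell = truth.spec.width_mm / truth.spec.n
        assert d.mean() < cell


class TestEnclosedFaces:
    def test_unit_square_exact(self, grid2mm):
        tr = scar.build_trace(grid2mm, UNIT_SQUARE,
                              densify_loop(UNIT_SQUARE, 0.1))
        clip = scar.enclosed_faces(tr, np.array([1.0, 1.0, 0.0]))
        assert clip.area_inside == pytest.approx(1.0, abs=1e-12)

    def test_offgrid_rectangle_half_percent(self, grid2mm):
        rect = np.array([[0.33, 0.27, 0], [1.18, 0.27, 0],
                         [1.18, 0.87, 0], [0.33, 0.87, 0]])
        tr = scar.build_trace(grid2mm, rect, densify_loop(rect, 0.07))
        clip = scar.enclosed_faces(tr, np.array([0.7, 0.5, 0.0]))
        expected = 0.85 * 0.6
        assert clip.area_inside == pytest.approx(expected, rel=0.005)

    def test_partition_of_parent_area(self, grid2mm):
        rect = np.array([[0.33, 0.27, 0], [1.18, 0.27, 0],
                         [1.18, 0.87, 0], [0.33, 0.87, 0]])
        tr = scar.build_trace(grid2mm, rect, densify_loop(rect, 0.07))
        clip = scar.enclosed_faces(tr, np.array([0.7, 0.5, 0.0]))
        assert clip.area_inside + clip.area_outside == pytest.approx(
            clip.parent_area, rel=1e-9)

    def test_seed_outside_warns_and_selects_complement(self, grid2mm):
        tr = scar.build_trace(grid2mm, UNIT_SQUARE,
                              densify_loop(UNIT_SQUARE, 0.1))
        with pytest.warns(UserWarning, match="outside"):
            clip = scar.enclosed_faces(tr, np.array([0.1, 0.1, 0.0]))
        assert clip.area_inside == pytest.approx(4.0 - 1.0, abs=1e-9)

    def test_trace_around_single_face(self):
        mesh = make_plane_grid(4, 4.0)
        # one triangle: (0,0) (1,0) (1,1); trace its edges via 4 points
        loop = np.array([[0, 0, 0], [0.5, 0, 0], [1, 0, 0], [1, 1, 0]],
                        dtype=float)
        tr = scar.build_trace(mesh, loop)
        clip = scar.enclosed_faces(tr, np.array([0.7, 0.25, 0.0]))
        assert clip.area_inside == pytest.approx(0.5, abs=1e-12)

    def test_spherical_cap_area(self):
        R = 10.0
        sph = trimesh.creation.uv_sphere(radius=R, count=(100, 100))
        v, f = weld_vertices(np.asarray(sph.vertices), np.asarray(sph.faces))
        mesh = TriangleMesh(v, f)
        theta = np.deg2rad(57.0)
        m = 128
        ang = 2 * np.pi * np.arange(m) / m + 0.013
        circle = np.stack(
            [R * np.sin(theta) * np.cos(ang), R * np.sin(theta) * np.sin(ang),
             np.full(m, R * np.cos(theta))], axis=1)
        tr = scar.build_trace(mesh, circle[[0, m // 4, m // 2, 3 * m // 4]],
                              circle)
        clip = scar.enclosed_faces(tr, np.array([0.0, 0.0, R]))
        expected = 2 * np.pi * R * R * (1 - np.cos(theta))
        assert clip.area_inside == pytest.approx(expected, rel=0.02)
        assert clip.area_inside + clip.area_outside == pytest.approx(
            clip.parent_area, rel=1e-9)


class TestSurfaceArea:
    def test_area_invariant_under_rigid_motion(self):
        mesh, truth = generate_case(clean_case(ridge_height_mm=0.3))
        area0, _ = pipeline.measure_scar(mesh, truth.scar_anchors,
                                         truth.scar_trace)
        spec_moved = clean_case(ridge_height_mm=0.3, perturb_angle_deg=23.0,
                                perturb_axis=(1.0, 0.4, -0.2),
                                perturb_translation_mm=(5.0, -3.0, 8.0))
        mesh2, truth2 = generate_case(spec_moved)
        area1, _ = pipeline.measure_scar(mesh2, truth2.scar_anchors,
                                         truth2.scar_trace)
        assert area1 == pytest.approx(area0, rel=1e-9)

    def test_measured_area_matches_brute_force_truth(self):
        mesh, truth = generate_case(clean_case(ridge_height_mm=0.3))
        area, _ = pipeline.measure_scar(mesh, truth.scar_anchors,
                                        truth.scar_trace)
        assert area == pytest.approx(truth.scar_area_mm2, rel=0.02)

    def test_area_monotone_in_ridge_height(self):
        areas = []
        for h in (0.0, 0.3, 0.6):
            mesh, truth = generate_case(clean_case(ridge_height_mm=h))
            a, _ = pipeline.measure_scar(mesh, truth.scar_anchors,
                                         truth.scar_trace)
            areas.append(a)
        assert areas[0] < areas[1] < areas[2]

    def test_disjoint_subsets_additive(self, grid2mm):
        sq1 = np.array([[0.2, 0.2, 0], [0.8, 0.2, 0], [0.8, 0.8, 0],
                        [0.2, 0.8, 0]])
        sq2 = sq1 + np.array([1.0, 1.0, 0.0])
        areas = []
        for sq in (sq1, sq2):
            tr = scar.build_trace(grid2mm, sq, densify_loop(sq, 0.07))
            clip = scar.enclosed_faces(tr, sq.mean(axis=0))
            areas.append(clip.area_inside)
        assert sum(areas) == pytest.approx(2 * 0.36, rel=0.005)

    def test_surface_area_dispatch(self, grid2mm, null_case):
        assert scar.surface_area(grid2mm) == pytest.approx(4.0)
        assert scar.surface_area(null_case.region) == pytest.approx(
            null_case.region.area())
        with pytest.raises(TypeError):
            scar.surface_area(42)
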