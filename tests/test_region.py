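import numpy as np
import pytest

from nasolab import region as reg
from nasolab.geometry import shortest_vertex_path
from nasolab.mesh_io import LandmarkSet

from .conftest import make_plane_grid


def grid_landmarks(size=10.0):
    """A lip-like landmark layout on a flat grid of the given size."""
    return LandmarkSet(
        right_cheilion=[0.15 * size, 0.2 * size, 0.0],
        left_cheilion=[0.85 * size, 0.2 * size, 0.0],
        right_alare=[0.35 * size, 0.8 * size, 0.0],
        left_alare=[0.65 * size, 0.8 * size, 0.0],
        subnasale=[0.5 * size, 0.8 * size, 0.0],
        vermilion_border=[[0.35 * size, 0.2 * size, 0.0],
                          [0.5 * size, 0.2 * size, 0.0],
                          [0.65 * size, 0.2 * size, 0.0]],
    )


class TestSnapLandmarks:
    def test_on_surface_point_unchanged(self):
        mesh = make_plane_grid(10, 10.0)
        lm = grid_landmarks()
        snapped = reg.snap_landmarks(mesh, lm, tolerance=1.0)
        np.testing.assert_allclose(snapped.subnasale, lm.subnasale, atol=1e-12)

    def test_point_above_plane_projects_orthogonally(self):
        mesh = make_plane_grid(10, 10.0)
        lm = grid_landmarks()
        lm.subnasale = lm.subnasale + np.array([0.0, 0.0, 0.5])
        snapped = reg.snap_landmarks(mesh, lm, tolerance=1.0)
        np.testing.assert_allclose(snapped.subnasale,
                                   [5.0, 8.0, 0.0], atol=1e-12)

    def test_far_point_names_the_landmark(self):
        mesh = make_plane_grid(10, 10.0)
        lm = grid_landmarks()
        lm.subnasale = lm.subnasale + np.array([0.0, 0.0, 5.0])
        with pytest.raises(ValueError, match="subnasale"):
            reg.snap_landmarks(mesh, lm, tolerance=1.0)

    def test_snapping_is_idempotent(self):
        mesh = make_plane_grid(10, 10.0, jitter=0.1, seed=4)
        lm = grid_landmarks()
        for name in ("subnasale", "right_cheilion"):
            setattr(lm, name, getattr(lm, name) + np.array([0.0, 0.0, 0.3]))
        s1 = reg.snap_landmarks(mesh, lm, tolerance=1.0)
        s2 = reg.snap_landmarks(mesh, s1, tolerance=1.0)
        for name in ("subnasale", "right_cheilion", "left_alare"):
            np.testing.assert_allclose(getattr(s1, name), getattr(s2, name),
                                       atol=1e-9)


class TestBoundary:
    def test_two_anchor_path_close_to_straight_line(self):
        """On a grid, an edge path between two points exceeds the straight
        distance by at most the grid-metric bound (~8%)."""
        mesh = make_plane_grid(30, 10.0)
        a, b = 5, mesh.n_vertices - 7
        path, length = shortest_vertex_path(mesh.vertices, mesh.faces, a, b)
        straight = np.linalg.norm(mesh.vertices[a] - mesh.vertices[b])
        assert straight <= length <= 1.08 * straight

    def test_closed_boundary_length_near_polygon_perimeter(self):
        mesh = make_plane_grid(40, 10.0)
        lm = reg.snap_landmarks(mesh, grid_landmarks(), 1.0)
        boundary = reg.boundary_from_landmarks(mesh, lm)
        assert boundary.closed
        # perimeter of the anchor polygon (straight segments)
        anchors = boundary.anchors
        perim = np.linalg.norm(
            np.diff(np.vstack([anchors, anchors[:1]]), axis=0), axis=1).sum()
        # octile grid-metric overhead peaks at ~8.3% (22.5 deg segments)
        assert perim <= boundary.length() <= 1.085 * perim

    def test_coincident_anchors_rejected(self):
        mesh = make_plane_grid(20, 10.0)
        lm = grid_landmarks()
        lm.right_alare = lm.subnasale.copy()
        lm.left_alare = np.array([6.5, 8.0, 0.0])
        with pytest.raises(ValueError, match="coincide|same mesh vertex"):
            reg.boundary_from_landmarks(mesh, lm)


class TestExtractRegion:
    def test_square_region_area_within_two_percent(self):
        """A square boundary on a fine planar grid encloses (near) the
        square's area; the centroid rule's discretisation error is small."""
        mesh = make_plane_grid(100, 10.0)
        lm = LandmarkSet(
            right_cheilion=[2.13, 2.07, 0.0],
            left_cheilion=[7.87, 2.07, 0.0],
            right_alare=[2.13, 7.81, 0.0],
            left_alare=[7.87, 7.81, 0.0],
            subnasale=[5.0, 7.81, 0.0],
            vermilion_border=[[3.0, 2.07, 0.0], [5.0, 2.07, 0.0],
                              [7.0, 2.07, 0.0]],
        )
        lm = reg.snap_landmarks(mesh, lm, 1.0)
        boundary = reg.boundary_from_landmarks(mesh, lm)
        region = reg.extract_region(mesh, boundary)
        expected = (7.87 - 2.13) * (7.81 - 2.07)
        assert region.area() == pytest.approx(expected, rel=0.02)
        assert region.area() <= region.parent_area

    def test_region_plus_complement_covers_parent(self, delta1_case):
        region = delta1_case.region
        refined = delta1_case.boundary.refined
        assert region.area() < refined.area()
        # complement area (everything not reached) closes the budget
        from nasolab.geometry import face_areas

        total = face_areas(refined.vertices, refined.faces).sum()
        assert region.area() < total

    def test_seed_outside_returns_complement_with_warning(self, null_case):
        mesh = null_case.mesh
        boundary = null_case.boundary
        # a point clearly outside the lip region (lateral border)
        outside = mesh.vertices[np.argmax(mesh.vertices[:, 0])]
        with pytest.warns(UserWarning, match="larger side|outside"):
            comp = reg.extract_region(mesh, boundary, seed_hint=outside)
        inside = null_case.region
        refined_total = null_case.boundary.refined.area()
        assert comp.area() + inside.area() == pytest.approx(
            refined_total, rel=1e-6)

    def test_region_is_edge_connected(self, delta1_case):
        import networkx as nx

        sub = delta1_case.region.mesh
        g = nx.Graph()
        g.add_nodes_from(range(sub.n_faces))
        from collections import defaultdict

        edge_faces = defaultdict(list)
        for fi, (a, b, c) in enumerate(sub.faces):
            for e in ((a, b), (b, c), (c, a)):
                edge_faces[tuple(sorted((int(e[0]), int(e[1]))))].append(fi)
        for faces in edge_faces.values():
            for x, y in zip(faces, faces[1:]):
                g.add_edge(x, y)
        assert nx.number_connected_components(g) == 1
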