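"""Low-level triangle-mesh geometry shared across the pipeline.

Everything here operates on plain ``(vertices, faces)`` arrays so it can be
used both on full scans and on extracted sub-regions without carrying any
domain semantics.  Coordinates are millimetres throughout.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra
from scipy.spatial import cKDTree


def weld_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than ``tol`` by snapping to a regular grid.

    Grid-rounding (rather than pairwise distance clustering) makes the
    operation idempotent: welding a welded mesh changes nothing.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    if len(vertices) == 0:
        return vertices.reshape(0, 3), faces.reshape(0, 3)
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    # preserve first-occurrence ordering so welding is stable
    order = np.argsort(first, kind="stable")
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    new_vertices = vertices[first[order]]
    new_faces = rank[inverse][faces] if len(faces) else faces
    if len(new_faces):
        keep = (
            (new_faces[:, 0] != new_faces[:, 1])
            & (new_faces[:, 1] != new_faces[:, 2])
            & (new_faces[:, 0] != new_faces[:, 2])
        )
        new_faces = new_faces[keep]
    return new_vertices, new_faces


def face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=np.int64)
    if len(f) == 0:
        return np.zeros(0)
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def face_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=np.int64)
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    norm = np.linalg.norm(cross, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return cross / norm


def closest_point_on_triangles(
    points: np.ndarray, tri: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact closest point on each triangle for each point (paired).

    ``points``: (n, 3); ``tri``: (n, 3, 3).  Returns (closest (n,3),
    squared distance (n,)).  Standard region-based algorithm (Ericson),
    vectorised over the pairs.
    """
    p = np.asarray(points, dtype=float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex A
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    # vertex B
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    # vertex C
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m
    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1 - d3
    t = np.where(denom != 0, d1 / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = a[m] + t[m, None] * ab[m]
    done |= m
    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2 - d6
    t = np.where(denom != 0, d2 / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = a[m] + t[m, None] * ac[m]
    done |= m
    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    denom = (d4 - d3) + (d5 - d6)
    t = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m
    # interior
    m = ~done
    denom = va + vb + vc
    denom_safe = np.where(denom == 0, 1.0, denom)
    v = vb / denom_safe
    w = vc / denom_safe
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]

    d2_ = np.einsum("ij,ij->i", p - out, p - out)
    return out, d2_


class SurfaceLocator:
    """Nearest-point-on-surface queries against a fixed triangle mesh.

    Candidate faces come from a KD-tree over vertices (faces incident to the
    k nearest vertices) plus a KD-tree over face centroids; exact
    point-to-triangle distances decide among candidates.  For well-shaped
    scan meshes this is exact in practice and avoids per-query rebuild costs.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        if len(self.faces) == 0:
            raise ValueError("cannot locate points on an empty mesh")
        self._vtree = cKDTree(self.vertices)
        self._centroids = self.vertices[self.faces].mean(axis=1)
        self._ctree = cKDTree(self._centroids)
        nv = len(self.vertices)
        # vertex -> incident faces (CSR-style)
        counts = np.zeros(nv, dtype=np.int64)
        np.add.at(counts, self.faces.ravel(), 1)
        self._voffsets = np.concatenate([[0], np.cumsum(counts)])
        order = np.argsort(self.faces.ravel(), kind="stable")
        self._vfaces = np.repeat(np.arange(len(self.faces)), 3)[order]

    def _incident(self, vids: np.ndarray) -> np.ndarray:
        parts = [
            self._vfaces[self._voffsets[v] : self._voffsets[v + 1]] for v in vids
        ]
        return np.unique(np.concatenate(parts)) if parts else np.zeros(0, np.int64)

    def query_fast(
        self, points: np.ndarray, k_faces: int = 16
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised nearest-point query considering the ``k_faces`` faces
        with nearest centroids per point.  Exact for well-shaped meshes when
        the true nearest face is among those candidates (feature scales
        larger than a few face diameters); use :meth:`query` for the fully
        exact per-point search."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        kf = min(k_faces, len(self.faces))
        _, fidx = self._ctree.query(pts, k=kf)
        fidx = fidx.reshape(len(pts), kf)
        tri = self.vertices[self.faces[fidx.ravel()]]
        rep = np.repeat(pts, kf, axis=0)
        cp, d2 = closest_point_on_triangles(rep, tri)
        d2 = d2.reshape(len(pts), kf)
        j = np.argmin(d2, axis=1)
        rows = np.arange(len(pts))
        closest = cp.reshape(len(pts), kf, 3)[rows, j]
        dist = np.sqrt(d2[rows, j])
        return closest, dist, fidx[rows, j]

    def query(
        self, points: np.ndarray, k_vertices: int = 6, k_faces: int = 10
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (closest points, distances, face indices) for ``points``."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        kv = min(k_vertices, len(self.vertices))
        kf = min(k_faces, len(self.faces))
        _, vidx = self._vtree.query(pts, k=kv)
        _, fidx = self._ctree.query(pts, k=kf)
        vidx = np.atleast_2d(vidx)
        fidx = np.atleast_2d(fidx)
        closest = np.empty_like(pts)
        dist = np.empty(len(pts))
        face_of = np.empty(len(pts), dtype=np.int64)
        for i, p in enumerate(pts):
            cand = np.unique(np.concatenate([self._incident(vidx[i]), fidx[i]]))
            tri = self.vertices[self.faces[cand]]
            cp, d2 = closest_point_on_triangles(
                np.broadcast_to(p, (len(cand), 3)), tri
            )
            j = int(np.argmin(d2))
            closest[i] = cp[j]
            dist[i] = np.sqrt(d2[j])
            face_of[i] = cand[j]
        return closest, dist, face_of


def edge_array(faces: np.ndarray) -> np.ndarray:
    """Unique undirected edges (sorted pairs) of a face array."""
    f = np.asarray(faces, dtype=np.int64)
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def edge_graph(vertices: np.ndarray, faces: np.ndarray):
    """Sparse symmetric matrix of edge lengths for shortest-path queries."""
    e = edge_array(faces)
    w = np.linalg.norm(vertices[e[:, 0]] - vertices[e[:, 1]], axis=1)
    n = len(vertices)
    m = coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]),
                                  np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(n, n),
    )
    return m.tocsr()


def shortest_vertex_path(
    vertices: np.ndarray, faces: np.ndarray, start: int, goal: int,
    graph=None, tie_tol: float = 1e-9,
) -> tuple[list[int], float]:
    """Dijkstra shortest path along mesh edges between two vertex indices.

    Regular scan meshes have many equal-length edge paths; ties are broken
    deterministically by choosing, among the true shortest paths (the
    shortest-path DAG, slack ``tie_tol`` mm per edge), the one hugging the
    straight start-goal chord most closely.  This keeps the selected
    boundary geometry reproducible and mirror-consistent on symmetric
    meshes while its length remains exactly the Dijkstra optimum.
    """
    vertices = np.asarray(vertices, dtype=float)
    g = edge_graph(vertices, faces) if graph is None else graph
    ds = _csgraph_dijkstra(g, directed=False, indices=start)
    if not np.isfinite(ds[goal]):
        raise ValueError(f"vertices {start} and {goal} are not connected")
    dt = _csgraph_dijkstra(g, directed=False, indices=goal)
    total = float(ds[goal])

    e = edge_array(faces)
    w = np.linalg.norm(vertices[e[:, 0]] - vertices[e[:, 1]], axis=1)
    # chord distance of edge midpoints (secondary weight)
    a = vertices[start]
    chord = vertices[goal] - a
    cn = np.linalg.norm(chord)
    u = chord / cn if cn > 0 else np.zeros(3)
    mid = 0.5 * (vertices[e[:, 0]] + vertices[e[:, 1]]) - a
    off = mid - (mid @ u)[:, None] * u
    pen = np.linalg.norm(off, axis=1) * w

    # directed edges of the shortest-path DAG
    srcs, dsts, pens = [], [], []
    for (i, j), wk, pk in zip(e, w, pen):
        if ds[i] + wk + dt[j] <= total + tie_tol:
            srcs.append(i); dsts.append(j); pens.append(pk)
        if ds[j] + wk + dt[i] <= total + tie_tol:
            srcs.append(j); dsts.append(i); pens.append(pk)
    srcs = np.asarray(srcs); dsts = np.asarray(dsts); pens = np.asarray(pens)
    # DP over nodes in order of increasing distance from start (DAG order)
    nodes = np.unique(np.concatenate([srcs, dsts, [start, goal]]))
    best = {int(n): np.inf for n in nodes}
    pred = {int(n): -1 for n in nodes}
    best[start] = 0.0
    order = np.argsort(ds[srcs], kind="stable")
    for k in order:
        i, j, pk = int(srcs[k]), int(dsts[k]), float(pens[k])
        if best[i] + pk < best[j] - 1e-15:
            best[j] = best[i] + pk
            pred[j] = i
    path = [goal]
    while path[-1] != start:
        p = pred[path[-1]]
        if p < 0:
            raise RuntimeError("tie-broken shortest-path reconstruction failed")
        path.append(p)
    path.reverse()
    length = float(
        np.linalg.norm(np.diff(vertices[path], axis=0), axis=1).sum()
    )
    return path, length


class RefinedMesh:
    """A working copy of a mesh into which exact surface points can be
    inserted as vertices by splitting the containing face (or edge).

    Used to anchor landmark and trace points on the mesh so that boundaries
    can be traced as vertex paths along edges.
    """

    VERTEX_SNAP = 1e-9

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = [np.asarray(v, dtype=float) for v in np.asarray(vertices, float)]
        self.faces = [tuple(int(i) for i in f) for f in np.asarray(faces, np.int64)]
        self.n_parent_vertices = len(self.vertices)

    def _arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.array(self.vertices), np.array(self.faces, dtype=np.int64)

    def insert_point(self, point: np.ndarray, tol: float = 1e-6) -> int:
        """Insert ``point`` (must lie on the surface within ``tol``) and
        return its vertex index."""
        v, f = self._arrays()
        loc = SurfaceLocator(v, f)
        cp, dist, fid = loc.query(point)
        cp, dist, fid = cp[0], float(dist[0]), int(fid[0])
        if dist > tol:
            raise ValueError(
                f"point {np.asarray(point)} is {dist:.3g} mm off the surface"
            )
        a, b, c = self.faces[fid]
        tri = v[[a, b, c]]
        # snap to an existing corner?
        d_corner = np.linalg.norm(tri - cp, axis=1)
        j = int(np.argmin(d_corner))
        if d_corner[j] < self.VERTEX_SNAP:
            return (a, b, c)[j]
        new_idx = len(self.vertices)
        self.vertices.append(cp)
        # on an edge?
        for (i0, i1), i2 in (((a, b), c), ((b, c), a), ((c, a), b)):
            p0, p1 = v[i0], v[i1]
            seg = p1 - p0
            L2 = seg @ seg
            t = np.clip((cp - p0) @ seg / L2, 0.0, 1.0)
            if np.linalg.norm(p0 + t * seg - cp) < self.VERTEX_SNAP:
                self._split_edge(i0, i1, new_idx)
                return new_idx
        # interior: split into three
        self.faces[fid] = (a, b, new_idx)
        self.faces.append((b, c, new_idx))
        self.faces.append((c, a, new_idx))
        return new_idx

    def _split_edge(self, i0: int, i1: int, new_idx: int) -> None:
        key = {i0, i1}
        for fi, (a, b, c) in enumerate(list(self.faces)):
            for (e0, e1), opp in (((a, b), c), ((b, c), a), ((c, a), b)):
                if {e0, e1} == key:
                    self.faces[fi] = (e0, new_idx, opp)
                    self.faces.append((new_idx, e1, opp))
                    break

    def shortest_path(self, start: int, goal: int) -> list[int]:
        v, f = self._arrays()
        path, _ = shortest_vertex_path(v, f, start, goal)
        return path
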