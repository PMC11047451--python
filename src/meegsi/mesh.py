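"""Triangular surface meshes and the geometry kernels built on them.

Head and source surfaces are closed, outward-oriented triangular meshes with
vertices in SI meters (right-handed RAS frame).  This module provides the
first- and second-order surface metrics (vertex normals, mean curvature), mesh
decimation, geodesic distances, the low-to-high resolution interpolant used to
carry source estimates between mesh resolutions, graph Laplacians for spatial
smoothness priors, point-to-surface distances, and the local outward warp used
by the lead-field correction loop.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra


class MeshValidationError(ValueError):
    """Raised when a mesh violates a structural invariant."""


@dataclass
class TriMesh:
    """A triangular surface mesh.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates in meters.
    triangles : (T, 3) int array
        Vertex indices of each triangle, counter-clockwise when viewed from
        outside for outward-oriented surfaces.
    """

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be a (V, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshValidationError("triangles must be a (T, 3) array")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshValidationError("vertices contain non-finite values")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            bad = int(self.triangles.max())
            raise MeshValidationError(
                f"triangle references vertex {bad} but mesh has "
                f"{len(self.vertices)} vertices"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.triangles.copy())

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a (E, 2) sorted-index array."""
        e = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        cr = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two triangles."""
        e = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def validate_closed(self) -> None:
        if not self.is_closed():
            raise MeshValidationError("mesh is not a closed 2-manifold")
        if np.any(self.triangle_areas() <= 0.0):
            raise MeshValidationError("mesh contains a zero-area triangle")


@dataclass
class SurfaceMetrics:
    """First- and second-order surface metrics per vertex."""

    normals: np.ndarray  # (V, 3) unit outward normals
    mean_curvature: np.ndarray  # (V,) signed mean curvature, 1/m


@dataclass
class InterpolantOperator:
    """Row-stochastic sparse operator carrying fields from a low- to a
    high-resolution mesh of the same surface."""

    weights: sp.csr_matrix  # (N_high, N_low), rows sum to 1
    source_id: str = "low"
    target_id: str = "high"

    def apply(self, values: np.ndarray) -> np.ndarray:
        return self.weights @ values


@dataclass
class GraphLaplacian:
    """Combinatorial graph Laplacian L = D - A, optionally deformed to
    L + eps*I so that it is full rank while converging uniformly to L as
    eps -> 0."""

    matrix: sp.csr_matrix
    deformation: float = 0.0


def vertex_normals(mesh: TriMesh) -> np.ndarray:
    """Area-weighted unit vertex normals.

    Raises on isolated vertices (no incident triangle), for which a normal is
    undefined.
    """
    v, t = mesh.vertices, mesh.triangles
    face_n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])  # 2*area*n
    acc = np.zeros_like(v)
    for k in range(3):
        np.add.at(acc, t[:, k], face_n)
    norms = np.linalg.norm(acc, axis=1)
    incident = np.zeros(len(v), dtype=bool)
    incident[t.ravel()] = True
    if not incident.all():
        idx = int(np.flatnonzero(~incident)[0])
        raise MeshValidationError(f"vertex {idx} has no incident triangle")
    if np.any(norms == 0):
        raise MeshValidationError("degenerate normal (zero accumulated area)")
    return acc / norms[:, None]


def _cotangent_weights(mesh: TriMesh) -> sp.csr_matrix:
    """Symmetric cotangent weight matrix W with W_ij = cot(a) + cot(b)."""
    v, t = mesh.vertices, mesh.triangles
    rows, cols, vals = [], [], []
    for k in range(3):
        i = t[:, k]
        j = t[:, (k + 1) % 3]
        o = t[:, (k + 2) % 3]
        a = v[i] - v[o]
        b = v[j] - v[o]
        cross = np.linalg.norm(np.cross(a, b), axis=1)
        cross = np.maximum(cross, 1e-300)
        cot = np.einsum("ij,ij->i", a, b) / cross
        rows.append(i)
        cols.append(j)
        vals.append(cot)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    W = sp.coo_matrix((vals, (rows, cols)), shape=(len(v), len(v)))
    W = W + W.T
    return W.tocsr()


def mean_curvature(mesh: TriMesh) -> np.ndarray:
    """Signed mean curvature per vertex (1/m), cotangent Laplace-Beltrami.

    Sign convention: positive on convex regions (gyral-crown-like) when the
    mesh is outward oriented, so a sphere of radius R has H ~ +1/R.
    """
    v = mesh.vertices
    W = _cotangent_weights(mesh)
    areas = mesh.triangle_areas()
    if np.any(areas <= 0):
        raise MeshValidationError("degenerate (zero-area) triangle")
    # Voronoi vertex area A_i = (1/8) sum_j w_ij |x_i - x_j|^2, falling back to
    # barycentric thirds wherever the Voronoi cell degenerates (obtuse fans)
    Wc = W.tocoo()
    d2 = np.sum((v[Wc.row] - v[Wc.col]) ** 2, axis=1)
    vert_area = np.zeros(len(v))
    np.add.at(vert_area, Wc.row, 0.125 * Wc.data * d2)
    bary = np.zeros(len(v))
    for k in range(3):
        np.add.at(bary, mesh.triangles[:, k], areas / 3.0)
    bad = vert_area <= 0.1 * bary
    vert_area[bad] = bary[bad]
    deg = np.asarray(W.sum(axis=1)).ravel()
    # mean-curvature normal K_i = (1/(2A_i)) * sum_j w_ij (x_i - x_j)
    K = (deg[:, None] * v - W @ v) / (2.0 * vert_area[:, None])
    n = vertex_normals(mesh)
    return 0.5 * np.einsum("ij,ij->i", K, n)


def surface_metrics(mesh: TriMesh) -> SurfaceMetrics:
    return SurfaceMetrics(normals=vertex_normals(mesh), mean_curvature=mean_curvature(mesh))


# ---------------------------------------------------------------------------
# decimation


def _vertex_quadrics(mesh: TriMesh) -> np.ndarray:
    """Per-vertex 4x4 quadric error matrices (sum of incident plane quadrics,
    area weighted)."""
    v, t = mesh.vertices, mesh.triangles
    n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    area2 = np.linalg.norm(n, axis=1)
    area2 = np.maximum(area2, 1e-300)
    nu = n / area2[:, None]
    d = -np.einsum("ij,ij->i", nu, v[t[:, 0]])
    p = np.hstack([nu, d[:, None]])  # (T, 4)
    Kf = np.einsum("ti,tj->tij", p, p) * (0.5 * area2)[:, None, None]
    Q = np.zeros((len(v), 4, 4))
    for k in range(3):
        np.add.at(Q, t[:, k], Kf)
    return Q


def _collapse_cost(Q: np.ndarray, pa: np.ndarray, pb: np.ndarray):
    """Optimal collapse position and cost for combined quadric Q."""
    A = Q[:3, :3]
    b = -Q[:3, 3]
    try:
        x = np.linalg.solve(A + 1e-12 * np.trace(A) * np.eye(3), b)
    except np.linalg.LinAlgError:
        x = 0.5 * (pa + pb)
    # guard against ill-conditioned solves flinging the vertex away
    if np.linalg.norm(x - 0.5 * (pa + pb)) > 2.0 * np.linalg.norm(pa - pb) + 1e-12:
        x = 0.5 * (pa + pb)
    h = np.append(x, 1.0)
    return x, float(h @ Q @ h)


def resample_mesh(mesh: TriMesh, target_vertices: int) -> TriMesh:
    """Decimate a mesh to approximately ``target_vertices`` vertices.

    Iterative edge collapse driven by quadric error, with a link-condition
    guard so closed manifolds stay closed.  The identity is returned when the
    target equals the current vertex count.
    """
    V = mesh.n_vertices
    if target_vertices > V:
        raise ValueError(f"target {target_vertices} exceeds vertex count {V}")
    if target_vertices < 12:
        raise ValueError("target must be at least 12 vertices")
    if target_vertices == V:
        return mesh.copy()

    verts = mesh.vertices.copy()
    Q = _vertex_quadrics(mesh)
    neighbors: list[set] = [set() for _ in range(V)]
    for a, b in mesh.edges():
        neighbors[a].add(int(b))
        neighbors[b].add(int(a))
    alive = np.ones(V, dtype=bool)
    version = np.zeros(V, dtype=np.int64)

    heap: list = []

    def push(a: int, b: int) -> None:
        a, b = (a, b) if a < b else (b, a)
        _, cost = _collapse_cost(Q[a] + Q[b], verts[a], verts[b])
        heapq.heappush(heap, (cost, a, b, int(version[a]), int(version[b])))

    for a, b in mesh.edges():
        push(int(a), int(b))

    merged_into = np.arange(V)  # union-find parent: dead vertex -> absorber

    def find(i: int) -> int:
        while merged_into[i] != i:
            merged_into[i] = merged_into[merged_into[i]]
            i = merged_into[i]
        return i

    n_alive = V
    while n_alive > target_vertices and heap:
        cost, a, b, va, vb = heapq.heappop(heap)
        if not (alive[a] and alive[b]) or version[a] != va or version[b] != vb:
            continue
        if b not in neighbors[a]:
            continue
        # link condition: common neighbors of a and b must be exactly the two
        # triangle apexes, otherwise the collapse pinches the surface
        common = neighbors[a] & neighbors[b]
        if len(common) != 2:
            continue
        pos, _ = _collapse_cost(Q[a] + Q[b], verts[a], verts[b])
        # collapse b into a
        verts[a] = pos
        Q[a] = Q[a] + Q[b]
        alive[b] = False
        merged_into[b] = a
        neighbors[a].discard(b)
        for nb in list(neighbors[b]):
            if nb == a:
                continue
            neighbors[nb].discard(b)
            neighbors[nb].add(a)
            neighbors[a].add(nb)
        neighbors[b].clear()
        version[a] += 1
        n_alive -= 1
        for nb in neighbors[a]:
            push(a, nb)

    # rebuild: remap every original triangle through the collapse chains and
    # drop faces that became degenerate or duplicated
    remap = np.full(V, -1, dtype=np.int64)
    remap[alive] = np.arange(int(alive.sum()))
    tri = mesh.triangles.copy()
    for k in range(3):
        tri[:, k] = [remap[find(int(i))] for i in tri[:, k]]
    keep = (tri[:, 0] != tri[:, 1]) & (tri[:, 1] != tri[:, 2]) & (tri[:, 0] != tri[:, 2])
    tri = tri[keep]
    # remove duplicate faces irrespective of rotation (should not occur under
    # the link condition, but keep the rebuild defensive)
    key = np.sort(tri, axis=1)
    _, uniq = np.unique(key, axis=0, return_index=True)
    tri = tri[np.sort(uniq)]
    return TriMesh(verts[alive], tri)


def geodesic_distances(mesh: TriMesh, seeds) -> np.ndarray:
    """Graph geodesic distances (Dijkstra on the edge graph) from a seed set.

    Upper-bounds the true polyhedral geodesic; unreachable vertices get +inf
    with a warning.
    """
    seeds = np.atleast_1d(np.asarray(seeds, dtype=np.int64))
    if seeds.size == 0:
        raise ValueError("at least one seed vertex required")
    if seeds.min() < 0 or seeds.max() >= mesh.n_vertices:
        raise ValueError("seed index out of range")
    g = _edge_graph(mesh)
    d = dijkstra(g, directed=False, indices=seeds, min_only=True)
    if np.any(np.isinf(d)):
        warnings.warn("mesh has unreachable components; distances set to +inf")
    return d


def _edge_graph(mesh: TriMesh) -> sp.csr_matrix:
    """Chord-length graph over the 1- and 2-ring neighborhoods.

    Second-ring chords cut the metrication bias of pure edge-graph Dijkstra
    from a few percent to well under 1% on icosphere fixtures while keeping
    path lengths >= straight-line distance (triangle inequality).
    """
    V = mesh.n_vertices
    e = mesh.edges()
    nbr: list[set] = [set() for _ in range(V)]
    for a, b in e:
        nbr[a].add(int(b))
        nbr[b].add(int(a))
    rows, cols = [], []
    for i in range(V):
        two = set()
        for j in nbr[i]:
            two |= nbr[j]
        two.discard(i)
        rows += [i] * len(two)
        cols += list(two)
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    w = np.linalg.norm(mesh.vertices[rows] - mesh.vertices[cols], axis=1)
    return sp.coo_matrix((w, (rows, cols)), shape=(V, V)).tocsr()


def build_interpolant(low: TriMesh, high: TriMesh, k: int = 3) -> InterpolantOperator:
    """Weighted-average interpolant from a low- to a high-resolution mesh.

    Weights are proportional to inverse surface geodesic distance to the k
    nearest low-mesh vertices, normalized per row; a high vertex coincident
    with a low vertex takes that vertex's value exactly.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > low.n_vertices:
        raise ValueError("k exceeds number of low-mesh vertices")
    from scipy.spatial import cKDTree

    # embed the low vertices into the high mesh graph via nearest high vertex
    tree = cKDTree(high.vertices)
    snap_d, snap_i = tree.query(low.vertices)
    g = _edge_graph(high)
    D = dijkstra(g, directed=False, indices=snap_i)  # (N_low, N_high)
    D = D + snap_d[:, None]  # account for the off-surface snap gap
    # coincident low/high vertices: exact zero
    D[np.arange(low.n_vertices), snap_i] = snap_d

    N_high = high.n_vertices
    rows = np.repeat(np.arange(N_high), k)
    order = np.argsort(D, axis=0)[:k, :]  # (k, N_high) low indices
    cols = order.T.ravel()
    dk = D[order, np.arange(N_high)[None, :]].T  # (N_high, k)
    w = np.empty_like(dk)
    coincident = dk[:, 0] < 1e-12
    with np.errstate(divide="ignore"):
        w = 1.0 / np.maximum(dk, 1e-300)
    w[coincident, :] = 0.0
    w[coincident, 0] = 1.0
    w /= w.sum(axis=1, keepdims=True)
    W = sp.csr_matrix((w.ravel(), (rows, cols)), shape=(N_high, low.n_vertices))
    return InterpolantOperator(weights=W)


def graph_laplacian(mesh: TriMesh, deformation: float = 0.0) -> GraphLaplacian:
    """Combinatorial graph Laplacian L = D - A, deformed to L + eps*I.

    The deformed operator is full rank for eps > 0 and converges uniformly to
    L as eps -> 0.
    """
    if deformation < 0:
        raise ValueError("deformation must be >= 0")
    e = mesh.edges()
    V = mesh.n_vertices
    A = sp.coo_matrix(
        (np.ones(2 * len(e)), (np.concatenate([e[:, 0], e[:, 1]]), np.concatenate([e[:, 1], e[:, 0]]))),
        shape=(V, V),
    ).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    L = sp.diags(deg) - A
    if deformation > 0:
        L = L + deformation * sp.eye(V)
    return GraphLaplacian(matrix=L.tocsr(), deformation=float(deformation))


def laplacian_pseudoinverse_factor(lap: GraphLaplacian) -> np.ndarray:
    """Standardization factor M: exact inverse of L + eps*I for eps > 0,
    Moore-Penrose pseudoinverse of the singular combinatorial Laplacian at
    eps = 0."""
    L = lap.matrix.toarray()
    if lap.deformation > 0:
        return np.linalg.inv(L)
    warnings.warn("deformation 0: using Moore-Penrose pseudoinverse of the Laplacian")
    return np.linalg.pinv(L, hermitian=True)


def _closest_on_triangles(p: np.ndarray, a, b, c) -> np.ndarray:
    """Closest point to ``p`` on each triangle (a, b, c); vectorized over
    triangles (standard barycentric region classification)."""
    ab = b - a
    ac = c - a
    ap = p[None, :] - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p[None, :] - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p[None, :] - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex a
    out[m] = a[m]
    done |= m
    m = ~done & (d3 >= 0) & (d4 <= d3)  # vertex b
    out[m] = b[m]
    done |= m
    m = ~done & (d6 >= 0) & (d5 <= d6)  # vertex c
    out[m] = c[m]
    done |= m
    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d1 / (d1 - d3)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m
    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    with np.errstate(invalid="ignore", divide="ignore"):
        w = d2 / (d2 - d6)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m
    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m
    m = ~done  # interior
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = vb / denom
        w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def closest_point_on_surface(points: np.ndarray, mesh: TriMesh):
    """Nearest point on the surface for each query point.

    Returns ``(closest_points, distances)``; exact point-to-triangle
    distances over all triangles.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if mesh.n_triangles == 0:
        raise MeshValidationError("mesh has no triangles")
    a = mesh.vertices[mesh.triangles[:, 0]]
    b = mesh.vertices[mesh.triangles[:, 1]]
    c = mesh.vertices[mesh.triangles[:, 2]]
    closest = np.empty_like(points)
    dists = np.empty(len(points))
    for i, p in enumerate(points):
        cand = _closest_on_triangles(p, a, b, c)
        d2 = np.einsum("ij,ij->i", cand - p[None, :], cand - p[None, :])
        k = int(np.argmin(d2))
        closest[i] = cand[k]
        dists[i] = np.sqrt(d2[k])
    return closest, dists


def surface_surface_distances(points, outer: TriMesh, min_distance_m: float | None = None):
    """Unsigned nearest point-to-triangle distances from points (or an inner
    mesh's vertices) to a surface, with optional below-threshold flags."""
    if isinstance(points, TriMesh):
        points = points.vertices
    _, dist = closest_point_on_surface(points, outer)
    if min_distance_m is None:
        return dist
    return dist, dist < min_distance_m


def warp_surface_outward(
    inner_skull: TriMesh,
    offending_points: np.ndarray,
    min_distance_m: float,
    smoothing_radius_m: float,
    outer_limit: TriMesh | None = None,
    max_passes: int = 10,
):
    """Push the inner-skull mesh locally outward until every offending point
    sits at least ``min_distance_m`` from the surface.

    Vertices farther than ``smoothing_radius_m`` (graph geodesic) from the
    region facing an offending point are left untouched; displacement is
    tapered smoothly to zero at the radius.  If an ``outer_limit`` shell is
    supplied and the warp would pierce it, the correction stops short and the
    second return value is False (incorrigible).

    Returns ``(warped_mesh, corrigible)``.  Idempotent: a satisfied input is
    returned unchanged.
    """
    pts = np.atleast_2d(np.asarray(offending_points, dtype=np.float64))
    mesh = inner_skull.copy()
    if pts.size == 0:
        return mesh, True
    corrigible = True
    for _ in range(max_passes):
        dist = surface_surface_distances(pts, mesh)
        need = dist < min_distance_m - 1e-12
        if not np.any(need):
            break
        normals = vertex_normals(mesh)
        disp = np.zeros(mesh.n_vertices)
        from scipy.spatial import cKDTree

        tree = cKDTree(mesh.vertices)
        for p, d in zip(pts[need], dist[need]):
            idx = tree.query_ball_point(p, smoothing_radius_m)
            if not idx:
                idx = [int(tree.query(p)[1])]
            idx = np.asarray(idx)
            r = np.linalg.norm(mesh.vertices[idx] - p, axis=1)
            taper = 0.5 * (1.0 + np.cos(np.pi * np.minimum(r / smoothing_radius_m, 1.0)))
            # overshoot to 110% of the minimum distance so the corrected
            # points clear the strict below-threshold flag with margin
            amount = max(1.1 * min_distance_m - d, 0.0) * taper
            disp[idx] = np.maximum(disp[idx], amount)
        new_vertices = mesh.vertices + disp[:, None] * normals
        if outer_limit is not None:
            # do not cross the outer shell: cap displacement at 90% of the
            # available gap to the outer surface
            gap = surface_surface_distances(mesh.vertices, outer_limit)
            over = disp > 0.9 * gap
            if np.any(over):
                disp = np.minimum(disp, 0.9 * gap)
                new_vertices = mesh.vertices + disp[:, None] * normals
                corrigible = False
        mesh = TriMesh(new_vertices, mesh.triangles)
        if not corrigible:
            break
    else:
        dist = surface_surface_distances(pts, mesh)
        if np.any(dist < min_distance_m - 1e-12):
            corrigible = False
    final = surface_surface_distances(pts, mesh)
    if np.any(final < min_distance_m - 1e-12):
        corrigible = False
    return mesh, corrigible
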