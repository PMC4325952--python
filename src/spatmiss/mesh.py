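"""Triangulation of the study region and the sparse-precision (GMRF)
representation of the Matérn field.

A λ=1 Matérn Gaussian field in the plane is, to good approximation, the
solution of the SPDE (κ² − Δ)(τ u) = white noise.  Discretising with
piecewise-linear finite elements on a triangulation with V vertices turns the
field into a Gaussian Markov random field with the sparse precision matrix

    Q(κ, τ) = (τ²/2) · (κ⁴ C + 2 κ² G + G C⁻¹ G),

where C is the (lumped, diagonal) mass matrix and G the stiffness matrix.
The τ²/2 multiplier makes the implied marginal variance match the analytic
parametrisation σ² = 1/(2π κ² τ²) used throughout this package.  Field values
at arbitrary observation locations are obtained with the barycentric
projector A (one row per location, at most three nonzero weights).

The mesher covers the data region (an inner polygon) with triangles whose
longest edge respects a cap, surrounded by a coarser extension zone that
pushes the artificial boundary away from the data to limit edge effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from matplotlib.tri import Triangulation, TrapezoidMapTriFinder
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import MultiPoint, Point, Polygon

from .matern import MaternParams

__all__ = [
    "Mesh",
    "Projector",
    "PrecisionMatrix",
    "build_mesh",
    "grid_mesh",
    "make_projector",
    "fem_matrices",
    "assemble_precision",
    "SpdeOperator",
    "write_mesh",
    "read_mesh",
]


@dataclass
class Mesh:
    vertices: np.ndarray        # (V, 2) km
    triangles: np.ndarray       # (T, 3) vertex indices
    inner_boundary: Polygon     # data region
    outer_boundary: Polygon     # meshed extent (inner + extension)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * np.abs(_cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]))


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """z-component of the cross product of planar vectors."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


@dataclass
class Projector:
    """Sparse N×V barycentric interpolation weights."""

    weights: sp.csr_matrix

    def __matmul__(self, other):
        return self.weights @ other


@dataclass
class PrecisionMatrix:
    Q: sp.csc_matrix
    params: MaternParams


def _thin_points(points: np.ndarray, min_dist: float) -> np.ndarray:
    """Greedy first-come thinning: keep a point iff it is at least
    ``min_dist`` from every previously kept point."""
    if min_dist <= 0:
        return points
    kept: list[np.ndarray] = []
    tree = None
    pending: list[np.ndarray] = []
    # rebuild the KD-tree in chunks to keep this O(n log n)-ish
    for pt in points:
        ok = True
        if tree is not None:
            if tree.query(pt, k=1)[0] < min_dist:
                ok = False
        if ok and pending:
            d = np.linalg.norm(np.asarray(pending) - pt, axis=1)
            if d.min() < min_dist:
                ok = False
        if ok:
            pending.append(pt)
        if len(pending) >= 256:
            kept.extend(pending)
            tree = cKDTree(np.asarray(kept))
            pending = []
    kept.extend(pending)
    return np.asarray(kept)


def _grid_points(bounds, spacing: float, jitter_scale: float = 1e-6) -> np.ndarray:
    """Near-regular grid over a bounding box; a deterministic sub-micron
    jitter avoids exactly collinear quadruples that would give Delaunay
    slivers."""
    xmin, ymin, xmax, ymax = bounds
    xs = np.arange(xmin, xmax + spacing, spacing)
    ys = np.arange(ymin, ymax + spacing, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    rng = np.random.default_rng(12345)
    pts = pts + rng.uniform(-1, 1, pts.shape) * spacing * jitter_scale
    return pts


def _polygon_contains(poly: Polygon, points: np.ndarray) -> np.ndarray:
    from shapely import contains_xy

    return contains_xy(poly, points[:, 0], points[:, 1])


def build_mesh(
    locations: np.ndarray,
    max_edge_inner: float = 2.0,
    max_edge_outer: float = 50.0,
    min_vertex_dist: float = 0.75,
    extension: float | None = None,
    range_guess: float | None = None,
    inner_boundary: Polygon | None = None,
    max_vertices: int = 50_000,
) -> Mesh:
    """Triangulate the region around ``locations`` with per-zone edge caps.

    Data locations are used as seed vertices after thinning to
    ``min_vertex_dist``; filler vertices are added on a near-regular grid so
    that every triangle whose centroid lies in the data region has longest
    edge ≤ ``max_edge_inner`` (``max_edge_outer`` in the extension zone).
    The extension width defaults to max(15 km, 1.5 × ``range_guess``).
    """
    locations = np.asarray(locations, dtype=float)
    if locations.shape[0] < 3:
        raise ValueError("need at least 3 locations")
    if not (0 < max_edge_inner <= max_edge_outer):
        raise ValueError("require 0 < max_edge_inner <= max_edge_outer")
    hull = MultiPoint([tuple(p) for p in locations]).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("locations are collinear; cannot build a 2-D mesh")
    if inner_boundary is None:
        inner_boundary = hull.buffer(1.0, quad_segs=8)
    if extension is None:
        extension = max(15.0, 1.5 * (range_guess or 0.0))
    outer_boundary = inner_boundary.buffer(extension, quad_segs=8)

    seeds = _thin_points(locations, min_vertex_dist)

    # filler grids: spacing s gives Delaunay edges up to s·√2 on a square grid
    s_in = max_edge_inner / math.sqrt(2.0) * 0.97
    inner_pts = _grid_points(inner_boundary.bounds, s_in)
    inner_pts = inner_pts[_polygon_contains(inner_boundary, inner_pts)]
    if len(seeds) and len(inner_pts):
        tree = cKDTree(seeds)
        d, _ = tree.query(inner_pts, k=1)
        inner_pts = inner_pts[d >= min_vertex_dist]

    s_out = max_edge_outer / math.sqrt(2.0) * 0.97
    outer_pts = _grid_points(outer_boundary.bounds, s_out)
    keep = _polygon_contains(outer_boundary, outer_pts) & ~_polygon_contains(
        inner_boundary.buffer(0.25 * s_in), outer_pts
    )
    outer_pts = outer_pts[keep]
    ring = outer_boundary.exterior.segmentize(s_out)
    ring_pts = np.asarray(ring.coords)[:-1]

    pieces = [p for p in (seeds, inner_pts, outer_pts, ring_pts) if len(p)]
    points = np.vstack(pieces)

    inner_cap2 = max_edge_inner**2
    outer_cap2 = max_edge_outer**2
    for _ in range(30):
        if len(points) > max_vertices:
            raise RuntimeError(
                f"mesh refinement exceeded {max_vertices} vertices"
            )
        tri = Delaunay(points)
        simp = tri.simplices
        verts = tri.points
        p = verts[simp]
        centroids = p.mean(axis=1)
        in_inner = _polygon_contains(inner_boundary, centroids)
        cap2 = np.where(in_inner, inner_cap2, outer_cap2)
        e2 = np.stack(
            [
                ((p[:, 1] - p[:, 2]) ** 2).sum(1),
                ((p[:, 0] - p[:, 2]) ** 2).sum(1),
                ((p[:, 0] - p[:, 1]) ** 2).sum(1),
            ],
            axis=1,
        )
        longest = e2.max(axis=1)
        bad = longest > cap2
        if not bad.any():
            break
        # split the longest edge of each offending triangle
        which = e2[bad].argmax(axis=1)
        tb = simp[bad]
        pairs = np.stack(
            [np.delete(tb[i], which[i]) for i in range(len(tb))]
        )
        mids = verts[pairs].mean(axis=1)
        mids = np.unique(np.round(mids, 9), axis=0)
        points = np.vstack([points, mids])
    else:
        raise RuntimeError("mesh refinement did not converge")

    areas = 0.5 * np.abs(_cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]))
    good = areas > 1e-12 * max(outer_cap2, 1.0)
    return Mesh(
        vertices=verts,
        triangles=simp[good],
        inner_boundary=inner_boundary,
        outer_boundary=outer_boundary,
    )


def grid_mesh(bounds, spacing: float) -> Mesh:
    """Regular fallback mesh: square cells split into two triangles.

    Useful for tests and convergence studies where mesher-dependent vertex
    placement would add noise.
    """
    xmin, ymin, xmax, ymax = bounds
    xs = np.arange(xmin, xmax + 0.5 * spacing, spacing)
    ys = np.arange(ymin, ymax + 0.5 * spacing, spacing)
    nx, ny = len(xs), len(ys)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    vertices = np.column_stack([gx.ravel(), gy.ravel()])

    def vid(i, j):
        return i * ny + j

    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            tris.append((a, b, c))
            tris.append((a, c, d))
    poly = Polygon(
        [(xs[0], ys[0]), (xs[-1], ys[0]), (xs[-1], ys[-1]), (xs[0], ys[-1])]
    )
    return Mesh(
        vertices=vertices,
        triangles=np.asarray(tris, dtype=int),
        inner_boundary=poly,
        outer_boundary=poly,
    )


def make_projector(mesh: Mesh, locations: np.ndarray) -> Projector:
    """Barycentric interpolation weights of each location in its containing
    triangle.  A location coincident with a vertex yields a one-hot row."""
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    triang = Triangulation(
        mesh.vertices[:, 0], mesh.vertices[:, 1], mesh.triangles
    )
    finder = TrapezoidMapTriFinder(triang)
    tri_idx = finder(locations[:, 0], locations[:, 1])
    if np.any(tri_idx < 0):
        bad = int(np.nonzero(tri_idx < 0)[0][0])
        raise ValueError(
            f"location index {bad} at {tuple(locations[bad])} lies outside the mesh"
        )
    rows, cols, vals = [], [], []
    for i, (pt, t) in enumerate(zip(locations, tri_idx)):
        vidx = mesh.triangles[t]
        a, b, c = mesh.vertices[vidx]
        T = np.column_stack([b - a, c - a])
        lam12 = np.linalg.solve(T, pt - a)
        w = np.array([1.0 - lam12.sum(), lam12[0], lam12[1]])
        w = np.clip(w, 0.0, None)
        w = w / w.sum()
        for j in range(3):
            if w[j] > 1e-12:
                rows.append(i)
                cols.append(vidx[j])
                vals.append(w[j])
    A = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(locations), mesh.n_vertices)
    )
    return Projector(weights=A)


def fem_matrices(mesh: Mesh) -> tuple[sp.dia_matrix, sp.csc_matrix]:
    """Lumped mass matrix C (diagonal) and stiffness matrix G of the P1
    finite-element basis on the mesh."""
    v = mesh.vertices
    t = np.asarray(mesh.triangles, dtype=int)
    p0, p1, p2 = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    area = 0.5 * _cross2(p1 - p0, p2 - p0)
    if np.any(np.abs(area) <= 0):
        raise ValueError("degenerate triangle encountered during assembly")
    sign = np.sign(area)
    area = np.abs(area)
    # edge vectors opposite each vertex, oriented consistently
    e = np.stack([p2 - p1, p0 - p2, p1 - p0], axis=1)  # (T, 3, 2)
    e *= sign[:, None, None]

    c_diag = np.zeros(mesh.n_vertices)
    np.add.at(c_diag, t.ravel(), np.repeat(area / 3.0, 3))

    rows, cols, vals = [], [], []
    for i in range(3):
        for j in range(3):
            rows.append(t[:, i])
            cols.append(t[:, j])
            vals.append((e[:, i] * e[:, j]).sum(axis=1) / (4.0 * area))
    G = sp.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(mesh.n_vertices,) * 2,
    )
    C = sp.diags(c_diag).tocsc()
    return C, G


class SpdeOperator:
    """Cached FEM matrices for one mesh; builds Q(κ, τ) and its sparse
    square root on demand.

    ``precision_root`` returns K with KᵀK = Q, using the factorisation
    Q = (τ²/2)·(κ²C + G) C⁻¹ (κ²C + G); K is sparse because C is diagonal.
    """

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.C, self.G = fem_matrices(mesh)
        c = self.C.diagonal()
        self._c_inv_sqrt = sp.diags(1.0 / np.sqrt(c))
        self._GCinvG = (self.G @ sp.diags(1.0 / c) @ self.G).tocsc()

    def precision(self, kappa: float, tau: float) -> sp.csc_matrix:
        k2 = kappa * kappa
        Q = (tau * tau / 2.0) * (
            k2 * k2 * self.C + 2.0 * k2 * self.G + self._GCinvG
        )
        return Q.tocsc()

    def precision_root(self, kappa: float, tau: float) -> sp.csc_matrix:
        k2 = kappa * kappa
        K = (tau / math.sqrt(2.0)) * (
            self._c_inv_sqrt @ (k2 * self.C + self.G)
        )
        return K.tocsc()

    def sample(self, kappa: float, tau: float, n_draws: int, rng) -> np.ndarray:
        """Draws from N(0, Q⁻¹), shape (n_draws, V)."""
        from scipy.sparse.linalg import splu

        K = self.precision_root(kappa, tau)
        lu = splu(K.tocsc())
        z = rng.standard_normal((self.mesh.n_vertices, n_draws))
        return lu.solve(z).T


def assemble_precision(mesh: Mesh, kappa: float, tau: float) -> PrecisionMatrix:
    if kappa <= 0 or tau <= 0:
        raise ValueError("kappa and tau must be positive")
    op = SpdeOperator(mesh)
    return PrecisionMatrix(
        Q=op.precision(kappa, tau), params=MaternParams.from_kappa_tau(kappa, tau)
    )


def write_mesh(mesh: Mesh, prefix) -> None:
    """Plain-text mesh dump: <prefix>_vertices.tsv, <prefix>_triangles.tsv,
    <prefix>_boundary.tsv (zone column: inner/outer)."""
    import pandas as pd

    pd.DataFrame(mesh.vertices, columns=["x_km", "y_km"]).to_csv(
        f"{prefix}_vertices.tsv", sep="\t", index=False
    )
    pd.DataFrame(mesh.triangles, columns=["v0", "v1", "v2"]).to_csv(
        f"{prefix}_triangles.tsv", sep="\t", index=False
    )
    rows = []
    for zone, poly in (("inner", mesh.inner_boundary), ("outer", mesh.outer_boundary)):
        for x, y in np.asarray(poly.exterior.coords):
            rows.append((zone, x, y))
    pd.DataFrame(rows, columns=["zone", "x_km", "y_km"]).to_csv(
        f"{prefix}_boundary.tsv", sep="\t", index=False
    )


def read_mesh(prefix) -> Mesh:
    import pandas as pd

    verts = pd.read_csv(f"{prefix}_vertices.tsv", sep="\t").to_numpy()
    tris = pd.read_csv(f"{prefix}_triangles.tsv", sep="\t").to_numpy()
    bnd = pd.read_csv(f"{prefix}_boundary.tsv", sep="\t")
    polys = {}
    for zone, grp in bnd.groupby("zone"):
        polys[zone] = Polygon(grp[["x_km", "y_km"]].to_numpy())
    return Mesh(
        vertices=verts,
        triangles=tris.astype(int),
        inner_boundary=polys["inner"],
        outer_boundary=polys["outer"],
    )
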