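"""Mesh and coordinate-geometry primitives for nested head-surface models.

All coordinates are in millimetres.  The head coordinate convention throughout
the package is the CTF frame: origin midway between the left and right
pre-auricular points, x-axis toward the nasion, ALS orientation
(x = anterior, y = left, z = superior), original head size.

Surfaces are *star-shaped* with respect to an interior reference point: every
ray from that point crosses the surface exactly once.  This permits a radial
parameterization on a shared reference triangulation, which is what makes
vertex-wise correspondence across heads (and hence a statistical shape model)
possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

TISSUES = ("scalp", "skull", "csf", "cortex")

_DET_EPS = 1e-12  # Moller-Trumbore determinant cutoff for parallel rays


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """One triangulated tissue boundary.

    Parameters
    ----------
    vertices : (V, 3) float array, mm.
    triangles : (F, 3) int array, 0-based vertex indices, counterclockwise
        winding seen from outside (outward normals) for closed meshes.
    tissue : one of ``scalp, skull, csf, cortex, other``.
    star_center : optional 3-vector; if set, the mesh is flagged star-shaped
        with respect to this point.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    tissue: str = "other"
    star_center: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (F, 3)")
        v = len(self.vertices)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= v
        ):
            raise ValueError("triangle index out of range")
        if self.triangles.size:
            t = self.triangles
            if np.any((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])):
                raise ValueError("triangle repeats a vertex")
        if self.tissue not in TISSUES + ("other",):
            raise ValueError(f"unknown tissue tag {self.tissue!r}")
        if self.star_center is not None:
            self.star_center = np.asarray(self.star_center, dtype=float).reshape(3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def with_vertices(self, vertices: np.ndarray, **kw) -> "SurfaceMesh":
        """Copy of this mesh with new vertex positions (same triangulation)."""
        return replace(self, vertices=np.asarray(vertices, dtype=float), **kw)

    def triangle_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = self.triangles
        return self.vertices[t[:, 0]], self.vertices[t[:, 1]], self.vertices[t[:, 2]]


@dataclass
class Fiducials:
    """Anatomical landmarks: nasion and left/right pre-auricular points (mm)."""

    nas: np.ndarray
    lpa: np.ndarray
    rpa: np.ndarray

    def __post_init__(self) -> None:
        self.nas = np.asarray(self.nas, dtype=float).reshape(3)
        self.lpa = np.asarray(self.lpa, dtype=float).reshape(3)
        self.rpa = np.asarray(self.rpa, dtype=float).reshape(3)

    def as_array(self) -> np.ndarray:
        return np.stack([self.nas, self.lpa, self.rpa])

    def is_collinear(self, tol: float = 1e-9) -> bool:
        n = np.cross(self.lpa - self.nas, self.rpa - self.nas)
        scale = max(
            np.linalg.norm(self.lpa - self.nas), np.linalg.norm(self.rpa - self.nas), 1.0
        )
        return bool(np.linalg.norm(n) <= tol * scale * scale)


@dataclass
class HeadModel:
    """Four nested tissue shells sharing one triangulation, plus fiducials.

    ``shells`` is ordered outermost-first: scalp, skull, CSF, cortex.
    """

    shells: list[SurfaceMesh]
    fiducials: Fiducials
    coord_system: str = "native"

    def __post_init__(self) -> None:
        if len(self.shells) != 4:
            raise ValueError("HeadModel requires exactly four shells")
        v0 = self.shells[0].n_vertices
        t0 = self.shells[0].triangles
        for s in self.shells[1:]:
            if s.n_vertices != v0 or not np.array_equal(s.triangles, t0):
                raise ValueError("shells must share one triangulation")
        if self.coord_system not in ("native", "acpc", "ctf"):
            raise ValueError(f"unknown coord_system {self.coord_system!r}")

    @property
    def v_count(self) -> int:
        return self.shells[0].n_vertices

    @property
    def triangles(self) -> np.ndarray:
        return self.shells[0].triangles

    def shell(self, tissue: str) -> SurfaceMesh:
        for s in self.shells:
            if s.tissue == tissue:
                return s
        raise KeyError(tissue)

    @property
    def scalp(self) -> SurfaceMesh:
        return self.shells[0]

    @property
    def cortex(self) -> SurfaceMesh:
        return self.shells[3]

    def cortex_centroid(self) -> np.ndarray:
        """Mean cortex vertex, the ray origin for shape-difference metrics."""
        return self.shells[3].vertices.mean(axis=0)


@dataclass
class RigidTransform:
    """Proper rigid motion ``p -> rotation @ p + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        rtr = self.rotation @ self.rotation.T
        if not np.allclose(rtr, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def apply_mesh(self, mesh: SurfaceMesh) -> SurfaceMesh:
        center = None
        if mesh.star_center is not None:
            center = self.apply(mesh.star_center)
        return SurfaceMesh(
            self.apply(mesh.vertices), mesh.triangles, mesh.tissue, center
        )

    def apply_fiducials(self, fid: Fiducials) -> Fiducials:
        return Fiducials(self.apply(fid.nas), self.apply(fid.lpa), self.apply(fid.rpa))

    def apply_head(self, head: HeadModel, coord_system: str | None = None) -> HeadModel:
        return HeadModel(
            [self.apply_mesh(s) for s in head.shells],
            self.apply_fiducials(head.fiducials),
            coord_system or head.coord_system,
        )


@dataclass
class RayHit:
    point: np.ndarray
    triangle: int
    distance: float


@dataclass
class NestingReport:
    ok: bool
    min_gap_per_pair: dict[str, float]
    n_misses: int = 0
    n_order_violations: int = 0


# ---------------------------------------------------------------------------
# Reference sphere triangulations
# ---------------------------------------------------------------------------

def _fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-even unit directions (Fibonacci lattice on the sphere)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def unit_sphere_mesh(v_count: int = 1922) -> SurfaceMesh:
    """Evenly triangulated closed unit sphere with exactly ``v_count`` vertices.

    When ``v_count`` matches an icosphere count (10 * 4**n + 2) the subdivided
    icosahedron is used; otherwise a Fibonacci lattice is triangulated by its
    convex hull.  Either way the mesh is closed, genus 0, with 2V - 4 outward
    wound triangles and is star-shaped about the origin.
    """
    import trimesh

    ico_counts = {10 * 4 ** n + 2: n for n in range(8)}
    if v_count in ico_counts:
        ico = trimesh.creation.icosphere(subdivisions=ico_counts[v_count], radius=1.0)
        verts = np.asarray(ico.vertices, dtype=float)
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)
        return SurfaceMesh(verts, np.asarray(ico.faces), "other", np.zeros(3))

    if v_count < 4:
        raise ValueError("need at least 4 vertices for a closed surface")
    from scipy.spatial import ConvexHull

    dirs = _fibonacci_directions(v_count)
    hull = ConvexHull(dirs)
    tris = hull.simplices.astype(np.int64)
    # orient each triangle outward (sphere centered at origin)
    a, b, c = dirs[tris[:, 0]], dirs[tris[:, 1]], dirs[tris[:, 2]]
    normals = np.cross(b - a, c - a)
    flip = np.einsum("ij,ij->i", normals, (a + b + c) / 3.0) < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return SurfaceMesh(dirs, tris, "other", np.zeros(3))


# ---------------------------------------------------------------------------
# Ray casting
# ---------------------------------------------------------------------------

def _moller_trumbore_batch(
    v0: np.ndarray,
    v1: np.ndarray,
    v2: np.ndarray,
    origins: np.ndarray,
    directions: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Ray/triangle intersection parameters for R rays against F triangles.

    Returns ``(t, hit)`` of shape (R, F): ray parameter and a boolean mask of
    valid forward hits.  Degenerate (zero-area) triangles never register.
    """
    e1 = v1 - v0  # (F,3)
    e2 = v2 - v0
    d = directions[:, None, :]  # (R,1,3)
    pvec = np.cross(d, e2[None, :, :])  # (R,F,3)
    det = np.einsum("fk,rfk->rf", e1, pvec)
    ok = np.abs(det) > _DET_EPS
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origins[:, None, :] - v0[None, :, :]  # (R,F,3)
    u = np.einsum("rfk,rfk->rf", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1[None, :, :])
    v = np.einsum("rk,rfk->rf", directions, qvec) * inv_det
    t = np.einsum("fk,rfk->rf", e2, qvec) * inv_det
    tol = 1e-9
    hit = ok & (u >= -tol) & (v >= -tol) & (u + v <= 1.0 + tol) & (t > tol)
    return t, hit


def ray_mesh_intersect(
    mesh: SurfaceMesh, origin: np.ndarray, direction: np.ndarray
) -> RayHit | None:
    """Nearest forward intersection of one ray with a mesh, or ``None``.

    Ties between coincident hits are broken by the lowest triangle index.
    """
    origin = np.asarray(origin, dtype=float).reshape(1, 3)
    direction = np.asarray(direction, dtype=float).reshape(1, 3)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("direction must be nonzero")
    direction = direction / norm
    if mesh.n_triangles == 0:
        return None
    v0, v1, v2 = mesh.triangle_corners()
    t, hit = _moller_trumbore_batch(v0, v1, v2, origin, direction)
    t, hit = t[0], hit[0]
    if not hit.any():
        return None
    t_masked = np.where(hit, t, np.inf)
    idx = int(np.argmin(t_masked))  # argmin returns first (lowest index) on ties
    dist = float(t_masked[idx])
    return RayHit(origin[0] + dist * direction[0], idx, dist)


def ray_mesh_intersect_many(
    mesh: SurfaceMesh,
    origins: np.ndarray,
    directions: np.ndarray,
    max_pairs: int = 2 ** 22,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized nearest-hit query for R rays.

    Returns ``(distances, tri_idx)`` of shape (R,); misses have distance NaN
    and index -1.  Directions are normalized internally.  Work is chunked so
    peak memory stays near ``max_pairs`` ray-triangle pairs.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if origins.shape[0] == 1 and directions.shape[0] > 1:
        origins = np.broadcast_to(origins, directions.shape).copy()
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("direction must be nonzero")
    directions = directions / norms
    n_rays = len(directions)
    f = mesh.n_triangles
    dist = np.full(n_rays, np.nan)
    tri = np.full(n_rays, -1, dtype=np.int64)
    if f == 0:
        return dist, tri
    v0, v1, v2 = mesh.triangle_corners()
    chunk = max(1, max_pairs // max(f, 1))
    for lo in range(0, n_rays, chunk):
        hi = min(lo + chunk, n_rays)
        t, hit = _moller_trumbore_batch(v0, v1, v2, origins[lo:hi], directions[lo:hi])
        t_masked = np.where(hit, t, np.inf)
        idx = np.argmin(t_masked, axis=1)
        best = t_masked[np.arange(hi - lo), idx]
        found = np.isfinite(best)
        dist[lo:hi][found] = best[found]
        tri[lo:hi][found] = idx[found]
    return dist, tri


def star_ray_intersect(
    mesh: SurfaceMesh,
    center: np.ndarray,
    directions: np.ndarray,
    k_candidates: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared-origin nearest-hit query, accelerated for star-shaped meshes.

    Candidate triangles for each ray are those incident to the
    ``k_candidates`` mesh vertices whose directions (seen from ``center``)
    are closest to the ray direction; rays not resolved by a candidate fall
    back to the full triangle scan.  Results equal
    :func:`ray_mesh_intersect_many` (same nearest hit, lowest triangle index
    on ties); only the work is reduced.
    """
    from scipy.spatial import cKDTree

    center = np.asarray(center, dtype=float).reshape(3)
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("direction must be nonzero")
    u = directions / norms
    verts = mesh.vertices - center
    vn = np.linalg.norm(verts, axis=1, keepdims=True)
    vn[vn == 0] = 1.0
    tree = cKDTree(verts / vn)
    _, near = tree.query(u, k=k_candidates)
    near = np.atleast_2d(near)

    # vertex -> incident triangles (CSR over the fixed topology)
    tris = mesh.triangles
    flat = tris.ravel()
    order = np.argsort(flat, kind="stable")
    tri_of = order // 3
    counts = np.bincount(flat, minlength=mesh.n_vertices)
    starts = np.concatenate([[0], np.cumsum(counts)])
    max_deg = int(counts.max()) if len(counts) else 0

    n_rays = len(u)
    cand_per_ray = k_candidates * max_deg
    cand = np.zeros((n_rays, cand_per_ray), dtype=np.int64)
    valid = np.zeros((n_rays, cand_per_ray), dtype=bool)
    for j in range(k_candidates):
        vidx = near[:, j]
        for d in range(max_deg):
            has = d < counts[vidx]
            col = j * max_deg + d
            cand[has, col] = tri_of[starts[vidx[has]] + d]
            valid[:, col] = has

    v = mesh.vertices
    c0 = v[tris[cand, 0]]  # (R, C, 3)
    c1 = v[tris[cand, 1]]
    c2 = v[tris[cand, 2]]
    e1 = c1 - c0
    e2 = c2 - c0
    du = u[:, None, :]
    pvec = np.cross(du, e2)
    det = np.einsum("rck,rck->rc", e1, pvec)
    ok = valid & (np.abs(det) > _DET_EPS)
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = (center - c0)
    a = np.einsum("rck,rck->rc", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    b = np.einsum("rk,rck->rc", u, qvec) * inv_det
    t = np.einsum("rck,rck->rc", e2, qvec) * inv_det
    tol = 1e-9
    hit = ok & (a >= -tol) & (b >= -tol) & (a + b <= 1.0 + tol) & (t > tol)
    t_masked = np.where(hit, t, np.inf)
    # nearest hit; ties resolved to the lowest triangle index
    tmin = t_masked.min(axis=1)
    dist = np.where(np.isfinite(tmin), tmin, np.nan)
    tri_idx = np.full(n_rays, -1, dtype=np.int64)
    found = np.isfinite(tmin)
    if found.any():
        at_min = t_masked <= tmin[:, None] + 1e-300
        big = np.iinfo(np.int64).max
        tri_idx[found] = np.where(at_min, cand, big)[found].min(axis=1)
    missed = ~found
    if missed.any():
        d2, t2 = ray_mesh_intersect_many(mesh, center[None, :], u[missed])
        dist[missed] = d2
        tri_idx[missed] = t2
    return dist, tri_idx


# ---------------------------------------------------------------------------
# CTF alignment
# ---------------------------------------------------------------------------

def ctf_from_fiducials(fid: Fiducials) -> RigidTransform:
    """Rigid transform into the CTF head frame defined by three fiducials.

    Origin is the midpoint of LPA and RPA; x-axis points toward NAS; z is the
    fiducial-plane normal oriented superiorly; y = z x x (so LPA has y > 0).
    """
    if fid.is_collinear():
        raise ValueError("fiducials are collinear: head frame is ill-posed")
    origin = 0.5 * (fid.lpa + fid.rpa)
    x = fid.nas - origin
    x = x / np.linalg.norm(x)
    z = np.cross(x, fid.lpa - fid.rpa)
    z = z / np.linalg.norm(z)
    y = np.cross(z, x)
    rot = np.stack([x, y, z])
    return RigidTransform(rot, -rot @ origin)


# ---------------------------------------------------------------------------
# Scalp-proxy preprocessing
# ---------------------------------------------------------------------------

def cut_above_ears(
    points: np.ndarray, fid: Fiducials, offset: float = 35.0
) -> np.ndarray:
    """Keep points whose height above the fiducial plane exceeds ``offset`` mm.

    The plane is spanned by NAS, LPA and RPA; its normal is oriented
    superiorly (positive z after CTF alignment).  Points exactly at the
    offset are kept.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    ctf = ctf_from_fiducials(fid)
    normal = np.cross(fid.lpa - fid.nas, fid.rpa - fid.nas)
    normal = normal / np.linalg.norm(normal)
    if (ctf.rotation @ normal)[2] < 0:
        normal = -normal
    signed = (points - fid.nas) @ normal
    kept = points[signed >= offset]
    if len(kept) == 0:
        warnings.warn("cut_above_ears removed every point", stacklevel=2)
    return kept


def move_inward(
    points: np.ndarray, normals: np.ndarray, distance: float
) -> np.ndarray:
    """Shift each point inward by ``distance`` mm along its outward normal."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    normals = np.atleast_2d(np.asarray(normals, dtype=float))
    if normals.shape != points.shape:
        raise ValueError("one normal per point required")
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-length normal")
    return points - distance * normals / norms


def vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Outward vertex normals: area-weighted average of incident triangle normals."""
    v0, v1, v2 = mesh.triangle_corners()
    fn = np.cross(v1 - v0, v2 - v0)  # magnitude = 2 * area
    out = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(out, mesh.triangles[:, k], fn)
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return out / norms


def decimate_pointcloud(points: np.ndarray, target_n: int) -> np.ndarray:
    """Farthest-point subsampling to exactly ``target_n`` spatially spread points.

    Deterministic: the seed point is the one farthest from the centroid.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    if target_n <= 0:
        raise ValueError("target_n must be positive")
    if target_n > n:
        raise ValueError("target_n exceeds number of points")
    if target_n == n:
        return points.copy()
    centroid = points.mean(axis=0)
    start = int(np.argmax(np.linalg.norm(points - centroid, axis=1)))
    chosen = np.empty(target_n, dtype=np.int64)
    chosen[0] = start
    d = np.linalg.norm(points - points[start], axis=1)
    for i in range(1, target_n):
        nxt = int(np.argmax(d))
        chosen[i] = nxt
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return points[chosen]


# ---------------------------------------------------------------------------
# Star-shaped meshing and nesting
# ---------------------------------------------------------------------------

def project_to_sphere_triangulation(
    radial_fn: Callable[[np.ndarray], np.ndarray],
    center: np.ndarray,
    reference: SurfaceMesh,
    tissue: str = "other",
) -> SurfaceMesh:
    """Build a star-shaped surface by radially projecting a reference sphere.

    ``radial_fn`` maps an (N, 3) array of unit directions to N positive radii
    (mm).  Vertex i is ``center + radial_fn(u_i) * u_i`` where ``u_i`` are the
    reference sphere's vertex directions; triangles are copied, so all
    surfaces built from one reference share a triangulation.
    """
    center = np.asarray(center, dtype=float).reshape(3)
    u = reference.vertices / np.linalg.norm(reference.vertices, axis=1, keepdims=True)
    r = np.asarray(radial_fn(u), dtype=float).reshape(len(u))
    if np.any(r <= 0):
        raise ValueError("radial function must be strictly positive")
    return SurfaceMesh(center + r[:, None] * u, reference.triangles, tissue, center)


def check_nesting(head: HeadModel, n_rays: int = 200) -> NestingReport:
    """Verify shells appear in order cortex <= csf <= skull <= scalp.

    Casts ``n_rays`` quasi-even rays from the cortex centroid and requires the
    four hit distances to be strictly increasing innermost to outermost along
    every ray.  Reports the minimum radial gap per adjacent shell pair.
    """
    origin = head.cortex_centroid()
    dirs = _fibonacci_directions(n_rays)
    origins = np.broadcast_to(origin, dirs.shape)
    hits = []
    misses = 0
    for s in head.shells:  # scalp, skull, csf, cortex
        d, _ = ray_mesh_intersect_many(s, origins, dirs)
        misses += int(np.isnan(d).sum())
        hits.append(d)
    # innermost to outermost
    order = [hits[3], hits[2], hits[1], hits[0]]
    names = ["cortex-csf", "csf-skull", "skull-scalp"]
    min_gaps: dict[str, float] = {}
    violations = 0
    for name, inner, outer in zip(names, order[:-1], order[1:]):
        gap = outer - inner
        valid = np.isfinite(gap)
        min_gaps[name] = float(np.min(gap[valid])) if valid.any() else float("nan")
        violations += int(np.sum(gap[valid] <= 0))
    ok = misses == 0 and violations == 0
    return NestingReport(ok, min_gaps, misses, violations)
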