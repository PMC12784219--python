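"""Scalp-proxy fitting: estimate PC weights so the model scalp matches a proxy.

Given a statistical shape model and a sparse sample of an individual's scalp
(photogrammetry point cloud or digitized electrode positions), the fit
minimizes

    sum_k || v_proxy_k - v_model_k ||  +  lambda * g(head)

over the leading PC weights, where ``v_model_k`` is either the closest scalp
vertex to proxy point k (*vertex distance*) or the intersection of the ray
from the cortex centroid through proxy point k with the scalp mesh (*shape
difference*, meshing-independent).  Correspondences are recomputed at every
objective evaluation.  The penalty ``g`` discourages adjacent tissue shells
from approaching closer than a threshold T (default 1 mm), keeping the fitted
head usable for boundary-element modeling.

Because only the scalp enters the data term while the components couple all
four tissues, the skull, CSF and cortex surfaces (and the fiducials) are
estimated implicitly through the population covariance.

The minimization is quasi-Newton (BFGS) on weights rescaled by the model's
singular values, with numerical gradients; the objective is piecewise-smooth
because correspondences switch discretely, so the best-seen iterate is
returned.  A much faster alternating frozen-correspondence linear solver is
available as ``optimizer="linear"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

from .mesh import (
    Fiducials,
    HeadModel,
    SurfaceMesh,
    ctf_from_fiducials,
    ray_mesh_intersect_many,
    star_ray_intersect,
)
from .shape_model import PCWeights, ShapeModel, reconstruct, TISSUE_ORDER


@dataclass
class ScalpProxy:
    """Point sample of the outer head surface, with fiducials, in mm."""

    points: np.ndarray
    fiducials: Fiducials
    provenance: str = "photogrammetry"
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 4:
            raise ValueError("a scalp proxy needs at least 4 points")
        if self.provenance not in ("photogrammetry", "electrodes", "mesh"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def to_ctf(self) -> "ScalpProxy":
        """Rigidly align the proxy into the CTF frame of its own fiducials."""
        t = ctf_from_fiducials(self.fiducials)
        return ScalpProxy(
            t.apply(self.points), t.apply_fiducials(self.fiducials),
            self.provenance, self.labels,
        )


@dataclass
class FitConfig:
    """Options for the scalp-proxy fit.

    n_pcs : number of leading components to optimize (10-16 is a good
        accuracy/runtime compromise; large values overfit the scalp proxy).
    metric : ``"shape_difference"`` (default; error along the ray from the
        cortex centroid, meshing-independent) or ``"vertex_distance"``.
    penalty_threshold : T in mm; inter-shell vertex pairs closer than T
        contribute (T - distance) to the penalty.
    penalty_weight : multiplier lambda on the penalty (0 disables it).
    squared : use squared instead of plain Euclidean norms in the data term.
    optimizer : ``"bfgs"`` (default) or ``"linear"`` (alternating
        frozen-correspondence least squares; ignores the penalty).
    """

    n_pcs: int = 16
    metric: str = "shape_difference"
    penalty_threshold: float = 1.0
    penalty_weight: float = 1.0
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0
    squared: bool = False
    optimizer: str = "bfgs"
    fd_step: float = 1e-3  # in singular-value-scaled weight units

    def __post_init__(self) -> None:
        if self.penalty_threshold <= 0:
            raise ValueError("penalty_threshold must be positive")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be at least 1")
        if self.metric not in ("vertex_distance", "shape_difference"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.optimizer not in ("bfgs", "linear"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class FitResult:
    """Outcome of a scalp-proxy fit."""

    weights: PCWeights
    head: HeadModel
    objective: float  # data term at the returned weights (mm)
    penalty: float  # unweighted penalty g (mm)
    residuals: np.ndarray  # per-proxy-point distances (mm)
    n_obj_evals: int
    converged: bool
    trace: list[float] = field(default_factory=list)
    n_ray_fallbacks: int = 0


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def vertex_distance_metric(
    proxy_points: np.ndarray, scalp: SurfaceMesh, return_indices: bool = False
):
    """Distance from each proxy point to its nearest scalp mesh vertex."""
    pts = np.atleast_2d(np.asarray(proxy_points, dtype=float))
    d, idx = cKDTree(scalp.vertices).query(pts)
    if return_indices:
        return d, idx
    return d


def shape_difference_metric(
    proxy_points: np.ndarray,
    scalp: SurfaceMesh,
    center: np.ndarray,
    return_details: bool = False,
):
    """Distance from each proxy point to the scalp along its centroid ray.

    The ray runs from ``center`` (the mean cortex vertex when fitting a full
    head) through the proxy point; the error is the distance between the
    proxy point and the ray's intersection with the scalp mesh.  Rays that
    miss (non-star-shaped intermediate meshes) fall back to the
    nearest-vertex distance for that point; the fallback count is reported.
    """
    pts = np.atleast_2d(np.asarray(proxy_points, dtype=float))
    center = np.asarray(center, dtype=float).reshape(3)
    dirs = pts - center
    radii = np.linalg.norm(dirs, axis=1)
    if np.any(radii == 0):
        raise ValueError("proxy point coincides with the ray center")
    hit_dist, tri = star_ray_intersect(scalp, center, dirs)
    dist = np.abs(hit_dist - radii)
    missed = np.isnan(hit_dist)
    if missed.any():
        dist[missed] = vertex_distance_metric(pts[missed], scalp)
    if return_details:
        return dist, missed, tri
    return dist


# ---------------------------------------------------------------------------
# Inter-shell penalty
# ---------------------------------------------------------------------------

def penalty_g(head: HeadModel, threshold: float = 1.0) -> float:
    """Soft non-intersection penalty between tissue shells.

    For every unordered pair of distinct shells and every cross-shell vertex
    pair closer than ``threshold`` (mm), the shortfall ``threshold - d`` is
    accumulated.  Zero iff all inter-shell vertex pairs are at least the
    threshold apart.
    """
    trees = [cKDTree(s.vertices) for s in head.shells]
    total = 0.0
    for a in range(4):
        for b in range(a + 1, 4):
            dmat = trees[a].sparse_distance_matrix(
                trees[b], threshold, output_type="coo_matrix"
            )
            if dmat.nnz:
                total += float(np.sum(threshold - dmat.data))
    return total


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def _data_term(head: HeadModel, proxy_points: np.ndarray, cfg: FitConfig):
    if cfg.metric == "vertex_distance":
        res = vertex_distance_metric(proxy_points, head.scalp)
        n_fallback = 0
    else:
        res, missed, _ = shape_difference_metric(
            proxy_points, head.scalp, head.cortex_centroid(), return_details=True
        )
        n_fallback = int(missed.sum())
    value = float(np.sum(res ** 2 if cfg.squared else res))
    return value, res, n_fallback


def pcawarp_objective(
    weights: PCWeights | np.ndarray,
    model: ShapeModel,
    proxy: ScalpProxy,
    cfg: FitConfig,
    return_parts: bool = False,
):
    """Full fit objective: summed metric distances plus weighted penalty.

    The head is reconstructed from the weights and correspondences are
    recomputed, so the value reflects the current geometry exactly.
    """
    head = reconstruct(model, weights)
    data, res, n_fallback = _data_term(head, proxy.points, cfg)
    pen = penalty_g(head, cfg.penalty_threshold) if cfg.penalty_weight != 0 else 0.0
    value = data + cfg.penalty_weight * pen
    if return_parts:
        return value, data, pen, res, head, n_fallback
    return value


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _frozen_linear_solve(
    model: ShapeModel, proxy_pts: np.ndarray, cfg: FitConfig, w0: np.ndarray
) -> np.ndarray:
    """One alternating step: freeze correspondences at w0, solve least squares.

    With vertex-distance correspondences the target for proxy point k is a
    scalp vertex; with shape-difference it is the intersection point frozen
    via its triangle's barycentric coordinates.  Either way the target
    position is linear in the weights, giving a small dense LS problem.
    """
    n_pcs = len(w0)
    v = model.v_count
    head = reconstruct(model, w0)
    scalp = head.scalp
    comps = model.components[:n_pcs]
    if model.normalization == "zscore":
        comps = comps * model.scale  # denormalized basis
    scalp_mean = model.mean[: 3 * v].reshape(v, 3)
    scalp_comps = comps[:, : 3 * v].reshape(n_pcs, v, 3)

    if cfg.metric == "vertex_distance":
        _, idx = vertex_distance_metric(proxy_pts, scalp, return_indices=True)
        a = scalp_comps[:, idx, :]  # (n_pcs, K, 3)
        b = proxy_pts - scalp_mean[idx]
    else:
        center = head.cortex_centroid()
        _, missed, tri = shape_difference_metric(
            proxy_pts, scalp, center, return_details=True
        )
        use = ~missed
        if not use.any():
            return w0
        tri = tri[use]
        pts = proxy_pts[use]
        # barycentric coordinates of the hit points on the *current* scalp
        corners = model.triangles[tri]  # (K,3) vertex ids
        d2, _ = star_ray_intersect(scalp, center, proxy_pts - center)
        u = (proxy_pts - center) / np.linalg.norm(
            proxy_pts - center, axis=1, keepdims=True
        )
        hitpts = (center + d2[:, None] * u)[use]
        v0 = scalp.vertices[corners[:, 0]]
        v1 = scalp.vertices[corners[:, 1]]
        v2 = scalp.vertices[corners[:, 2]]
        # solve for barycentric (b1, b2) of hit in triangle plane
        e1, e2 = v1 - v0, v2 - v0
        w = hitpts - v0
        d11 = np.einsum("ij,ij->i", e1, e1)
        d12 = np.einsum("ij,ij->i", e1, e2)
        d22 = np.einsum("ij,ij->i", e2, e2)
        dw1 = np.einsum("ij,ij->i", w, e1)
        dw2 = np.einsum("ij,ij->i", w, e2)
        det = d11 * d22 - d12 * d12
        det[det == 0] = 1.0
        b1 = (d22 * dw1 - d12 * dw2) / det
        b2 = (d11 * dw2 - d12 * dw1) / det
        b0 = 1.0 - b1 - b2
        bary = np.stack([b0, b1, b2], axis=1)  # (K,3)
        a = np.einsum(
            "kc,pkcx->pkx",
            bary,
            scalp_comps[:, corners, :],
        )
        b = pts - np.einsum("kc,kcx->kx", bary, scalp_mean[corners])

    amat = a.reshape(n_pcs, -1).T  # (3K, n_pcs)
    bvec = b.ravel()
    w, *_ = np.linalg.lstsq(amat, bvec, rcond=None)
    return w


def fit_pcawarp(model: ShapeModel, proxy: ScalpProxy, cfg: FitConfig | None = None) -> FitResult:
    """Estimate PC weights from a scalp proxy.

    The proxy is first rigidly aligned into the CTF frame of its own
    fiducials.  Weights start at zero (the mean head).  With the default
    quasi-Newton optimizer, weights are internally rescaled by the model's
    singular values so BFGS sees comparably scaled axes, gradients are
    numerical, and the best-seen iterate is returned (the objective is
    piecewise-smooth because correspondences switch).  Non-convergence at
    ``max_iter`` is reported via ``converged``, never raised.
    """
    cfg = cfg or FitConfig()
    n_pcs = min(cfg.n_pcs, model.n_comp)
    proxy = proxy.to_ctf()

    sv = model.singular_values[:n_pcs].copy()
    sv[sv < 1e-12] = 1.0  # degenerate directions: leave unscaled

    n_evals = 0
    best = {"x": np.zeros(n_pcs), "f": np.inf}

    def objective_scaled(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        f = pcawarp_objective(x * sv, model, proxy, cfg)
        if f < best["f"]:
            best["f"] = f
            best["x"] = x.copy()
        return f

    trace: list[float] = []
    converged = False

    if cfg.optimizer == "linear":
        w = np.zeros(n_pcs)
        f_prev = pcawarp_objective(w, model, proxy, cfg)
        n_evals += 1
        trace.append(f_prev)
        for _ in range(cfg.max_iter):
            w_new = _frozen_linear_solve(model, proxy.points, cfg, w)
            f_new = pcawarp_objective(w_new, model, proxy, cfg)
            n_evals += 1
            if f_new >= f_prev - cfg.tol * max(1.0, abs(f_prev)):
                if f_new < f_prev:
                    w, f_prev = w_new, f_new
                    trace.append(f_new)
                converged = True
                break
            w, f_prev = w_new, f_new
            trace.append(f_new)
        best["x"], best["f"] = w / sv, f_prev
    else:
        x0 = np.zeros(n_pcs)
        f0 = objective_scaled(x0)
        trace.append(f0)

        def cb(xk: np.ndarray) -> None:
            trace.append(best["f"])

        res = optimize.minimize(
            objective_scaled,
            x0,
            method="BFGS",
            jac=None,
            callback=cb,
            options={
                "maxiter": cfg.max_iter,
                "gtol": cfg.tol,
                "eps": cfg.fd_step,
                "finite_diff_rel_step": None,
            },
        )
        converged = bool(res.success)
        if not converged and not np.allclose(res.x, best["x"]):
            # restart once from the best iterate if the line search stalled
            res2 = optimize.minimize(
                objective_scaled,
                best["x"],
                method="BFGS",
                options={"maxiter": max(cfg.max_iter // 2, 10), "gtol": cfg.tol,
                         "eps": cfg.fd_step},
            )
            converged = bool(res2.success)

    w_raw = best["x"] * sv
    value, data, pen, res_vec, head, n_fallback = pcawarp_objective(
        w_raw, model, proxy, cfg, return_parts=True
    )
    return FitResult(
        weights=PCWeights(w_raw),
        head=head,
        objective=data,
        penalty=pen,
        residuals=res_vec,
        n_obj_evals=n_evals,
        converged=converged,
        trace=trace,
        n_ray_fallbacks=n_fallback,
    )
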