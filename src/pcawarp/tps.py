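"""Template-warp baseline: thin-plate-spline individualization.

The established alternative to a statistical shape model is to warp a single
template head (classically the average ICBM-152 anatomy, the "wMNI-4"
four-shell model) to the measured scalp points with a 3D thin-plate spline
and to apply the same warp to the inner shells and fiducials.  This module
re-implements that idea in spirit as the comparison baseline: correspondences
between template scalp and proxy are built by the same centroid-ray
construction as the shape-difference metric, a TPS with kernel U(r) = r (the
3D biharmonic kernel) is fitted on those pairs, and the warp is applied to
all four shells.

Because every proxy point constrains the warp exactly (at zero
regularization), sparse or noisy proxies can bend the inner shells in ways no
real head exhibits — the known failure mode of template warping that the
shape-model approach avoids by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import HeadModel, ray_mesh_intersect_many
from .warp import ScalpProxy


@dataclass
class TPSTransform:
    """Fitted 3D thin-plate spline ``x -> affine(x) + sum_i c_i U(|x - s_i|)``."""

    control_src: np.ndarray  # (L, 3)
    affine: np.ndarray  # (4, 3): rows constant, x, y, z
    coefficients: np.ndarray  # (L, 3)
    bending_energy: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        k = _kernel(pts, self.control_src)
        p = np.column_stack([np.ones(len(pts)), pts])
        return p @ self.affine + k @ self.coefficients


def _kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3D TPS kernel U(r) = r between two point sets."""
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def fit_tps(src: np.ndarray, dst: np.ndarray, regularization: float = 0.0) -> TPSTransform:
    """Fit a 3D thin-plate spline mapping ``src`` control points to ``dst``.

    With zero regularization the transform interpolates ``dst`` exactly at
    ``src``.  The kernel coefficients satisfy the TPS side conditions
    (orthogonality to constants and linear functions of the sources), which
    makes a purely affine correspondence yield zero bending energy.
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape:
        raise ValueError("src and dst must have the same shape")
    n = len(src)
    if n < 4:
        raise ValueError("need at least 4 control points for a 3D TPS")
    k = _kernel(src, src) + regularization * np.eye(n)
    p = np.column_stack([np.ones(n), src])  # (L, 4)
    sys = np.zeros((n + 4, n + 4))
    sys[:n, :n] = k
    sys[:n, n:] = p
    sys[n:, :n] = p.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = dst
    try:
        sol = np.linalg.solve(sys, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "degenerate (coplanar or duplicated) control points; "
            "try regularization > 0"
        ) from exc
    coeff, aff = sol[:n], sol[n:]
    bend = float(np.einsum("ic,ij,jc->", coeff, _kernel(src, src), coeff))
    return TPSTransform(src, aff, coeff, bend)


def default_regularization(src: np.ndarray) -> float:
    """1e-6 times the median control spacing; stabilizes near-coplanar layouts."""
    from scipy.spatial import cKDTree

    src = np.atleast_2d(np.asarray(src, dtype=float))
    d, _ = cKDTree(src).query(src, k=2)
    return 1e-6 * float(np.median(d[:, 1]))


def warp_headmodel(
    template: HeadModel,
    proxy: ScalpProxy,
    regularization: float | None = None,
) -> HeadModel:
    """Warp a template head to a scalp proxy; apply the warp to all shells.

    Correspondences: each proxy point is paired with the intersection of the
    ray from the template cortex centroid through the point with the template
    scalp (the same construction as the shape-difference metric, so the two
    individualization routes see identical information).  A point whose ray
    misses the scalp is dropped.  The fitted TPS is applied to all four
    shells and the fiducials; the shared triangulation is preserved.
    """
    proxy = proxy.to_ctf()
    center = template.cortex_centroid()
    dirs = proxy.points - center
    dist, _ = ray_mesh_intersect_many(template.scalp, center[None, :], dirs)
    good = np.isfinite(dist)
    if good.sum() < 4:
        raise ValueError("too few valid scalp correspondences for a TPS warp")
    u = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    src = center + dist[good, None] * u[good]
    dst = proxy.points[good]
    if regularization is None:
        regularization = default_regularization(src)
    tps = fit_tps(src, dst, regularization)
    shells = [s.with_vertices(tps(s.vertices)) for s in template.shells]
    fid = template.fiducials
    nas, lpa, rpa = tps(np.stack([fid.nas, fid.lpa, fid.rpa]))
    return HeadModel(shells, type(fid)(nas, lpa, rpa), template.coord_system)
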