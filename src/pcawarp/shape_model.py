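"""Low-dimensional statistical shape model over nested head surfaces.

A head with V vertices per shell is flattened into a single vector of
``12 * V + 9`` coordinates: four shells (scalp, skull, CSF, cortex) of V
vertices with three coordinates each, followed by the three fiducials NAS,
LPA, RPA.  Because the population shares one triangulation and one head
frame, corresponding coordinates are comparable across heads and a plain PCA
of the (centered) coordinate matrix yields shape components: smooth,
population-wide deformation modes that couple the four tissues.  Adjusting a
handful of component weights then moves all four surfaces and the fiducials
coherently — the property the scalp-proxy fit exploits to estimate skull,
CSF and cortex from scalp measurements alone.

PCA is computed by thin SVD of the centered data matrix (no covariance
matrix is formed): for D in the tens of thousands and a few hundred heads
this is both faster and numerically safer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import Fiducials, HeadModel, SurfaceMesh, TISSUES

TISSUE_ORDER = TISSUES  # scalp, skull, csf, cortex — outermost first


@dataclass
class ShapeVector:
    """Flattened head coordinates (mm): 4 shells then NAS, LPA, RPA."""

    values: np.ndarray
    v_count: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != 12 * self.v_count + 9:
            raise ValueError(
                f"shape vector length {len(self.values)} != 12*{self.v_count}+9"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("shape vector contains non-finite entries")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PCWeights:
    """Weights of the leading principal components (one scalar per PC)."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()

    @property
    def n_pcs(self) -> int:
        return len(self.w)


@dataclass
class ShapeModel:
    """PCA shape basis over flattened head coordinates.

    ``components`` rows are orthonormal principal directions (length D);
    ``singular_values`` carry the per-component scale of the training data.
    ``normalization`` is ``"center"`` (subtract the mean; default — all
    coordinates share mm units) or ``"zscore"`` (additionally divide by the
    per-coordinate standard deviation held in ``scale``).
    ``triangles`` stores the shared reference triangulation so that a head
    can be rebuilt from a vector alone.
    """

    mean: np.ndarray
    components: np.ndarray
    singular_values: np.ndarray
    v_count: int
    triangles: np.ndarray
    normalization: str = "center"
    scale: np.ndarray | None = None
    n_train: int = 0
    tissue_order: tuple[str, ...] = TISSUE_ORDER

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.components = np.atleast_2d(np.asarray(self.components, dtype=float))
        self.singular_values = np.asarray(self.singular_values, dtype=float).ravel()
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        d = 12 * self.v_count + 9
        if self.mean.shape != (d,):
            raise ValueError("mean length inconsistent with v_count")
        if self.components.shape[1] != d:
            raise ValueError("component length inconsistent with v_count")
        if len(self.singular_values) != len(self.components):
            raise ValueError("one singular value per component required")
        if np.any(np.diff(self.singular_values) > 1e-9 * self.singular_values[0]):
            raise ValueError("singular values must be non-increasing")
        if self.normalization not in ("center", "zscore"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "zscore" and self.scale is None:
            raise ValueError("zscore normalization requires a scale vector")

    @property
    def n_comp(self) -> int:
        return len(self.components)

    @property
    def dim(self) -> int:
        return len(self.mean)

    def normalize(self, values: np.ndarray) -> np.ndarray:
        z = np.asarray(values, dtype=float) - self.mean
        if self.normalization == "zscore":
            z = z / self.scale
        return z

    def denormalize(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if self.normalization == "zscore":
            z = z * self.scale
        return z + self.mean


# ---------------------------------------------------------------------------
# Flatten / unflatten
# ---------------------------------------------------------------------------

def flatten_head(head: HeadModel) -> ShapeVector:
    """Flatten a head into [scalp xyz..., skull..., csf..., cortex..., NAS, LPA, RPA]."""
    v = head.v_count
    parts = [head.shell(t).vertices.ravel() for t in TISSUE_ORDER]
    parts.append(head.fiducials.as_array().ravel())
    return ShapeVector(np.concatenate(parts), v)


def unflatten(sv: ShapeVector, triangles: np.ndarray, coord_system: str = "ctf") -> HeadModel:
    """Inverse of :func:`flatten_head` given the shared triangulation."""
    v = sv.v_count
    vals = sv.values
    shells = []
    for i, tissue in enumerate(TISSUE_ORDER):
        block = vals[i * 3 * v : (i + 1) * 3 * v].reshape(v, 3)
        shells.append(SurfaceMesh(block, triangles, tissue))
    fid_block = vals[12 * v :].reshape(3, 3)
    fid = Fiducials(*fid_block)
    return HeadModel(shells, fid, coord_system)


# ---------------------------------------------------------------------------
# Model fitting and use
# ---------------------------------------------------------------------------

def fit_shape_model(
    population: list[HeadModel],
    n_comp: int | None = None,
    normalization: str = "center",
) -> ShapeModel:
    """PCA of the flattened, normalized head coordinates of a population.

    With centering alone the components are the right-singular vectors of the
    centered data matrix; reconstruction of any training head with all
    components is exact to numerical precision.
    """
    if len(population) < 2:
        raise ValueError("need at least two heads")
    v = population[0].v_count
    tris = population[0].triangles
    for h in population[1:]:
        if h.v_count != v or not np.array_equal(h.triangles, tris):
            raise ValueError("population heads must share one topology")
    x = np.stack([flatten_head(h).values for h in population])
    mean = x.mean(axis=0)
    xc = x - mean
    scale = None
    if normalization == "zscore":
        scale = xc.std(axis=0, ddof=1)
        scale[scale < 1e-12] = 1.0
        xc = xc / scale
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    max_comp = len(population) - 1  # centering removes one degree of freedom
    if n_comp is None:
        n_comp = max_comp
    n_comp = min(n_comp, max_comp)
    return ShapeModel(
        mean=mean,
        components=vt[:n_comp],
        singular_values=s[:n_comp],
        v_count=v,
        triangles=tris,
        normalization=normalization,
        scale=scale,
        n_train=len(population),
    )


def reconstruct(model: ShapeModel, weights: PCWeights | np.ndarray) -> HeadModel:
    """Head generated by the shape model at the given PC weights.

    Zero weights return the mean head.
    """
    w = weights.w if isinstance(weights, PCWeights) else np.asarray(weights, float).ravel()
    if len(w) > model.n_comp:
        raise ValueError("more weights than model components")
    z = w @ model.components[: len(w)]
    sv = ShapeVector(model.denormalize(z), model.v_count)
    return unflatten(sv, model.triangles)


def project_weights(model: ShapeModel, head: HeadModel, n_pcs: int) -> PCWeights:
    """Least-squares PC weights of a head (closed form via orthonormality)."""
    if n_pcs > model.n_comp:
        raise ValueError(f"n_pcs={n_pcs} exceeds model n_comp={model.n_comp}")
    z = model.normalize(flatten_head(head).values)
    return PCWeights(model.components[:n_pcs] @ z)


# ---------------------------------------------------------------------------
# Leave-one-out reconstruction-error curves
# ---------------------------------------------------------------------------

def _head_errors(fitted: HeadModel, truth: HeadModel, metric: str) -> dict[str, float]:
    from .evaluation import shape_error_report  # local import avoids cycle

    rep = shape_error_report(fitted, truth)
    return {t: rep.per_tissue[metric][t]["mean"] for t in TISSUE_ORDER}


def loo_curve(
    population: list[HeadModel],
    pcs_grid: list[int],
    metric: str = "vertex_distance",
    normalization: str = "center",
) -> pd.DataFrame:
    """Leave-one-head-out reconstruction error versus number of components.

    For each held-out head, the model is fit on the remaining heads; the
    held-out head is projected onto the leading ``n_pcs`` components and
    reconstructed, and the per-tissue error to the true head is scored with
    the requested metric.  ``n_pcs = 0`` is the mean-head baseline.  Returns
    mean error over folds, indexed by n_pcs with one column per tissue.
    """
    if len(population) < 3:
        raise ValueError("need at least three heads for cross-validation")
    rows: dict[int, dict[str, list[float]]] = {
        k: {t: [] for t in TISSUE_ORDER} for k in pcs_grid
    }
    for i, truth in enumerate(population):
        train = population[:i] + population[i + 1 :]
        model = fit_shape_model(train, normalization=normalization)
        for k in pcs_grid:
            kk = min(k, model.n_comp)
            w = project_weights(model, truth, kk) if kk > 0 else PCWeights([])
            fitted = reconstruct(model, w)
            errs = _head_errors(fitted, truth, metric)
            for t in TISSUE_ORDER:
                rows[k][t].append(errs[t])
    table = pd.DataFrame(
        {t: [float(np.mean(rows[k][t])) for k in pcs_grid] for t in TISSUE_ORDER},
        index=pd.Index(pcs_grid, name="n_pcs"),
    )
    return table
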