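"""Shape-error reporting, model comparison statistics, and a dipole harness.

Two shape metrics are reported throughout: *vertex distance* (Euclidean
distance between corresponding vertices; depends on the meshing) and *shape
difference* (distance along the ray from the cortex centroid through each
true vertex to the fitted surface; approximately normal to the surface and
independent of where vertices sit on it).

The equivalent-current-dipole harness mirrors the standard two-stage inverse
fit: a linear grid search minimizing residual variance (RV) over a regular
lattice inside the cortex, with the dipole moment solved in closed form per
grid point, followed by a nonlinear refinement of the position.  The forward
model is an analytic homogeneous conducting sphere — adequate for exercising
the fitting machinery; realistic multi-compartment BEM/FEM solvers are
deliberately out of scope and any object satisfying the small forward
interface (``gain``/``contains``) can be substituted.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .mesh import HeadModel, SurfaceMesh, ray_mesh_intersect_many, star_ray_intersect
from .shape_model import TISSUE_ORDER
from .warp import FitConfig, ScalpProxy, fit_pcawarp

# fixed isotropic conductivities (S/m) used for four-shell head models;
# cortex is the mean of gray and white matter
CONDUCTIVITY = {"scalp": 0.465, "skull": 0.01, "csf": 1.65, "cortex": 0.201}


# ---------------------------------------------------------------------------
# Shape-error reports
# ---------------------------------------------------------------------------

@dataclass
class ErrorReport:
    """Per-tissue shape errors of a fitted head against a ground truth."""

    per_tissue: dict  # {metric: {tissue: {median, mean, sd}}}
    n_vertices: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric, tissues in self.per_tissue.items():
            for tissue, st in tissues.items():
                rows.append({"metric": metric, "tissue": tissue, **st})
        return pd.DataFrame(rows)


def _shape_difference_per_vertex(
    fitted_shell: SurfaceMesh, truth_shell: SurfaceMesh, center: np.ndarray
) -> np.ndarray:
    """Distance from each truth vertex along its centroid ray to the fitted shell."""
    dirs = truth_shell.vertices - center
    radii = np.linalg.norm(dirs, axis=1)
    hit, _ = star_ray_intersect(fitted_shell, center, dirs)
    out = np.abs(hit - radii)
    missed = np.isnan(hit)
    if missed.any():  # fall back to nearest fitted vertex
        from .warp import vertex_distance_metric

        out[missed] = vertex_distance_metric(truth_shell.vertices[missed], fitted_shell)
    return out


def per_vertex_error_map(
    fitted: HeadModel, truth: HeadModel, cap: float = 11.0
) -> dict[str, dict[str, np.ndarray]]:
    """Per-vertex shape-difference maps per tissue.

    ``display`` values are capped at ``cap`` mm (for rendering); ``raw``
    values are retained.
    """
    center = truth.cortex_centroid()
    out = {}
    for tissue in TISSUE_ORDER:
        raw = _shape_difference_per_vertex(fitted.shell(tissue), truth.shell(tissue), center)
        out[tissue] = {"raw": raw, "display": np.minimum(raw, cap)}
    return out


def shape_error_report(fitted: HeadModel, truth: HeadModel) -> ErrorReport:
    """Median/mean/sd per tissue under both shape metrics."""
    center = truth.cortex_centroid()
    per: dict = {"vertex_distance": {}, "shape_difference": {}}
    same_topology = fitted.v_count == truth.v_count
    for tissue in TISSUE_ORDER:
        f_shell, t_shell = fitted.shell(tissue), truth.shell(tissue)
        if same_topology:
            vd = np.linalg.norm(f_shell.vertices - t_shell.vertices, axis=1)
            per["vertex_distance"][tissue] = _stats(vd)
        sd = _shape_difference_per_vertex(f_shell, t_shell, center)
        per["shape_difference"][tissue] = _stats(sd)
    if not same_topology:
        per.pop("vertex_distance")
    return ErrorReport(per, truth.v_count)


def _stats(x: np.ndarray) -> dict[str, float]:
    return {
        "median": float(np.median(x)),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
    }


# ---------------------------------------------------------------------------
# Residual variance
# ---------------------------------------------------------------------------

def residual_variance(x: np.ndarray, xhat: np.ndarray) -> float:
    """RV = sum((x - xhat)^2) / sum(x^2): unexplained fraction of signal power.

    Scale-invariant in the pair (x, xhat); 0 for a perfect fit, 1 for a zero
    prediction.
    """
    x = np.asarray(x, dtype=float).ravel()
    xhat = np.asarray(xhat, dtype=float).ravel()
    if x.shape != xhat.shape:
        raise ValueError("patterns must have the same length")
    denom = float(np.sum(x * x))
    if denom == 0.0:
        raise ValueError("all-zero target pattern")
    return float(np.sum((x - xhat) ** 2) / denom)


# ---------------------------------------------------------------------------
# Analytic single-sphere EEG forward model
# ---------------------------------------------------------------------------

@dataclass
class Dipole:
    """Equivalent current dipole: position (mm) and moment vector."""

    position: np.ndarray
    moment: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.moment = np.asarray(self.moment, dtype=float).reshape(3)


@dataclass
class ElectrodeSet:
    labels: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if len(self.positions) < 3:
            raise ValueError("need at least 3 electrodes")


@dataclass
class ConductingSphere:
    """Homogeneous conducting sphere: center (mm), radius (mm), conductivity (S/m)."""

    center: np.ndarray
    radius: float
    conductivity: float = 0.33

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)


def _sphere_gain(
    pos: np.ndarray, electrodes: np.ndarray, sphere: ConductingSphere
) -> np.ndarray:
    """(E, 3) gain: average-referenced surface potential per unit moment axis.

    Closed form for the interior-Neumann problem (insulating exterior),
    obtained by summing the classical Legendre series with generating
    functions.  With f = b/R (dipole eccentricity), x = cos of the angle
    between dipole and electrode directions, and g = sqrt(1 - 2fx + f^2):

        Phi = (1 / 4 pi sigma R^2) [ (p.bhat) S1 + (p.rhat - (p.bhat) x) T ]
        S1  = 2 (x - f) / g^3 + (1/f) (1/g - 1)
        T   = 2 / g^3 + (g + 1) / (g (1 - f x + g))

    The limit f -> 0 reduces to the central-dipole result 3 p.rhat / (4 pi
    sigma R^2).
    """
    b_vec = pos - sphere.center
    b = float(np.linalg.norm(b_vec))
    r_sph = sphere.radius
    if b >= r_sph:
        raise ValueError("dipole must be strictly inside the sphere")
    sigma = sphere.conductivity
    rhat = (electrodes - sphere.center) / r_sph  # unit since electrodes on sphere
    pref = 1.0 / (4.0 * np.pi * sigma * r_sph ** 2)
    if b < 1e-9 * r_sph:
        gain = 3.0 * pref * rhat
    else:
        bhat = b_vec / b
        f = b / r_sph
        x = rhat @ bhat
        g = np.sqrt(np.maximum(1.0 - 2.0 * f * x + f * f, 1e-30))
        s1 = 2.0 * (x - f) / g ** 3 + (1.0 / g - 1.0) / f
        t = 2.0 / g ** 3 + (g + 1.0) / (g * (1.0 - f * x + g))
        # potential for moment p: pref * [ (p.bhat) s1 + (p.rhat - (p.bhat) x) t ]
        gain = pref * (np.outer(s1 - t * x, bhat) + t[:, None] * rhat)
    return gain - gain.mean(axis=0)  # average reference


class SphereForwardModel:
    """Forward interface over a homogeneous sphere and a fixed montage.

    Any substitute forward model needs ``gain(position) -> (E, 3)`` and
    ``contains(position) -> bool``.
    """

    def __init__(self, sphere: ConductingSphere, electrodes: ElectrodeSet):
        radii = np.linalg.norm(electrodes.positions - sphere.center, axis=1)
        if not np.allclose(radii, sphere.radius, rtol=1e-6):
            raise ValueError("electrodes must lie on the sphere surface")
        self.sphere = sphere
        self.electrodes = electrodes

    def gain(self, position: np.ndarray) -> np.ndarray:
        return _sphere_gain(
            np.asarray(position, float), self.electrodes.positions, self.sphere
        )

    def contains(self, position: np.ndarray, margin: float = 1e-6) -> bool:
        d = np.linalg.norm(np.asarray(position, float) - self.sphere.center)
        return bool(d < self.sphere.radius * (1.0 - margin))

    def potentials(self, dipole: Dipole) -> np.ndarray:
        return self.gain(dipole.position) @ dipole.moment


def sphere_forward(
    dipole: Dipole, electrodes: ElectrodeSet, sphere: ConductingSphere
) -> np.ndarray:
    """Average-referenced potentials of a dipole in a homogeneous sphere."""
    return _sphere_gain(dipole.position, electrodes.positions, sphere) @ dipole.moment


# ---------------------------------------------------------------------------
# Dipole fitting
# ---------------------------------------------------------------------------

@dataclass
class DipoleFitResult:
    position: np.ndarray
    moment: np.ndarray
    rv: float
    stage: str  # "linear" or "nonlinear"
    n_evals: int = 0
    aborted: bool = False
    skipped_grid_points: int = 0


def source_grid(cortex: SurfaceMesh, spacing: float = 10.0) -> np.ndarray:
    """Axis-aligned lattice of candidate source positions inside a closed mesh.

    Interior test is ray parity: a point is inside iff a ray (+x) crosses the
    surface an odd number of times.
    """
    lo = cortex.vertices.min(axis=0)
    hi = cortex.vertices.max(axis=0)
    axes = [np.arange(lo[k] + spacing / 2, hi[k], spacing) for k in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    if len(pts) == 0:
        return pts
    inside = _ray_parity_inside(cortex, pts)
    return pts[inside]


def _ray_parity_inside(mesh: SurfaceMesh, points: np.ndarray) -> np.ndarray:
    v0, v1, v2 = mesh.triangle_corners()
    from .mesh import _moller_trumbore_batch

    direction = np.array([[1.0, 0.002, 0.0007]])  # slightly off-axis to dodge edges
    direction = direction / np.linalg.norm(direction)
    counts = np.zeros(len(points), dtype=int)
    chunk = max(1, 2 ** 22 // max(mesh.n_triangles, 1))
    for lo_i in range(0, len(points), chunk):
        hi_i = min(lo_i + chunk, len(points))
        dirs = np.broadcast_to(direction, (hi_i - lo_i, 3))
        _, hit = _moller_trumbore_batch(v0, v1, v2, points[lo_i:hi_i], dirs)
        counts[lo_i:hi_i] = hit.sum(axis=1)
    return counts % 2 == 1


def _moment_and_rv(pattern: np.ndarray, gain: np.ndarray):
    moment, *_ = np.linalg.lstsq(gain, pattern, rcond=None)
    return moment, residual_variance(pattern, gain @ moment)


def dipole_fit_linear(
    pattern: np.ndarray, forward, grid: np.ndarray
) -> DipoleFitResult:
    """Exhaustive RV scan over a source grid with per-point linear moments.

    At each grid position the optimal moment is the least-squares solution
    against the 3-column gain; the position with the lowest RV wins, ties
    broken by the lowest grid index.  Rank-deficient gains are skipped and
    counted.
    """
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    if len(grid) == 0:
        raise ValueError("empty source grid")
    best_rv = np.inf
    best: DipoleFitResult | None = None
    skipped = 0
    for i, pos in enumerate(grid):
        g = forward.gain(pos)
        if np.linalg.matrix_rank(g) < 3:
            skipped += 1
            continue
        moment, rv = _moment_and_rv(pattern, g)
        if rv < best_rv - 1e-15:
            best_rv = rv
            best = DipoleFitResult(pos.copy(), moment, rv, "linear", n_evals=i + 1)
    if best is None:
        return DipoleFitResult(
            np.full(3, np.nan), np.zeros(3), 1.0, "linear",
            aborted=True, skipped_grid_points=skipped,
        )
    best.n_evals = len(grid)
    best.skipped_grid_points = skipped
    return best


def dipole_fit_nonlinear(
    pattern: np.ndarray, forward, init: DipoleFitResult
) -> DipoleFitResult:
    """Refine a dipole position continuously, re-solving the moment per step.

    Nelder-Mead over position (derivative-free; the RV landscape near the
    compartment boundary is not smooth), positions outside the source
    compartment rejected with a large objective.  Never returns a higher RV
    than the initializer; an aborted fit is flagged with RV = 1.0.
    """
    if init.aborted or not np.all(np.isfinite(init.position)):
        return DipoleFitResult(
            np.full(3, np.nan), np.zeros(3), 1.0, "nonlinear", aborted=True
        )
    n_evals = 0

    def objective(pos: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        if not forward.contains(pos):
            return 2.0
        g = forward.gain(pos)
        if np.linalg.matrix_rank(g) < 3:
            return 2.0
        _, rv = _moment_and_rv(pattern, g)
        return rv

    res = optimize.minimize(
        objective, init.position, method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 400},
    )
    pos = res.x
    if forward.contains(pos):
        moment, rv = _moment_and_rv(pattern, forward.gain(pos))
    else:
        rv = np.inf
        moment = np.zeros(3)
    if rv > init.rv:  # keep the better iterate
        pos, moment, rv = init.position, init.moment, init.rv
    return DipoleFitResult(np.asarray(pos), moment, float(rv), "nonlinear", n_evals)


def add_noise_snr(
    pattern: np.ndarray, snr: float, rng: np.random.Generator, kind: str = "power"
) -> np.ndarray:
    """Add white noise at a given signal-to-noise ratio.

    ``kind="power"`` (default) interprets SNR as signal power / noise power;
    ``kind="amplitude"`` as an RMS amplitude ratio.
    """
    pattern = np.asarray(pattern, dtype=float)
    p_sig = float(np.mean(pattern ** 2))
    if kind == "power":
        sd = np.sqrt(p_sig / snr)
    elif kind == "amplitude":
        sd = np.sqrt(p_sig) / snr
    else:
        raise ValueError(f"unknown SNR kind {kind!r}")
    return pattern + rng.normal(0.0, sd, pattern.shape)


# ---------------------------------------------------------------------------
# Paired model comparison
# ---------------------------------------------------------------------------

def compare_models(paired_errors: pd.DataFrame) -> pd.DataFrame:
    """One-sided Wilcoxon signed-rank tests between all ordered model pairs.

    ``paired_errors`` has one row per observation (head/dipole) and one
    column per model.  For each ordered pair (A, B) the alternative is that
    A's errors are smaller than B's.  P-values are Benjamini-Hochberg
    adjusted over all tested pairs; all-tied pairs get p = 1 and a flag.
    """
    from statsmodels.stats.multitest import multipletests

    if len(paired_errors) < 6:
        raise ValueError("need at least 6 paired observations")
    models = list(paired_errors.columns)
    rows = []
    for a in models:
        for b in models:
            if a == b:
                continue
            diff = paired_errors[a].to_numpy() - paired_errors[b].to_numpy()
            if np.all(diff == 0):
                rows.append({"model_a": a, "model_b": b, "p_raw": 1.0, "all_tied": True})
                continue
            stat = stats.wilcoxon(diff, alternative="less")
            rows.append(
                {"model_a": a, "model_b": b, "p_raw": float(stat.pvalue),
                 "all_tied": False}
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p_raw"].to_numpy(), method="fdr_bh")[1]
    return table


# ---------------------------------------------------------------------------
# PC-count / proxy-count sweep
# ---------------------------------------------------------------------------

def sweep_table(
    population,
    pcs_grid: list[int] = (1, 5, 10, 16),
    proxy_sizes: list[int] = (21, 64, 343),
    n_folds: int | None = None,
    proxy_mode: str = "electrodes",
    proxy_noise_sd: float = 0.0,
    metric: str = "shape_difference",
    max_iter: int = 40,
    seed: int = 0,
) -> pd.DataFrame:
    """Full factorial leave-one-out accuracy sweep over PC and proxy counts.

    For each (n_pcs, proxy size) cell and each evaluated fold, the shape
    model is fit on all other heads, a proxy of the requested size is sampled
    from the held-out head, the scalp-proxy fit is run, and per-tissue median
    shape differences against the held-out truth are recorded.  ``n_folds``
    limits how many held-out heads are evaluated (all by default).  Runtime
    per cell is logged in the table.
    """
    from .shape_model import fit_shape_model

    heads = population.heads if hasattr(population, "heads") else list(population)
    n = len(heads)
    folds = range(n if n_folds is None else min(n_folds, n))
    rows = []
    models = {}
    for i in folds:
        train = heads[:i] + heads[i + 1 :]
        models[i] = fit_shape_model(train)
    for n_pcs in pcs_grid:
        for n_proxy in proxy_sizes:
            t0 = time.perf_counter()
            errs = {t: [] for t in TISSUE_ORDER}
            for i in folds:
                proxy = sample_scalp_proxy_cached(
                    heads[i], proxy_mode, n_proxy, proxy_noise_sd, seed + i
                )
                cfg = FitConfig(n_pcs=n_pcs, metric=metric, max_iter=max_iter)
                fit = fit_pcawarp(models[i], proxy, cfg)
                rep = shape_error_report(fit.head, heads[i])
                for t in TISSUE_ORDER:
                    errs[t].append(rep.per_tissue["shape_difference"][t]["median"])
            rows.append(
                {
                    "n_pcs": n_pcs,
                    "n_proxy": n_proxy,
                    "runtime_s": time.perf_counter() - t0,
                    **{t: float(np.median(errs[t])) for t in TISSUE_ORDER},
                }
            )
    return pd.DataFrame(rows)


def sample_scalp_proxy_cached(head, mode, n_points, noise_sd, seed):
    from .synthetic import sample_scalp_proxy

    return sample_scalp_proxy(head, mode, n_points, noise_sd, seed)
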