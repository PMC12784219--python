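"""Synthetic populations of nested head models with low-rank shape variation.

The real training database behind the shape model is a large set of MRI
segmentations meshed on a shared sphere-projection triangulation.  This
module generates a statistical stand-in: per head, four star-shaped
ellipsoidal shells on one reference triangulation, deformed by a small number
of smooth latent shape factors shared (with tissue-specific loadings) across
all tissues, plus independent vertex noise.  The cross-tissue coupling is the
property that makes inner surfaces predictable from the scalp — the same
assumption the real database embodies.

Construction is *exactly linear* in the latent variables: head i equals the
template plus ``sum_f z_if * mode_f`` where each mode displaces all mesh
vertices and the fiducials while preserving CTF consistency (fiducial
midpoint at the origin, NAS on +x, ears in the z = 0 plane).  A noiseless
population therefore has sample covariance of rank exactly ``k_latent``, and
latent recovery experiments have a known ground truth.  The antisymmetric
left/right part of the ear displacement is folded into the origin — which is
precisely what fiducial-based CTF alignment does to a real head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import (
    Fiducials,
    HeadModel,
    SurfaceMesh,
    TISSUES,
    check_nesting,
    cut_above_ears,
    decimate_pointcloud,
    project_to_sphere_triangulation,
    ray_mesh_intersect_many,
    unit_sphere_mesh,
)
from .warp import ScalpProxy


@dataclass
class PopulationSpec:
    """Parameters of the synthetic head population.

    base_radii : mean shell radii in mm, outermost first (scalp > skull >
        CSF > cortex).  100/95/90/85 gives adult-scale shells with 5 mm
        inter-shell gaps.
    anisotropy : per-axis scale of all shells; the default makes heads
        longer front-to-back than side-to-side, roughly adult proportions.
    mode_amplitudes : RMS scalp displacement (mm) per latent factor; the
        default geometric decay gives a few dominant factors and a total
        scalp variation of ~5 mm RMS, matching adult inter-individual
        head-size variability.
    tissue_loadings : (4, k) coupling of tissues to factors; by default every
        factor deforms all four shells with slightly smaller gain toward the
        cortex, so inner surfaces are correlated with — but not identical
        to — the scalp.
    vertex_noise_sd : per-vertex isotropic jitter (mm) emulating segmentation
        and meshing noise.
    """

    n_heads: int = 60
    k_latent: int = 8
    base_radii: tuple[float, float, float, float] = (100.0, 95.0, 90.0, 85.0)
    anisotropy: tuple[float, float, float] = (1.0, 0.82, 0.95)
    mode_amplitudes: np.ndarray | None = None
    tissue_loadings: np.ndarray | None = None
    vertex_noise_sd: float = 0.3
    v_count: int = 1922
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(a > b for a, b in zip(self.base_radii, self.base_radii[1:])):
            raise ValueError("base radii must be strictly decreasing")
        if self.k_latent > 15:
            raise ValueError("at most 15 latent factors (harmonics up to degree 3)")
        if self.mode_amplitudes is None:
            self.mode_amplitudes = 3.0 * 0.85 ** np.arange(self.k_latent)
        self.mode_amplitudes = np.asarray(self.mode_amplitudes, float)[: self.k_latent]
        if self.tissue_loadings is None:
            gains = np.array([1.0, 0.92, 0.88, 0.82])
            self.tissue_loadings = np.tile(gains[:, None], (1, self.k_latent))
        self.tissue_loadings = np.asarray(self.tissue_loadings, float)
        if self.tissue_loadings.shape != (4, self.k_latent):
            raise ValueError("tissue_loadings must be (4, k_latent)")


@dataclass
class SyntheticPopulation:
    heads: list[HeadModel]
    latents: np.ndarray  # (n_heads, k_latent)
    spec: PopulationSpec
    n_rejected: int = 0


# ---------------------------------------------------------------------------
# Smooth directional mode functions
# ---------------------------------------------------------------------------

def harmonic_modes(directions: np.ndarray, k: int) -> np.ndarray:
    """First ``k`` real spherical harmonics (degrees 1-3) on unit directions.

    Ordered deterministically by (degree, order): (1,-1), (1,0), (1,1),
    (2,-2), ...  Scaled so each mode has unit RMS over the sphere.
    Returns (N, k).
    """
    from scipy.special import sph_harm_y

    u = np.atleast_2d(np.asarray(directions, float))
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    phi = np.arctan2(u[:, 1], u[:, 0])
    cols = []
    for l in range(1, 4):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m > 0:
                val = np.sqrt(2.0) * (-1.0) ** m * y.real
            elif m < 0:
                val = np.sqrt(2.0) * (-1.0) ** m * y.imag
            else:
                val = y.real
            cols.append(val * np.sqrt(4.0 * np.pi))  # unit RMS over the sphere
            if len(cols) == k:
                return np.column_stack(cols)
    return np.column_stack(cols[:k])


def _ellipsoid_radius(u: np.ndarray, semi_axes: np.ndarray) -> np.ndarray:
    q = (u / semi_axes) ** 2
    return 1.0 / np.sqrt(q.sum(axis=1))


# ---------------------------------------------------------------------------
# Head construction
# ---------------------------------------------------------------------------

def _build_head(
    spec: PopulationSpec,
    reference: SurfaceMesh,
    z: np.ndarray,
    rng: np.random.Generator | None,
) -> HeadModel:
    """One head from latent vector z; optionally with vertex noise."""
    u = reference.vertices  # unit directions
    modes = harmonic_modes(u, spec.k_latent)  # (V, k)
    r_mean = float(np.prod(spec.base_radii[0] * np.asarray(spec.anisotropy)) ** (1 / 3))
    g = modes * (spec.mode_amplitudes / r_mean)  # (V, k), dimensionless
    shells = []
    for t_idx, tissue in enumerate(TISSUES):
        semi = spec.base_radii[t_idx] * np.asarray(spec.anisotropy)
        base = _ellipsoid_radius(u, semi)
        factor = 1.0 + g @ (spec.tissue_loadings[t_idx] * z)
        if np.any(factor <= 0):
            raise ValueError("latent draw produced nonpositive radius")
        verts = u * (base * factor)[:, None]
        if rng is not None and spec.vertex_noise_sd > 0:
            verts = verts + rng.normal(0.0, spec.vertex_noise_sd, verts.shape)
        shells.append(SurfaceMesh(verts, reference.triangles, tissue, np.zeros(3)))

    # fiducials on the noiseless scalp radial field, preserving exact CTF form
    semi_s = spec.base_radii[0] * np.asarray(spec.anisotropy)
    axes = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]])
    base_ax = _ellipsoid_radius(axes, semi_s)
    g_ax = harmonic_modes(axes, spec.k_latent) * (spec.mode_amplitudes / r_mean)
    load_s = spec.tissue_loadings[0] * z
    nas_r = base_ax[0] * (1.0 + g_ax[0] @ load_s)
    # symmetric part of the ear displacement; the antisymmetric part is a
    # lateral origin shift that CTF alignment absorbs
    ear_sym = 0.5 * (g_ax[1] + g_ax[2]) @ load_s
    ear_r = base_ax[1] * (1.0 + ear_sym)
    fid = Fiducials([nas_r, 0, 0], [0, ear_r, 0], [0, -ear_r, 0])
    return HeadModel(shells, fid, "ctf")


def make_template(spec: PopulationSpec) -> HeadModel:
    """The population mean head: nested anisotropic shells, zero latents."""
    reference = unit_sphere_mesh(spec.v_count)
    head = _build_head(spec, reference, np.zeros(spec.k_latent), None)
    if not check_nesting(head, n_rays=100).ok:
        raise ValueError("base radii violate nesting")
    return head


def generate_population(spec: PopulationSpec) -> SyntheticPopulation:
    """Draw a seeded population of nested heads with latent shape factors.

    Latents are standard normal; a head failing the nesting check (or
    producing a nonpositive radius) is rejected and resampled, keeping the
    latent distribution interpretable.  Same seed, same population.
    """
    rng = np.random.default_rng(spec.seed)
    reference = unit_sphere_mesh(spec.v_count)
    heads: list[HeadModel] = []
    latents = np.empty((spec.n_heads, spec.k_latent))
    n_rejected = 0
    while len(heads) < spec.n_heads:
        z = rng.standard_normal(spec.k_latent)
        try:
            head = _build_head(spec, reference, z, rng)
        except ValueError:
            n_rejected += 1
            continue
        if not check_nesting(head, n_rays=60).ok:
            n_rejected += 1
            continue
        latents[len(heads)] = z
        heads.append(head)
    return SyntheticPopulation(heads, latents, spec, n_rejected)


# ---------------------------------------------------------------------------
# Scalp-proxy samplers
# ---------------------------------------------------------------------------

def _ring_directions(n_points: int, theta_max: float) -> np.ndarray:
    """Quasi-regular ring-and-arc layout of exactly n_points directions on a cap."""
    if n_points == 1:
        return np.array([[0.0, 0.0, 1.0]])
    n_rings = max(1, int(round(np.sqrt(n_points / 2.0))))
    thetas = theta_max * (np.arange(n_rings) + 0.5) / n_rings
    weights = np.sin(thetas)
    counts = np.maximum(1, np.floor(n_points * weights / weights.sum()).astype(int))
    # largest-remainder top-up to the exact requested count
    while counts.sum() < n_points:
        frac = n_points * weights / weights.sum() - counts
        counts[int(np.argmax(frac))] += 1
    while counts.sum() > n_points:
        counts[int(np.argmax(counts))] -= 1
    dirs = []
    for i, (th, c) in enumerate(zip(thetas, counts)):
        az = 2 * np.pi * (np.arange(c) + 0.5 * (i % 2)) / c
        dirs.append(
            np.column_stack(
                [np.sin(th) * np.cos(az), np.sin(th) * np.sin(az),
                 np.full(c, np.cos(th))]
            )
        )
    return np.vstack(dirs)


def sample_scalp_proxy(
    head: HeadModel,
    mode: str = "photogrammetry",
    n_points: int = 150,
    noise_sd: float = 0.0,
    seed: int = 0,
    min_height: float = 35.0,
) -> ScalpProxy:
    """Sample a scalp proxy from a head's scalp surface.

    ``photogrammetry`` scatters points uniformly over the scalp above the
    ear-plane offset; ``electrodes`` lays out a deterministic quasi-regular
    ring-and-arc montage (21/64/343 points emulate 10-20/10-10/10-5
    densities).  Isotropic Gaussian noise of ``noise_sd`` mm is added to
    either.  Fiducials are copied from the head.
    """
    if mode not in ("photogrammetry", "electrodes"):
        raise ValueError(f"unknown proxy mode {mode!r}")
    rng = np.random.default_rng(seed)
    center = head.cortex_centroid()
    fid = head.fiducials

    def cast(dirs: np.ndarray) -> np.ndarray:
        d, _ = ray_mesh_intersect_many(head.scalp, center[None, :], dirs)
        ok = np.isfinite(d)
        un = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        return (center + d[:, None] * un)[ok]

    if mode == "photogrammetry":
        pts = np.empty((0, 3))
        for _ in range(200):
            raw = rng.standard_normal((4 * n_points, 3))
            raw[:, 2] = np.abs(raw[:, 2])  # upper hemisphere only
            cand = cast(raw)
            cand = cut_above_ears(cand, fid, min_height)
            pts = np.vstack([pts, cand])
            if len(pts) >= n_points:
                break
        if len(pts) < n_points:
            raise ValueError("could not sample enough scalp points above the cut")
        pts = pts[:n_points]
    else:
        # cap opening angle from the scalp extent above the height cut
        top = cast(np.array([[0.0, 0.0, 1.0]]))[0]
        theta_max = float(np.arccos(np.clip((min_height + 2.0) / top[2], -1, 1)))
        dirs = _ring_directions(4 * n_points, theta_max)
        cand = cast(dirs)
        cand = cut_above_ears(cand, fid, min_height)
        if len(cand) < n_points:
            raise ValueError("electrode layout does not fit above the cut")
        pts = decimate_pointcloud(cand, n_points)

    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    labels = [f"E{i+1:03d}" for i in range(len(pts))]
    return ScalpProxy(pts, fid, "electrodes" if mode == "electrodes" else
                      "photogrammetry", labels)
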