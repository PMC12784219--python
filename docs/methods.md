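# Methods

This note documents the models, numerical choices and limitations of
`pcawarp`, in the spirit of a methods appendix: what is computed, under which
assumptions, and what the tests do and do not demonstrate.

## Coordinate conventions and mesh representation

All coordinates are millimetres. Heads live in the CTF frame: origin at the
midpoint of the left/right pre-auricular points, x-axis toward the nasion,
ALS orientation (x anterior, y left, z superior), original head size. The
frame is constructed from the three fiducials as x̂ = unit(NAS − origin),
ẑ = unit(x̂ × (LPA − RPA)), ŷ = ẑ × x̂; this puts NAS exactly on +x and both
ears in the z = 0 plane, and is idempotent (re-aligning an aligned head is
the identity to 1e−9). Collinear fiducials are rejected as ill-posed.

Tissue boundaries are closed triangulated surfaces that are *star-shaped*
about an interior point: every ray from that point crosses the surface once.
All four shells of a head — and all heads of a population — share one
reference triangulation, obtained by projecting the vertices of an evenly
triangulated unit sphere along their directions onto each surface. This
shared parameterization is what makes vertex-wise correspondence, and hence a
coordinate-level PCA, meaningful.

The reference sphere uses the subdivided icosahedron when the requested
vertex count matches 10·4ⁿ + 2 (e.g. 642), and a Fibonacci lattice
triangulated by its convex hull otherwise (e.g. the database resolution
1922). Both are closed genus-0 meshes with exactly 2V − 4 triangles and
outward winding. Note the database literature sometimes quotes 3990 triangles
for V = 1922; a closed genus-0 surface with 1922 vertices has 3840, and this
package uses closed meshes throughout.

Ray-triangle intersection is Möller–Trumbore with a 1e−12 determinant cutoff;
coincident hits are resolved to the lowest triangle index, so all queries are
reproducible and equal the brute-force per-triangle scan (tested). For the
fitting inner loop, rays sharing one origin against star-shaped meshes are
accelerated by restricting each ray to the triangles incident to the few mesh
vertices whose directions are nearest the ray direction, with a full-scan
fallback for the rare unresolved ray; the result is identical to the full
scan, only cheaper (~30× at 642 vertices).

Scalp-proxy preprocessing follows field practice: cut 35 mm above the plane
spanned by NAS/LPA/RPA (superior normal; boundary points kept), optional
inward shift of electrode positions along outward normals (12 mm is the
usual correction for cap-mounted electrodes), and farthest-point decimation to ~150
points (seeded at the point farthest from the centroid, hence deterministic).

## The statistical shape model

A head is flattened to a vector of 12V + 9 coordinates in fixed order
(scalp, skull, CSF, cortex, then NAS, LPA, RPA). "Normalization" defaults to
centering only: all coordinates share mm units, and per-coordinate variance
scaling (available as `normalization="zscore"`) would inflate the influence
of low-variance coordinates. PCA is computed by thin SVD of the centered
n × D data matrix — no covariance matrix is ever formed, which for D ≈ 23k
and n of a few hundred is both faster and numerically better conditioned.
With centering, at most n − 1 components exist; training heads are
reconstructed exactly (to 1e−6 mm) when all components are used, and weights
of a known head are closed-form inner products by orthonormality.

One scalar weight per component is used everywhere. The weights are
reported in raw units but optimized in units of the singular values, so the
optimizer sees comparably scaled axes.

## Scalp-proxy fitting

The data term sums plain (unsquared) Euclidean distances between each proxy
point and its model correspondence; a squared variant exists behind a flag.
Two correspondence rules are provided:

- **vertex distance** — nearest scalp vertex (KD-tree; equals the brute-force
  scan). Meshing-dependent but cheap and differentiable almost everywhere.
- **shape difference** (default) — intersection of the ray from the mean
  cortex vertex through the proxy point with the scalp mesh. Approximately
  normal to the surface and invariant to retriangulation. Surface normals
  themselves are not used because they are unreliable on distorted
  intermediate meshes during optimization; the cortex-centroid ray is a
  robust stand-in. A ray that misses (non-star-shaped intermediate mesh)
  falls back to the nearest-vertex distance for that point and is counted in
  the result.

The non-intersection penalty g accumulates (T − d) over all inter-shell
vertex pairs closer than T (default 1 mm), computed exactly with a radius-T
KD-tree query. Unordered shell pairs are counted once; a double-counting
convention would only rescale the penalty weight λ (default 1, i.e. plain
addition). The penalty is active for both metrics and can be disabled with
λ = 0. g = 0 is equivalent to all inter-shell pairs being at least T apart.

Optimization starts from zero weights (the mean head). The default optimizer
is BFGS with numerical gradients (central step 1e−3 in scaled units) and one
restart from the best-seen iterate if the line search stalls; because
correspondences switch discretely, the objective is only piecewise smooth and
the best-seen iterate is returned. Reaching `max_iter` sets
`converged=False` but never raises. The alternative `optimizer="linear"`
alternates freezing the correspondences (nearest vertex, or the intersection
triangle with its barycentric coordinates — both linear in the weights) with
a small dense least-squares solve. On every problem we tested, the two land
in the same basin with data terms within a few percent; the linear mode is
two orders of magnitude faster and is what the batch evaluation sweeps use.
Both are deterministic given model, proxy and configuration.

Practical choice of the component count: 10–16 components balance accuracy
against overfitting; with many more components than the population's true
latent dimensionality, the fit chases the scalp proxy (error on the
proxy-covered scalp region drops) while the unseen inner surfaces worsen.
This overfitting direction is asserted by the acceptance tests.

## Thin-plate-spline baseline

The comparison baseline warps a template head to the proxy with a 3D TPS
(kernel U(r) = r). Correspondences are built exactly like the
shape-difference metric — template-scalp intersections of cortex-centroid
rays through the proxy points — so both individualization routes see the same
information. The TPS system enforces the usual side conditions (kernel
coefficients orthogonal to constants and linear functions), so an affine
correspondence yields zero bending energy and is recovered exactly. Default
regularization is 1e−6 times the median control spacing, which stabilizes
near-coplanar electrode layouts; at zero regularization the warp interpolates
the proxy exactly, which is precisely why adversarial or noisy proxies can
bend the inner shells unnaturally — the known failure mode the shape-model
approach avoids, and the reason the package reports (rather than repairs)
nesting violations of warped heads.

## Synthetic population generator

The generator emulates the *output conventions* of an MRI-segmentation
database: per head, four nested star-shaped shells on a shared triangulation,
CTF-aligned, with fiducials. Defaults: scalp/skull/CSF/cortex base radii
100/95/90/85 mm (5 mm gaps), per-axis anisotropy (1.0, 0.82, 0.95) for adult
proportions, 8 latent factors with RMS scalp amplitudes 3.0·0.85^f mm
(≈5 mm total RMS scalp variation, adult-scale inter-individual variability),
tissue loadings (1.0, 0.92, 0.88, 0.82) so every factor deforms all shells
coherently but with decreasing gain toward the cortex, and 0.3 mm isotropic
vertex noise emulating segmentation/meshing jitter.

Latent factors multiply the radial field with smooth directional patterns —
real spherical harmonics of degrees 1–3 (unit RMS, deterministic order).
Construction is *exactly linear* in the latent vector, including the
fiducials: NAS moves with the anterior scalp radius along +x, the ears move
with the symmetric part of the lateral scalp radius (the antisymmetric part
corresponds to a lateral origin shift, which is exactly what fiducial-based
CTF alignment removes from a real head). Consequently a noiseless population
has sample covariance of rank exactly k — which is what makes the latent
recovery and rank tests sharp. Heads violating nesting (or driving a radius
nonpositive) are rejected and resampled, keeping the latent law standard
normal; rejections are counted and are rare at the default amplitudes.

Proxy samplers: photogrammetry mode scatters seeded uniform directions over
the upper scalp; electrode mode lays out deterministic rings-and-arcs over
the cap above the 35 mm plane (exact requested counts; 21/64/343 emulate
10-20/10-10/10-5 densities), both with optional isotropic noise.

What the generator does *not* emulate: gyri/sulci and real cortical
geometry, skull-base/jaw anatomy, demographic covariates, asymmetric
non-Gaussian shape variation, and any segmentation bias. Tests passing on
this population therefore demonstrate the *machinery* (correspondence,
projection, optimization, statistics) and the population-coupling principle,
not anatomical accuracy on real heads.

## Evaluation harness

Shape errors are reported per tissue as median/mean/sd under both metrics;
vertex distance requires identical topology, shape difference (per truth
vertex, along the ray from the truth cortex centroid to the fitted surface)
does not. Per-vertex error maps cap displayed values at 11 mm while keeping
the raw values.

Residual variance RV = Σ(x − x̂)²/Σx² is the fitting error throughout the
dipole harness; it is scale-invariant and 1 for a zero prediction.

The forward model is the closed-form surface potential of a current dipole
in a homogeneous conducting sphere with insulating exterior, derived by
summing the classical Legendre series with generating functions (the f → 0
limit reduces to the central-dipole result 3p·r̂/4πσR²); it matches a
400-term series oracle to 1e−14 and is average-referenced. The four
conductivities carried as configuration constants (scalp 0.465, skull 0.01,
CSF 1.65, cortex 0.201 S/m) are the standard values for four-shell models;
the single-sphere harness itself uses one conductivity, and any object
implementing `gain(position)`/`contains(position)` can replace it. Realistic
BEM/FEM solvers are deliberately out of scope.

Dipole fitting is the standard two-stage routine: a linear search computing
the RV-optimal moment (least squares against the 3-column gain) at every
point of a 10 mm axis-aligned lattice inside the cortex mesh (interior test
by ray parity), ties broken by lowest grid index and rank-deficient gains
skipped and counted; then a nonlinear Nelder–Mead refinement of the position
with the moment re-solved per step, constrained to the source compartment by
objective penalty, returning the better of init and refined (so RV never
increases) and flagging aborted fits with RV = 1. SNR for noise injection is
a power ratio by default (amplitude ratio behind a flag, since the convention
is often left unstated). Model comparisons use one-sided Wilcoxon
signed-rank tests over all ordered model pairs with Benjamini–Hochberg
correction; observations with an aborted fit should be discarded jointly
across all compared models.

## Problem sizes used by the tests and the acceptance script

The synthetic study runs at reduced resolution: 60 heads, 8 latent factors,
642-vertex shells, 0.3 mm vertex noise; leave-one-out evaluation over 12–15
folds and proxy-size trends over 8–10 sampling seeds, with noise-free
343-point electrode proxies unless stated. These sizes give stable medians
(results change by ≲20% across seeds) while keeping a full run to tens of
seconds. The batch sweeps use the frozen-correspondence linear optimizer;
BFGS/linear agreement is asserted separately on a smaller problem.

## Known limitations

- The shape model is linear; real cross-tissue shape dependence is not, and
  skull/inferior regions are known to be the hardest to predict from scalp
  data.
- The shape-difference metric degrades if an intermediate mesh stops being
  star-shaped about the cortex centroid (handled by fallback, reported, but
  a fit dominated by fallbacks deserves scrutiny).
- The penalty is vertex-based; two shells could in principle interpenetrate
  between vertices without triggering it at coarse resolutions.
- The single-sphere forward model exercises the fitting machinery only;
  localization numbers from it do not transfer to realistic four-shell
  conductor geometry.
- OBJ/PLY/STL text round-trips preserve coordinates to ~1e−6 mm (format
  float formatting), not bitwise.
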