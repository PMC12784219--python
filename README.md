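# pcawarp

Individualized four-shell M/EEG head models from scalp proxies via a PCA
statistical shape model.

## The problem

Accurate EEG/MEG source localization needs a volume-conductor model of the
subject's head — in boundary-element (BEM) practice, four nested tissue
surfaces (scalp, skull, CSF, cortex). The gold standard derives these from an
individual MRI, which most EEG studies do not have. The common fallbacks are a
template anatomy (ICBM-152, Colin27) or a template warped to the measured
sensor positions with a thin-plate spline, both of which can misplace sources
by centimetres.

`pcawarp` takes a third route: learn, from a population of heads meshed on a
*shared triangulation* in a common fiducial-based (CTF) coordinate frame, a
low-dimensional statistical shape model, then estimate an individual's full
head geometry from nothing but a *scalp proxy* — a photogrammetry point cloud
or digitized electrode positions. Because the shape components couple all four
tissues, fitting the scalp alone also predicts the skull, CSF and cortex
surfaces and the fiducials.

## The model

Each head with V vertices per shell is flattened into a vector of
`12 V + 9` coordinates (four shells, then NAS/LPA/RPA); at the database
resolution V = 1922 that is 23064 mesh coordinates, 23073 in total. A PCA of
the centered coordinate matrix gives orthonormal components `PC_j`; a new head
is expressed as

    v(w) = mean + Σ_j w_j · PC_j

and the weights are estimated from a scalp proxy `{p_k}` by minimizing

    Σ_k ‖ p_k − s_k(w) ‖  +  λ · g(w)

where `s_k(w)` is either the scalp vertex closest to `p_k` (*vertex
distance*) or the intersection of the ray from the cortex centroid through
`p_k` with the scalp mesh (*shape difference* — approximately normal to the
surface and independent of the meshing). The penalty
`g = Σ max(0, T − d)` over all inter-shell vertex pairs closer than
T = 1 mm keeps the fitted shells from intersecting, so the result remains
usable for BEM. The minimization is quasi-Newton (BFGS) on
singular-value-scaled weights with correspondences recomputed at every step; a
fast alternating frozen-correspondence linear solver is available as
`optimizer="linear"`.

The package also provides the classical comparison baseline (thin-plate-spline
warp of a template to the proxy, applied to all shells), a synthetic
population generator with controlled latent shape factors, and an
equivalent-current-dipole fitting harness (residual-variance grid search plus
nonlinear refinement over an analytic conducting-sphere forward model) for
end-to-end localization experiments.

## Worked example

```python
import numpy as np
from pcawarp import (PopulationSpec, generate_population, fit_shape_model,
                     FitConfig, fit_pcawarp, sample_scalp_proxy,
                     shape_error_report, reconstruct)

# a small synthetic study: 20 heads, 4 latent shape factors
spec = PopulationSpec(n_heads=20, k_latent=4, v_count=162,
                      vertex_noise_sd=0.2, seed=11)
pop = generate_population(spec)

truth = pop.heads[0]                      # held-out subject
model = fit_shape_model(pop.heads[1:])    # shape model never sees it

# digitized electrode positions as the scalp proxy
proxy = sample_scalp_proxy(truth, "electrodes", n_points=64, seed=3)
fit = fit_pcawarp(model, proxy, FitConfig(n_pcs=4, optimizer="linear"))

report = shape_error_report(fit.head, truth)
baseline = shape_error_report(reconstruct(model, []), truth)
print(f"proxy points: {proxy.n_points}, data term: {fit.objective:.2f} mm")
for tissue in ("scalp", "skull", "csf", "cortex"):
    got = report.per_tissue["shape_difference"][tissue]["median"]
    base = baseline.per_tissue["shape_difference"][tissue]["median"]
    print(f"{tissue:>6}: median shape difference {got:5.2f} mm "
          f"(mean-head baseline {base:5.2f} mm)")
```

Output:

```
proxy points: 64, data term: 8.04 mm
 scalp: median shape difference  0.15 mm (mean-head baseline  4.03 mm)
 skull: median shape difference  0.16 mm (mean-head baseline  3.56 mm)
   csf: median shape difference  0.14 mm (mean-head baseline  3.10 mm)
cortex: median shape difference  0.14 mm (mean-head baseline  2.78 mm)
```

Fitting 64 scalp points with four components reduces the error of every
shell — including the cortex, which was never measured — from millimetres to
fractions of a millimetre relative to simply using the population mean head.

The same pipeline is scriptable from the shell:

```sh
pcawarp synth --n-heads 20 --v-count 162 --seed 11 --out pop/
pcawarp build-db --heads pop/ --out model.npz
pcawarp fit --model model.npz --proxy electrodes.csv \
            --metric shape_difference --n-pcs 16 --out fitted/ --report fit.json
pcawarp baseline-tps --template pop/head000 --proxy electrodes.csv --out warped/
pcawarp evaluate --truth pop/head000 --fitted fitted/ --out report.json
pcawarp sweep --population pop/ --pcs 1,5,10 --proxies 21,64 --out table.csv
```

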