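# kinedelta

Bias-corrected nanoscale distances between fluorophore-labeled protein
ensembles, built for intra-kinetochore architecture mapping.

## The problem

Dual-color 3D localization microscopy measures, per kinetochore, a
displacement vector **v** between the centroids of two labeled protein
populations. The obvious distance estimate, Δ_3D = |**v**|, is
systematically too large: a norm cannot be negative, so localization
noise — anisotropic, because the point-spread function is ~2× wider
along the optical axis — inflates it. For separations comparable to the
noise (tens of nm, exactly the scale of kinetochore substructure), the
bias can exceed the true distance itself.

`kinedelta` infers the true separation Δ_EC under the generative model

    v_i = μ·u_i + ε_i,   u_i ~ Uniform(S²),
    ε_i ~ N(0, diag(τ_xy², τ_xy², τ_z²)),

by MCMC on the orientation-marginalized posterior, reporting the
posterior mean ± SD and a 95% highest-density interval for μ along with
noise estimates and convergence diagnostics (R̂, ESS). Around the
estimator it provides:

- **spot_io** — spot-table CSV I/O, per-cell chromatic correction
  (cell-average inter-channel displacement forced to zero per axis),
  channel pairing into displacement vectors, intensity normalization;
- **delta_stats** — collinearity z-tests for 3-marker triangles,
  condition comparisons, distance differences, nematic order
  N = Δ_EC/Δ_structural and its hinge-angle constraint curves,
  effective cell number (inverse Simpson index), disordered-region
  path lengths;
- **ensemble_sim** — a forward simulator of a microtubule-bound
  kinetochore (hexagonal K-fiber lattice, hinged two-arm NDC80 modules,
  MIS12 and CenpC layers) with grid fitting of the NDC80 hinge and
  elevation angles to measured distance triangles;
- **synthetic_data** — ground-truth-known generators for every pipeline
  stage;
- a `kinedelta` CLI wiring the pieces together.

## Worked example

```python
import numpy as np
from kinedelta import (
    SyntheticSpec, generate_pairs, chromatic_correct, pair_displacements,
    fit_distance, McmcConfig, DistanceEstimate, TriangleMeasurement,
    collinearity_test,
)

# two-color experiment with known truth: separation 50 nm, per-spot
# localization SDs 21 nm lateral / 42 nm axial
spec = SyntheticSpec(mu=50.0, sigma_xy=21.0, sigma_z=42.0,
                     n_cells=20, kts_per_cell=50, seed=7)
table = generate_pairs(spec)
disp = pair_displacements(chromatic_correct(table, "568"), "568", "488")
print(f"n = {len(disp)}, raw mean distance = {disp.norms().mean():.1f} nm")

post = fit_distance(disp, mcmc=McmcConfig(chains=2, iterations=3000, seed=1))
print(f"inferred separation = {post.mu_mean:.1f} +/- {post.mu_sd:.1f} nm "
      f"(95% HPD {post.mu_ci[0]:.1f}-{post.mu_ci[1]:.1f})")
print(f"noise estimates: lateral {post.tau_xy_mean:.1f} nm, axial {post.tau_z_mean:.1f} nm")

# are three measured pairwise distances compatible with collinear markers?
tri = TriangleMeasurement(
    ab=DistanceEstimate(43.5, 2.3), bc=DistanceEstimate(48.4, 3.1),
    ac=DistanceEstimate(81.9, 2.9),
)
z, p = collinearity_test(tri)
print(f"collinearity: z = {z:.2f}, one-sided p = {p:.3f}")
```

Output:

```
n = 1000, raw mean distance = 77.8 nm
inferred separation = 49.5 +/- 2.4 nm (95% HPD 44.6-53.9)
noise estimates: lateral 27.4 nm, axial 56.2 nm
collinearity: z = 2.07, one-sided p = 0.019
```

The raw distance overestimates the truth by 56% (77.8 vs 50 nm); the
corrected posterior covers it tightly. The triangle test rejects
collinearity at p = 0.019: the first marker lies off the axis defined by
the other two — the kind of offset the ensemble simulator then explains
geometrically (a broad transverse disc whose finite-count centroid
wobbles off-axis).

The same pipeline from the shell:

```sh
kinedelta synth pairs --mu 50 --sxy 21 --sz 42 --n-cells 20 --kts 50 --seed 7 spots.csv
kinedelta pair --ref 568 --query 488 --correct-chromatic spots.csv disp.csv
kinedelta bedca --chains 4 --iters 10000 --seed 1 disp.csv summary.json
kinedelta collinearity --ab 43.5,2.3 --bc 48.4,3.1 --ac 81.9,2.9
```

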