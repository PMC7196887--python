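# Methods

## The measurement problem

Two-color fluorescence localization of kinetochore proteins yields, per
kinetochore, a 3D displacement vector **v** between the centroids of two
labeled protein ensembles. The Euclidean norm Δ_3D = |**v**| is a biased
estimate of the true separation Δ: noise can only inflate a norm, never
produce a negative one, so Δ_3D overestimates Δ — severely when Δ is
comparable to the localization error, and the error is anisotropic
(the point-spread function is roughly twice as wide along the optical
axis as laterally). `kinedelta` infers the separation by Bayesian MCMC
under an explicit generative model, and packages the downstream
statistics and an ensemble-architecture simulator used to interpret the
inferred distances.

## Generative model and inference (`bedca`)

Model, per kinetochore i:

    v_i = mu * u_i + eps_i
    u_i ~ Uniform(S²)
    eps_i ~ N(0, diag(tau_xy², tau_xy², tau_z²))

with mu ≥ 0 the true separation, u_i a latent 3D orientation, and
(tau_xy, tau_z) the lateral/axial SDs of the *displacement* noise (each
contributing spot carries per-spot SD sigma, so tau = sigma·√2).
Orientations are taken uniform on the sphere: kinetochores tumble freely
in the imaging frame. Noise parameters are shared across a dataset (one
imaging session); they can be fixed from a same-epitope calibration
(`NoiseModel(fixed=True)`), where the two labels mark the same protein
and mu = 0 by construction.

Priors: mu ~ Uniform(0, 500 nm); tau² ~ Inverse-Gamma(2, 1000 nm²)
(prior mean 1000 nm², i.e. tau ≈ 32 nm, the order of a typical
localization error; weakly informative, configurable via `PriorConfig`).

**Marginal likelihood.** The orientation integrates out semi-analytically:
the lateral azimuth gives a modified-Bessel factor I0, leaving a 1D
integral over the polar cosine evaluated by Gauss–Legendre quadrature.
`likelihood_point` uses order-doubling to a relative tolerance of 1e-10
and serves as the reference; the sampler uses a fixed order-48 rule
(cross-checked against the reference in the test suite) with a
numba-compiled kernel where available (i0e via the Abramowitz–Stegun
rational approximations, relative error ~2e-7, far below the quadrature
truncation error).

**Sampler.** Adaptive Metropolis (Haario-style) jointly on
(mu, log tau_xy², log tau_z²) against the orientation-marginalized
posterior: the proposal covariance is learned during burn-in (frozen
afterwards) with an acceptance-tuned global scale, and mu is reflected
into [0, mu_max]. Joint marginal updates matter here for two reasons,
both observed directly while benchmarking one-at-a-time Gibbs variants:
(i) mu and the latent orientations are so strongly coupled that the
conjugate conditional of mu given {u_i} is several times narrower than
its marginal posterior, freezing the chain; (ii) mu and tau_xy trade off
along a likelihood ridge (both can absorb lateral spread), which the
learned covariance aligns with. The conjugate conditional pieces of the
un-marginalized model — truncated-normal mu | u, inverse-gamma tau² | u,
and the exact Fisher–Bingham orientation draw — remain in the module and
are verified against closed forms by KS and moment tests.

Defaults: 4 chains, 10 000 iterations, 50% burn-in, per-chain seeds
spawned from a master seed. The test suite and validation studies use
2 chains × 3000–4000 iterations, which the diagnostics show is ample for
the problem sizes studied (n ≈ 1000). Convergence is summarized by
split-R̂ and effective sample size (via ArviZ) for the free scalar
parameters; R̂ > 1.05 on any of them flags the summary as non-converged.

**Reporting.** The point estimate is the posterior mean of mu and the
"±" its posterior SD. The interval is a 95% highest-posterior-density
interval rather than an equal-tailed one: mu is bounded at 0, and an
equal-tailed interval can never contain the boundary, which would make
coverage statements meaningless for small separations. Two boundary
conventions follow from the same logic: an HPD window anchored at the
smallest draw is truncated to 0, and when the boundary-anchored window
is within 5% of the shortest window (ties are ubiquitous on flat
posteriors) the boundary-anchored one is reported. A `boundary_flag`
marks noise-dominated fits (mu_mean < mu_sd).

**Identifiability limit.** At n = 1000 and tau = (42, 85) nm, the
profile log-likelihood is flat (within ~0.5 nats) over mu ∈ [0, ~35] nm:
datasets of this size genuinely cannot resolve separations much below
the lateral noise scale, and the posterior honestly spans that range.
Validation therefore asserts interval coverage and bias reduction, not
pinpoint recovery, in this regime.

## Statistics on distance estimates (`delta_stats`)

All tests are normal-theory z-tests on (mean, sd) pairs, the sd being
the posterior SD from the inference step.

- **Collinearity.** For markers A–B–C with AC the candidate long side,
  z = |d_AB + d_BC − d_AC| / √(sd²_AB + sd²_BC + sd²_AC), with a
  one-sided upper-tail p. The absolute value makes the statistic
  insensitive to the sign of the excess (a negative excess arises when
  the middle marker's estimate is noisy), and one-sidedness reflects
  that only a positive excess indicates an off-axis marker.
- **Condition comparisons** are two-sided; **differences** propagate
  uncertainty in quadrature.
- **Nematic order.** For a population of identical two-arm rods,
  the measured ensemble separation between the rod ends is the
  single-rod end-to-end distance scaled by the alignment of the
  population: N = Δ_EC / Δ_structural, N = 1 aligned, N = 0 isotropic.
  `nematic_hinge_curve` maps a measured Δ_EC onto the order required at
  each hinge angle, with d(θ) from the law of cosines (arms 16/35 nm by
  default — the unique pair giving 51 nm straight and 19 nm folded) and
  a delta-method 95% band (±1.96 sd scaled by d(θ)).
- **Effective cell number** is the inverse Simpson index of per-cell
  kinetochore counts — the number of equally contributing cells that
  would give the same concentration of observations; it guards pooled
  estimates against pseudo-replication.
- **Disordered path length** multiplies residue count by a contour
  scale, default 64/300 ≈ 0.213 nm/residue (maximally extended chain);
  the scale is exposed since polymer models differ.

## Ensemble simulator (`ensemble_sim`)

One kinetochore = `n_microtubules` (20) parallel microtubules (radius
12.5 nm) on a hexagonal lattice at 70 nm pitch, each with
`ndc80_per_mt` (12) NDC80 modules. A module attaches at a uniformly
random azimuth on its microtubule surface with Gaussian axial spread
(10 nm); its short arm (16 nm, head-to-loop) rises at the elevation
angle from the inward fiber axis toward the tilt azimuth; the long arm
(35 nm, loop-to-C) continues at the hinge angle. The bend lies in the
axial plane of the arm: hinge > 180° rotates the long arm back toward
the fiber axis so the complex runs nearly parallel to the microtubule
(the conformation EM shows for lattice-bound NDC80), hinge < 180° bends
it away; a Gaussian dihedral wobble about the short arm is available
(`dihedral_sd`, default 0). A uniform-dihedral variant was evaluated
and rejected: it predicts a 44.5 nm Ndc80(C)–Ndc80(N) centroid distance
at the published angles versus the measured 48.4 nm, which the in-plane
convention reproduces. Both hinge and elevation carry 10° Gaussian
fluctuations per module by default ("moderate flexibility"). Nnf1 sits
10 nm beyond Ndc80(C) along the module axis. CenpC is a transverse
Gaussian disc (SD 120 nm) of `cenpc_count` (20) molecules at a fixed
axial depth (72.5 nm inward of the attachment plane); the depth and
count were calibrated once so that, at the published best-fit angles,
the simulated CenpC–Ndc80(C) and CenpC–Ndc80(N) centroid distances
match the measured 43.5/81.9 nm — the analogue of fixing supplementary
structural parameters from independent data.

The finite CenpC count is the mechanism behind the measured
non-collinearity: a per-kinetochore centroid of 20 molecules with
120 nm transverse SD wobbles ~27 nm off-axis, inflating the two CenpC
distances relative to the axial geometry by just the measured ~10 nm
excess. The NDC80 markers, pooled over ~240 modules, stay effectively
on-axis.

**Angle fitting.** `fit_angles` grid-searches hinge ∈ [180°, 230°] and
elevation ∈ [0°, 45°] (1° steps by default), minimizing
Σ_sides ((sim_mean − obs_mean)/obs_sd)² with common random numbers: all
random variates are drawn once and re-posed at every grid point, so the
objective surface is a smooth deterministic function of the angles.
Uncertainty is the SD of the argmin under bootstrap resampling of
kinetochores.

*Identifiability.* Azimuthal symmetry implies every marker centroid lies
on the fiber axis (up to finite-count wobble), so the three side means
constrain the two angles only through the module's axial projection
a·cos(e) + b·cos(e − (θ−180°)) — an exact ridge. The fit therefore
carries a weak Gaussian penalty on the elevation angle, default
(25 ± 10)°, the mid-range of microtubule-to-NDC80 tilt angles seen in
EM reconstructions (`elevation_prior=None` disables it). When the data
pin the ridge sharply (e.g. fitting the simulator's own output, whose
side SEMs are tiny), the penalty is negligible and recovery is exact;
on real-scale uncertainties the penalty selects a point on the ridge
and a degenerate-ridge warning plus inflated bootstrap SDs report the
flat direction honestly.

**Order vs fluctuation.** `order_vs_fluctuation` applies a common SD to
both loop angles (hinge and elevation), reporting the population
nematic order |mean unit C→N vector| and the principal centroid
distances. At zero fluctuation in a straight axial configuration N = 1;
N decreases monotonically and is < 0.05 by 120° SD. The identity
N = (axial centroid span)/(structural end-to-end) holds to Monte Carlo
error whenever both ends share the attachment distribution, which is
the bridge between the simulator and the N = Δ_EC/Δ_structural formula
used on measurements.

## Synthetic data (`synthetic_data`)

Generators emulate the statistical structure of the experiments with
known ground truth: fixed true separation (or a two-component mixture),
uniform random orientation per kinetochore, independent anisotropic
per-spot noise (displacement noise tau = sigma·√2), per-cell chromatic
offsets (fixed per channel plus optional per-cell jitter), and rigid
three-marker triangles with optional per-vertex ensemble blur that
reproduces centroid-level collinearity violations. Defaults (20 cells ×
50 kinetochores, sigma_xy = 21 nm, sigma_z = 42 nm, mu = 50 nm) mirror
the scale of a single imaging experiment. What the generators do *not*
emulate: spot-detection failures, sister-pair mis-assignment,
non-Gaussian noise tails, depth-dependent aberrations, and intensity
bleed-through — so green tests certify the inference machinery, not
robustness to those upstream artifacts.

## Chromatic correction and pairing (`spot_io`)

Correction is per cell and per channel (against a chosen reference):
the cell-mean per-axis displacement over kinetochores with both
channels is subtracted from the non-reference channel, making per-cell
mean displacements exactly zero (to 1e-9 nm in tests) on each axis.
It is idempotent, translation-invariant in the downstream displacement
set, and skips (with a warning) cells lacking paired reference spots.
Kinetochores missing a channel are dropped, never imputed; an optional
boolean `excluded` column honors upstream quality flags. CSV round
trips are bit-exact (shortest-round-trip float repr on write,
round-trip float parsing on read).

## Numerical and degenerate-input choices

- Quadrature orders: 48 (sampler), adaptive to 1e-10 (reference);
  orientation inverse-CDF grid 128 points.
- All-zero displacement sets are rejected; n < 10 warns (inference) or
  errors (moment initialization).
- Equal-arm fully folded hinge (d = 0) points are flagged undefined in
  hinge curves rather than propagating infinities.
- Every stochastic routine takes a seed; per-chain and per-kinetochore
  streams are spawned from it, so identical configurations reproduce
  byte-identical results.

## Validation problem sizes

The shipped validation suite runs BEDCA recovery at n = 1000
displacements (three noise regimes × five replicates, 2 chains × 3000
iterations), the angle fit at 200 kinetochores per grid point with a
2.5° self-consistency grid and the default 1° grid for the measured
triangle, and distributional checks at 2×10⁵ Monte Carlo draws. These
sizes were chosen to exercise each claim at the scale of one real
experiment while keeping the full suite in the minutes range.

## Known limitations

- The inference model assumes a single mu per dataset; mixtures must be
  split by label first (the generator produces labeled mixtures for
  exactly this workflow).
- Orientation-uniformity is an assumption; sister-axis-informed
  orientation priors are a natural extension and not implemented.
- The hinge/elevation pair is set-identified from one triangle (see
  above); reported point estimates depend on the documented elevation
  prior, and the bootstrap SDs/degeneracy warning should always be
  inspected alongside them.
- The simulator's copy numbers and CenpC distribution are effective
  parameters calibrated to printed measurements, not molecular counts.
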