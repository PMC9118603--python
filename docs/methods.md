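# Methods

## Model

The response is the vector of direct survey estimates of a prevalence
for every domain of a full cross-classification — district (nested in
division) × residence × age group × sex — on the square-root scale:

    ŷ = Xβ + Σᵢ Z⁽ⁱ⁾ v⁽ⁱ⁾ + e,    e ~ N(0, Σ),    Σ = diag(σ²ₑ,d).

Assumptions: the sampling errors are independent Gaussian with *known*
variances (the classical area-level/Fay–Herriot assumption); the sqrt
transform makes the Gaussian approximation and the known-variance
treatment tenable for proportions; all structure beyond the fixed
main effects is carried by additive random-effect components.

Each component is defined by a varying factor V with d levels (unknown
scalar or diagonal covariance V) and a grouping factor A with l levels
(known precision Q_A), giving an effect vector of length q = d·l with
covariance A ⊗ V, ordered V-level-within-A-level so the precision is
Q_A ⊗ V⁻¹.  The catalogue (name: V / structure / A):

| name          | V          | structure | A                          | params | q      |
|---------------|------------|-----------|----------------------------|--------|--------|
| RES_DIST      | residence  | diagonal  | district                   | 2      | 2L     |
| RES_DIST_AGE  | residence  | diagonal  | district×age               | 2      | 2·L·A  |
| RES_DIST_SEX  | residence  | diagonal  | district×sex               | 2      | 2·L·2  |
| AGE_DIST      | age        | diagonal  | district                   | A      | A·L    |
| SP_DIST       | 1          | scalar    | district (ICAR)            | 1      | L      |
| WN_DIV        | 1          | scalar    | division×res×age×sex       | 1      | —      |
| WN_DIST       | 1          | scalar    | district×res×age×sex       | 1      | D      |

(L districts, A age groups; on the 64-district lattice with 5 age
groups the effect counts are 128, 640, 256, 320, 64, 160 and 1280.
Note the district×sex residence component has 2·64·2 = 256 effects by
q = d·l.)  The per-indicator defaults drop RES_DIST for stunting and
SP_DIST for wasting; underweight keeps all seven.  Diagonal-V
components give rural and urban domains separate variance parameters;
full-covariance V (correlated age effects) is out of scope.

The spatial precision is the unscaled intrinsic CAR, Q_A = D_w − W
(graph Laplacian of the district adjacency): symmetric PSD, zero row
sums, rank l−1 on a connected graph.  No propriety parameter is used;
identification comes from a sum-to-zero constraint imposed by
re-centring the spatial effects after every Gibbs draw and dropping one
degree of freedom (l_eff = l−1) in its variance update.  Disconnected
graphs are rejected rather than patched, with the components listed.
Polygon inputs are converted to adjacency by queen contiguity; an
edge-list CSV overrides it.

## Variance smoothing

The sqrt transform uses the delta method, SE′ = SE/(2√p̂), which is
undefined at p̂ = 0 and degenerate at p̂ ∈ {0, 1}; such domains are
flagged missing rather than patched with continuity corrections.  The
GVF is ordinary least squares of log SE′² on log n, fitted separately
for rural and urban (their SE levels differ systematically), requiring
at least 10 usable rows per stratum.  Predictions replace the SEs of
*all* domains — the model treats sampling variances as known, so a
single smooth function of n per stratum is used wholesale, and every
Σ diagonal entry is strictly positive, including for degenerate
domains.  The covariate set (sample size only) is the classical
sample-size-driven GVF form; it matches the variance-stabilised scale,
where the binomial variance is approximately deff/(4n) regardless of
the estimate.  Alternative covariates can be added by fitting a
different design in `fit_gvf`'s place; the transform itself has no
variants (no arcsine/logit in this version).

## Gibbs sampler

Systematic scan over β | ·, each v⁽ⁱ⁾ | ·, each variance | ·, all
exactly conjugate.  β has a flat improper prior; its full conditional
is N((X′Σ⁻¹X)⁻¹X′Σ⁻¹r, (X′Σ⁻¹X)⁻¹) with r the response minus all
random effects.  Because every incidence matrix has exactly one 1 per
row, Z′Σ⁻¹Z is diagonal, so exchangeable-component updates are O(q);
only the spatial component needs a dense l×l Cholesky per iteration.
Variance parameters get inverse-gamma(0.001, 0.001) priors by default
(overridable per component): vague but proper, conjugate for the Gibbs
update σ²ₖ ~ IG(a₀ + l_eff/2, b₀ + u′ₖ Q_A uₖ/2).

Numerical choices: initialisation at the GLS fit ignoring random
effects, v = 0, σ² = 0.01 (cheap and deterministic); per-chain RNG
streams spawned from the master seed, so runs are bit-reproducible;
defaults 3 chains × 5000 iterations with 2500 burn-in and no thinning;
split R-hat (threshold 1.05) and bulk ESS computed via arviz; a
non-finite state aborts with the iteration index.  Fixed-variance mode
(`fixed_variances` in `SamplerConfig`) pins variance parameters, which
reduces the model to a Gaussian linear system with a closed-form
posterior — the basis of the oracle tests.

WAIC is −2(lppd − p_waic) with lppd = Σ_d log mean_s N(y_d | η_d^(s),
Σ_dd) and p_waic the per-domain variance of the pointwise
log-likelihood; DIC is D̄ + p_D with p_D = D̄ − D(η̄).  Both use only the
stored η draws and the known Σ.

## Prediction and aggregation

Draws of η are clipped to [0, 1] and squared; the point estimate is
the posterior mean of the *squared* draws — exactly mean(s)² + var(s),
the bias correction relative to squaring the posterior mean — and the
SE is the posterior sd of s².  The clip frequency is reported as a
model-health metric.  Aggregation is the weighted mean of prevalence
draws within each margin cell, draw by draw, with population weights;
two-path consistency (detailed → division → national equals detailed →
national) then holds to machine precision, and no benchmarking
constraint to the direct national estimate is applied.  Equal weights
are an explicit fallback for weightless runs.  The bivariate map
classification cuts estimates and SEs at their empirical terciles,
class (1,1) being low-estimate/high-accuracy; all-equal inputs are
flagged degenerate.

Model assessment uses RB, ARB, RRSE and the CV ratio as unweighted
means over margin cells (a weight vector is accepted), with cells
excluded — and counted — when the direct estimate or SE is zero.
Direct margin estimates aggregate domain estimates by weighted mean
with independence-based SEs.

## Synthetic generator

The generator emulates the inputs of a national cluster survey:

* Truth on the sqrt scale, s = Xβ + ΣZ⁽ⁱ⁾v⁽ⁱ⁾, clipped to
  [√zero_floor, 1] (zero_floor 10⁻⁴), squared to prevalence.  Effects
  are drawn from their component distributions; the spatial effect from
  the ICAR's proper part via eigendecomposition (sum-to-zero exact).
* Default magnitudes are the published posterior summaries of a
  stunting model (intercept 0.396; age contrasts up to 0.169; urban
  −0.091; component spreads 0.011–0.118).  The catalogued component
  values are interpreted as *standard deviations* on the sqrt scale:
  read as variances they would imply district-level sqrt-scale sds of
  ~0.27 and prevalence spreads far wider than any national survey
  exhibits, while as sds they give realistic 15–45% district ranges.
  `table_scale="variance"` overrides this reading.
* Sampling noise: n per domain uniform in a residence-specific range
  (rural 60–200, urban 20–60 — urban domains are smaller and noisier),
  a design effect deff = 1.5 deflating the effective binomial size,
  estimates k/n_eff with SE √(p̂(1−p̂)·deff/n) — zero at degenerate
  p̂ ∈ {0, 1}, which small urban samples produce by design.
* Weights: log-normal district totals, urban share uniform on
  (0.1, 0.5), near-uniform Dirichlet age/sex shares.

What it does **not** emulate: cluster/stratum microdata (so no true
design-based variance estimation), informative sampling, measurement
error in anthropometry, or missing domains.  Passing tests therefore
certify the estimation machinery under a correctly specified sampling
model, not robustness to design misspecification in real surveys.

## Problem sizes used in tests and the acceptance script

Oracle checks run on 20–24-domain toys with fixed variances; the
parameter-recovery experiment uses a 12-district, 2-division,
2-age lattice (96 domains), 50 replicates, 2 chains × 800 iterations —
enough for stable coverage proportions at the replicate count used; the
end-to-end run uses the full 64-district lattice (1280 domains) with
2 chains × 2000 iterations.  These sizes were chosen so the entire
suite re-runs in a few minutes on a single CPU while keeping Monte
Carlo error well below the tolerances tested.

## Known limitations

* No full-covariance V (correlated age effects), proper-CAR/Leroux
  spatial variants, HMC backend, or multivariate (multi-indicator)
  model.
* The known-Σ assumption ignores uncertainty in the GVF fit itself.
* Coverage calibration is demonstrated for fixed effects; variance
  parameters with few grouping levels are only weakly identified and
  their posteriors depend visibly on the inverse-gamma prior.
* Unbalanced lattices (structurally missing domains) are not supported;
  missing data should be handled upstream.
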