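# Methods

## The model

`wardmap` fits Bayesian geoadditive Poisson regressions for small-area
(ward-level) disease mapping.  For ward *i* = 1, …, *S* with event count
*y\_i* and population *n\_i*,

    y_i | eta_i ~ Poisson(mu_i),      mu_i = exp(eta_i + o_i),
    eta_i = alpha + x_i' beta + sum_j f_j(x_ij) + f_spat(s_i),

with offset *o\_i* = log(*n\_i*/1000), so that `exp(alpha + x'beta)` is an
events-per-1000-population rate and the fixed effects act on the log-rate
scale.  The predictor combines

* **fixed effects** `beta` with improper flat priors (and a flat prior on
  the intercept `alpha`);
* **P-spline smooths** `f_j = B_j gamma_j`: a B-spline basis with
  equidistant knots and a random-walk prior on adjacent coefficients,
  `p(gamma_j | tau_j^2) ∝ exp(-gamma_j' K_j gamma_j / (2 tau_j^2))` with
  `K_j = D_r' D_r` the r-th-order difference penalty;
* a **spatial effect** `f_spat` on the ward adjacency graph with an
  intrinsic Gaussian MRF (ICAR) prior,
  `p(f | tau_s^2) ∝ exp(-f' Q f / (2 tau_s^2))`, `Q = diag(degrees) − A`
  the graph Laplacian — each ward's effect is shrunk toward the mean of
  its neighbours;
* **inverse-gamma(a, b)** hyperpriors on every prior variance `tau^2`.

Both the random-walk and ICAR priors are improper: `Q` has one null vector
(the constant) per connected component and `K_j` has a polynomial
nullspace of dimension r.  Identifiability is restored by a sum-to-zero
constraint per component (spatial) and a mean-zero constraint per smooth,
with the removed level absorbed into the intercept.

### Default parameters

| parameter | default | units / scale | rationale |
| --- | --- | --- | --- |
| hyperprior a, b | 0.001, 0.001 | — | weakly informative conjugate convention for variance components |
| spline degree | 3 (cubic) | — | standard structured-additive-regression default |
| spline intervals (`n_inner_knots`) | 20 | — | generous basis; the penalty controls effective dimension |
| random-walk penalty order | 2 | — | shrinks toward linear trends; capped at K−1 for tiny bases |
| offset mode | per-1000 population | log scale | keeps counts integer-valued while reporting on a rate scale |
| chain length / burn-in / thin | 12000 / 2000 / 10 | iterations | 1000 retained draws give stable 95% interval endpoints at desk scale |
| linear-predictor clip | ±50 | log scale | prevents overflow in `exp` during early iterations |

Covariates enter on their native scales by default (a `standardize` switch
exists) so coefficients read as "log-rate change per unit of the
indicator".

## MCMC scheme

One sweep updates, in order: the fixed block; each smooth's coefficients
followed by a conjugate variance draw; the spatial block followed by its
variance draw; then the centering/absorption step.  Coefficient blocks use
**Metropolis–Hastings with IWLS proposals**: the Poisson log likelihood is
expanded to second order at the current state, giving working response
`z_i = eta_i + (y_i − mu_i)/mu_i` and weight `w_i = mu_i`; the proposal for
a block with design `X_b` and prior precision `K/tau^2` is the Gaussian
with precision `P = X_b' W X_b + K/tau^2` and mean `P^{-1} X_b' W z_part`,
where `z_part` removes all other blocks' contributions.  The acceptance
ratio uses the exact Poisson posterior, with the reverse-proposal density
rebuilt at the proposed state.  Spatial and spline coefficients are updated
as whole blocks via dense Cholesky solves (S = 105 is tiny; dense linear
algebra up to S = 500, sparse storage beyond).

Variance updates are conjugate: `tau^2 | coef ~ IG(a + rank(K)/2,
b + coef'K coef/2)`.  The shape uses the **rank** of the penalty, not its
dimension — the correct degrees-of-freedom accounting for improper priors
(rank = K − r for an order-r random walk, S − #components for the ICAR
structure).

With the Gaussian-likelihood test hook (`likelihood="gaussian"`, known
variance) the IWLS proposal coincides with the exact full conditional, the
acceptance probability is identically 1, and the sampler reduces to Gibbs;
this is how the chain is validated against closed-form conjugate posteriors.

### Centering

After each sweep the spatial field is centred to mean zero within every
graph component and each smooth's coefficients to mean zero, with the
removed constants added to the intercept.  Because the posterior is
invariant along these flat directions (flat intercept prior) the projection
leaves the identified quantities' distribution unchanged.  For a connected
graph the absorption is exact; for graphs with islands the per-component
levels are not separately identifiable from one intercept and the
projection removes them (the unit-weighted mean level is kept).  Spline
absorption is exact because B-spline rows sum to one.

## Reporting

Posterior mean, 95% credible region (2.5th/97.5th empirical percentiles,
*linear interpolation between order statistics* — the dialect is pinned for
bit-stable outputs and recorded in chain metadata), exceedance probability
P(effect > 0), and a three-way class at a nominal level (default 80%):
**positive** if the central 80% interval lies entirely above zero,
**negative** if entirely below, **null** otherwise.  At the 95% level this
rule reduces to the familiar "interval spans zero → not associated"
convention of effect tables.  Per-ward classes are written both as text
and as codes {+1, −1, 0} for choropleth tooling.

Convergence diagnostics report effective sample size and lag-1
autocorrelation per quantity.  ESS uses Geyer's initial-positive-sequence
estimator on the empirical autocorrelations (FFT-based): summing adjacent
autocorrelation pairs until the first non-positive pair.  A batch-means
variant was considered but at desk-scale chain lengths its bias/variance
trade-off (bias ≈ Σρ/batch-size against noise from few batches) is
markedly worse on strongly autocorrelated chains; the initial-sequence
estimator recovers the closed-form ESS of an AR(1) benchmark well.
Constant chains report the diagnostics as undefined (NaN), not as numbers.

## Synthetic data

Real ward-level admission, mortality and pollution tables are generally
not public, so the generator produces structurally faithful stand-ins:

* **lattice** — a 15 × 7 rook grid (105 wards) as the default spatial
  support, with queen neighbourhoods available;
* **covariates** — mixtures of a standardized intrinsic-GMRF draw and
  white noise (`spatial_mixing` = 0.5 by default), mapped to realistic
  native scales: four pollutant indicators expressed relative to their
  national standards (all below 1 — no ward exceeds a standard), per-cent
  population over 50 around 35 ± 5, deprivation score around 18 ± 8.  The
  particulates indicator gets deliberately small spatial variation, since
  particulates vary much less across such a county than the other
  pollutants.  The four pollutant columns are inter-correlated at 0.5 via
  a Cholesky mix (approximate, restandardized), which lets experiments
  reproduce collinearity-driven sign instability qualitatively;
* **spatial effect** — an exact draw from the ICAR prior (spectral
  construction on the non-null eigenspace, sum-to-zero by construction)
  with `tau^2 = 0.25`;
* **populations** — log-uniform on [2000, 20000];
* **counts** — Poisson with the per-1000 offset.  The default true
  intercept (−0.15) is set so the expected ward count is ≈ 20; true
  coefficients are of realistic magnitude per native unit (e.g. 3.0 per
  pollutant-index unit for NOx, 0 for SO2, −6.0 for particulates).

What the generator does **not** emulate: real ward geometry (irregular
shapes, shared-boundary adjacency), measurement error in pollution
indices, temporal structure within the study window, overdispersion beyond
the spatial field, and the spatial layout of a real county.  Passing
recovery tests therefore demonstrate that the estimator recovers its own
generative model at study scale — a necessary internal-consistency check —
not that any particular real-data estimate is unbiased.

## Experiments and problem sizes

The recovery experiment refits freshly simulated data (new covariates,
spatial field, populations, counts per replicate) and reports per-effect
bias, RMSE and 95% coverage plus the correlation of the posterior-mean
spatial field with the truth.  Repeated fits use shorter chains
(4000 / 1000 / thin 5, i.e. 600 retained draws) than the single-fit
default — posterior means and 95% endpoints are stable at that length for
this model size, and it keeps a 20-replicate experiment at around a
minute.  Oracle checks use a 50-ward Gaussian-likelihood problem against
the closed-form conjugate posterior and a 20-observation single-coefficient
Poisson model against a 2001-point grid quadrature (50 000 retained
draws).

## Numerical choices and degenerate inputs

* Linear predictors are clipped at ±50 inside every exponential; a warning
  is logged when the clip binds.
* All-zero count vectors produce a warning (the intercept is unbounded
  below) but the chain still runs under the clip.
* Exactly collinear fixed-effect designs raise an error advising covariate
  removal (singular proposal precision).
* A constant covariate cannot be standardized or spline-expanded; both
  raise informative errors.
* Ward order is file order; the adjacency graph is re-indexed to dataset
  order when the design is built, so one canonical order flows through
  design, chains and output files.
* Every run is deterministic given the configured seed; derived seeds in
  experiments are drawn from a master generator and recorded in reports.

## Known limitations

Single-chain inference (no parallel chains or R-hat); the fixed IWLS
proposal is not adapted, and its acceptance rate for the whole-field
spatial block degrades as the field dimension grows (≈ 0.45 at 36 wards,
≈ 0.14 at 105 — still valid MCMC, just slower mixing; diagnostics are
logged so short chains are visible); no weighted or higher-order
adjacency; no binomial/negative-binomial likelihoods; smooth terms and the
ICAR field can confound when a covariate is strongly spatially structured,
which widens fixed-effect intervals rather than biasing them under the
generative model, but is a real interpretive caveat on observational data;
and all conclusions from areal fits are ecological — ward-level
associations need not hold for individuals.
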