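# Methods

## Model

Each view m is an N × D_m matrix over the same N samples. The generative
model is

    y_ndm ~ p(y | x_ndm),   x_ndm = z_n · w_dm (+ μ_dm),
    z_n ~ N(0, I_K),
    w_dkm = s_dkm · ŵ_dkm,  s_dkm ~ Ber(θ_km),  ŵ_dkm ~ N(0, 1/α_km),
    θ_km ~ Beta(a_θ, b_θ),  α_km ~ Gamma(a_α, b_α),

with a per-view observation model: gaussian with feature-wise precision
τ_dm ~ Gamma(a_τ, b_τ); Bernoulli with the logistic link σ(x); Poisson
with the softplus rate link λ(x) = log(1 + eˣ). The ARD precision α_km
deactivates a whole factor within a view (large α forces its weights to
zero there); the spike-and-slab indicator s gives feature-wise sparsity
within an active factor. Together they encode which factor drives which
view, which is what makes the decomposition interpretable.

Assumptions worth stating explicitly: factors are linear and shared;
residuals are conditionally independent across entries; feature sets of
different views are unrelated; missingness is ignorable (excluded from all
sums, never imputed during training).

## Variational inference

The posterior is approximated by a fully factorised family with two
deliberate exceptions: q(z_n) keeps the full K × K covariance within each
sample, and q(s_dk, ŵ_dk) is a joint spike-and-slab factor (inclusion
probability γ plus slab moments conditional on inclusion). Both couplings
are cheap (K ≤ a few tens) and noticeably improve the quality of the
approximation over a diagonal/independent treatment.

Every update is the exact coordinate-ascent maximiser of the ELBO given
the other factors, so on gaussian data the ELBO is non-decreasing after
*every single* update — the test suite asserts this at a relative
tolerance of 1e-8, which is an effective tripwire for implementation
drift. Two details matter for that exactness:

* The excluded-branch slab q(ŵ | s = 0) equals N(0, 1/E[α]) with E[α]
  frozen at the time of the weight update (stored as `var_spike`); the ARD
  update and the ELBO both use this stored value, which keeps each step an
  exact argmax.
* The inclusion log-odds are logit γ = E[logit θ] + ½ log E[α]
  − ½ log λ + h²/(2λ), where λ = E[α] + Σ precision-weighted E[z²] and h is
  the precision-weighted residual correlation. The ½ log E[α] term (not
  E[log α]) arises because the s = 0 branch also carries the prior-width
  normaliser.

Weight updates sweep factors sequentially, so the residual seen by factor
k always reflects the freshest values of the other factors; features are
independent given Z and are updated in parallel.

### Non-gaussian likelihoods

Binary and count views enter through quadratic lower bounds on their
log-likelihoods in the linear predictor x, which makes every observed
entry an equivalent gaussian pseudo-observation (site precision plus
pseudo-datum), so a single set of conjugate updates serves all
likelihoods.

* Bernoulli: the Jaakkola–Jordan logistic bound with curvature
  tanh(ξ/2)/(4ξ) (limit 1/8 at ξ = 0). The optimal bound parameter is
  ξ² = E[x²]; the bound touches the exact log-likelihood at ξ = |x|.
* Poisson: the negative log-likelihood f(x) = λ(x) − y log λ(x) has a
  globally bounded second derivative. Numerically, sup_x of the
  y-coefficient is ≈ 0.16710 (attained near x ≈ 0.495), so the site
  precision 1/4 + 0.17·y is a valid global curvature majorant; expanding f
  around ξ with that curvature yields a lower bound tight at ξ = x, and
  the optimal refresh is ξ = E[x]. Counts above 1e6 are rejected: the
  quadratic bound becomes numerically useless there.

Both bounds are checked by property tests: never above the exact
log-likelihood over random (y, x, ξ) draws, tight at the optimum, and the
expected bound never decreases under a ξ refresh.

### Intercepts

Gaussian views are centred once by the observed feature mean, which is
stored as μ_dm and re-added for imputation and reporting. Non-gaussian
views carry a learned offset on the linear predictor, re-estimated every
iteration as the precision-weighted mean of the residual pseudo-data; the
precision weighting makes the offset the exact maximiser of the bound
objective, preserving monotonicity of the bound-ELBO.

## Training procedure

* **Initialisation.** Factor means are drawn i.i.d. standard normal from
  the run's seed (all other state starts at its prior); gaussian noise
  precisions start at the reciprocal empirical feature variance; bound
  parameters start at ξ = 0, which is a valid bound everywhere, and are
  optimally refreshed from the first iteration on.
* **Burn-in** (default 10 iterations): inclusion probabilities are clamped
  to 1 and q(θ) is frozen at its prior. Freezing θ — not just clamping γ —
  matters: a Beta update fed with clamped γ = 1 would drive E[logit θ] to
  +∞ and permanently lock the sparsity open.
* **Update order** per iteration: weights → factors → sparsity → ARD →
  noise → bound parameters/offsets. The order is a fixed, reproducible
  choice; any order gives valid coordinate ascent.
* **Pruning** (every 5 iterations after burn-in): a factor is removed when
  its variance explained is below the threshold (default 2%) in every
  view; all per-factor state shrinks consistently. With a fixed factor
  number requested, pruning is skipped entirely.
* **Convergence**: relative ELBO change below 1e-5, evaluated only at
  pruning checkpoints where nothing was pruned (or anywhere in fixed-K
  mode), so the model cannot converge with stale null factors between
  checks. Hard cap 500 iterations.
* **Restarts** (default 10): independent seeds derived deterministically
  from the master seed (seed + 7919·i mod 2³¹−1); the model with the
  highest final ELBO wins, ties going to the lowest restart index. Single
  restarts can land in rotated local optima; ELBO selection reliably
  separates these in the test-suite fixtures.

Prior hyperparameters default to Gamma(1e-5, 1e-5) for α and τ and
Beta(1, 1) for θ — proper but effectively uninformative, numerically safe.

## Downstream analyses

* **Variance decomposition.** R²_{m,k} = 1 − Σ(y − z_k w_k − μ)² / Σ(y − μ)²
  over observed entries with posterior means; the all-factor R² replaces
  z_k w_k by the full reconstruction. For non-gaussian views this is
  computed on the gaussian pseudo-data scale, where squared error is
  meaningful; this is a reporting convention, documented here because raw
  R² has no natural meaning for binary/count likelihoods.
* **Loading scaling.** "Scaled" weights divide a factor's weight vector by
  its maximum absolute entry, mapping every view to [−1, 1] so loadings
  are comparable across assays; an L2 option exists. All-zero vectors are
  returned unchanged with a warning.
* **Enrichment.** Per feature set, an equal-variance two-sample t-test of
  in-set versus out-of-set weights (signed by default; an absolute-value
  flag exists for undirected questions), Benjamini–Hochberg adjusted
  across sets within a factor, flagged at 1% FDR by default. Sets with
  fewer than two matched features are skipped with a reason; unmatched
  labels are counted, not silently dropped.
* **Imputation.** Missing entries are filled with E[Z]E[W]ᵀ + μ, mapped
  through σ (probability scale) for Bernoulli views and λ (rate scale)
  for Poisson views. The masking benchmark hides either random values or
  whole sample-rows of a target view, refits with a fixed factor number
  (default K = 10), and reports MSE against feature-wise-mean and
  kNN (k = 5, sample-space neighbours, NaN-aware euclidean distances via
  scikit-learn) baselines over repeated seeds (default 15), with standard
  errors.

## Simulator

`omifa.simulate` draws data from the generative model itself: Z standard
normal; weights as Ber(θ) × N(0, 1/α) with α = 1 for (view, factor) cells
marked active and α = 10³ for inactive ones; θ defaults to 0.5 and
gaussian noise precision τ to 1. Missingness is value-wise Bernoulli or
assay-wise (whole sample-rows of one view). Named presets encode the
standard study designs — mixed-likelihood comparison (3 views, one per
likelihood, N = 100, D = 5000, K_true = 10, 5% missing), activity-pattern
recovery (gaussian-only, no missing, K_true 10 or 15), and imputation —
each with a desk-scale variant (D reduced to 150–500) used by the test
suite and the acceptance script.

What passing on these simulations does **not** show: real omics data
violate the linear-gaussian factor structure (count overdispersion,
batch effects, heavy tails, nonlinear dose-response), features are
correlated beyond the factors, and missingness is rarely at random. The
simulations validate the inference machinery, not the biological adequacy
of the model.

## Numerical choices and degenerate inputs

* All sums skip masked entries via the boolean mask; sentinel values are
  never used, and flipping values at masked positions provably changes
  nothing (tested end-to-end).
* Feature ranking ties are broken by feature label; restart ties by
  lowest index — both for reproducibility.
* A sample observed nowhere keeps its N(0, I) prior posterior; a feature
  with no observations falls back to its prior (γ = E[θ], slab at the ARD
  prior); a constant view makes R² undefined and is flagged, not NaN-ed
  silently.
* A non-finite ELBO raises immediately, naming the offending term.
* Factor-covariance solves go through batched matrix inversion of
  I + (precision-weighted second moments); the identity prior guarantees
  positive definiteness.

## Limitations

* Single sample group, no covariates or time structure.
* No Gibbs sampler, no stochastic/minibatch VB; dense linear algebra
  limits practical sizes to roughly N in the thousands, D in the tens of
  thousands per view, K below ~100.
* Bernoulli and Poisson views are handled through bounds, not exact
  likelihoods; their ELBO contributions are bound values, and their R² is
  a pseudo-data-scale convention.
* The ELBO landscape is non-convex; restart selection mitigates but does
  not eliminate local optima.
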