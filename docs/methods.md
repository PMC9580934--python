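# Methods

`dmdir` benchmarks how the *directionality* of the assumed statistical model
— methylation as the dependent variable (X|Y) versus the phenotype as the
dependent variable (Y|X) — affects cell-type-level differential-methylation
calling from bulk tissue data. This note documents the generative model, the
three testing routes, the evaluation metrics, the numerical choices, and the
limitations of what the simulations can show.

## Generative model

Bulk methylation is modelled as a proportion-weighted mixture of latent
cell-type signals. For sample i, CpG j and cell type h:

    Z_ihj ~ N(mu_hj, sigma_hj^2)                 latent cell-type methylation
    X_ij  = sum_h W_ih Z_ihj + e_ij,  e_ij ~ N(0, tau_j^2)    observed bulk

with W (n x k) cell-type proportions drawn from a Dirichlet. This is
exactly the model both tested methods assume, which keeps the benchmark
internally coherent: any performance difference is attributable to
directionality and estimation, not to generative mismatch.

Phenotype coupling is directional:

* **X|Y** (`direction="xgy"`): a balanced binary phenotype is drawn first;
  at each truth entry (j, h) the latent mean of cases is shifted by
  `effect_size * sigma_hj`. Effects are therefore expressed in units of the
  latent cell-type standard deviation, making power curves scale-free.
* **Y|X** (`direction="ygx"`): the latent tensor carries no phenotype term;
  a liability aggregates the standardized latent components at the truth
  entries,

      L_i = sum_{(j,h) in truth} beta_jh (Z_ihj - mu_hj)/sigma_hj + eps_i,

  with `eps_i ~ N(0, liability_sd^2)`, `liability_sd = 1` by default, and
  cases are the top ceil(n/2) of the liability distribution. Standardizing
  the components gives `effect_size` the same per-entry meaning in both
  directions; unit liability noise makes an isolated entry of effect 1
  explain half of the liability variance.

Scenarios fix the within-CpG effect pattern: `uni1c` (one affected cell
type), `uni2c` (two, same sign), `bi2c` (two, opposite signs), `bi3c`
(three, mixed signs). Exactly `m_true` CpGs carry effects; affected cell
types are drawn uniformly.

Defaults (all configurable): n=500 samples, m=1000 CpGs, m_true=50, k=6
cell types with Dirichlet concentration (7.0, 2.5, 2.0, 1.5, 1.0, 0.5) —
blood-like: one dominant type and a 3% minor type — baseline means
mu ~ U(0.1, 0.9), latent standard deviations sigma ~ U(0.02, 0.1) and bulk
noise tau ~ U(0.005, 0.02), magnitudes typical of array beta-values. Latent
methylation is *not* truncated to [0, 1] and bulk values are clipped only
under an explicit `clip` flag (default off), keeping Gaussian likelihoods
exact for the oracle tests.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; benchmark replicate r uses seed
`master_seed + r`. Identical configuration and seed give bit-identical
cohorts. A `truth_seed` field lets independent cohorts share their ground
truth, which the replication (validation-rate) experiments require.

### What the generator does and does not emulate

It emulates the mixture structure, blood-like composition, beta-value-scale
baselines and cell-type-specific effects of array bulk methylation. It does
**not** emulate probe chemistry or batch artifacts, beta-value boundary
effects (no truncation by default), estimated — rather than known —
proportions, or confounder-driven association (a third factor influencing
both X and Y). Passing benchmarks here therefore demonstrate behaviour
under the methods' own modelling assumptions with known W; real-data
performance additionally depends on everything listed above.

## Testing routes

**Interaction regression (CellDMC-style, structurally X|Y).** Per CpG,
ordinary least squares of the bulk column on `[W | W*y | covariates]` —
no separate intercept, because the rows of W sum to one and its columns
span the constant. The k interaction coefficients are the cell-type effect
estimates, tested two-sided against t with n - (2k + p) degrees of freedom.
A constant phenotype makes every interaction column collinear with W and
raises a singular-design error naming the collapsed columns.

**Latent-model X|Y test.** `fit_tca` maximizes the per-CpG marginal
likelihood X_ij ~ N(sum_h W_ih mu_hj, v_ij), v_ij = sum_h W_ih^2 sigma_hj^2
+ tau_j^2, by an expectation–maximization scheme whose E-step is the
closed-form Gaussian conditioning of (Z, e) on X and whose M-step updates
means and variances from the posterior moments. Every iteration ascends the
exact marginal likelihood; iteration stops at relative objective change
below 1e-6 (per CpG) or 200 iterations, with non-converged CpGs flagged and
the best iterate returned. Variances are floored at 1e-8. Initialization:
mu from the OLS solve of X on W, sigma^2 as the OLS residual variance split
equally across cell types, tau^2 as 10% of it. EM was chosen over per-CpG
bounded quasi-Newton for the default path because it vectorizes across the
whole CpG panel; `polish=True` appends the quasi-Newton stage (alternating
exact weighted least squares for mu with L-BFGS-B on log-variances),
which resolves EM's slow tail along the sigma^2/tau^2 ridge and is used
where the variance estimates themselves are the quantity of interest.

The association test extends the marginal mean with `W_ih * beta_hj * y_i`
terms, estimating all coefficients per CpG by weighted least squares with
weights 1/v_ij from the fitted model. With equal weights the estimates
reduce exactly to the interaction OLS — the precise sense in which the
interaction model is a degenerate (homoscedastic) case of the latent model.
Standard errors are leverage-adjusted HC3-type sandwich estimates around
the weighted estimator, with a t(n - q) reference. The naive
"known-variance" Wald is anticonservative here (null z-standard-deviations
of 1.02–1.05, type-I rates near 5.5% at the 5% level) because the plug-in
weights are estimated from the same data and adapt to the residuals; with
the generative weights the naive test is exactly calibrated, which isolates
the plug-in as the cause. The leverage adjustment restores the 5% rate
without touching the point estimates.

**Latent-model Y|X test.** `estimate_tensor` returns the exact posterior
mean of Z given X under the fitted model (scalar-observation Gaussian
conditioning, closed form; posterior mean and mode coincide for Gaussians).
`tca_test_ygx` then tests each (CpG, cell type) column of the estimated
tensor against a binary phenotype with the logistic score test evaluated at
the null fit (intercept + covariates). Because no alternative model is ever
fitted, complete separation cannot occur; zero-variance columns are flagged
`degenerate` with p = 1. Continuous phenotypes take the analogous linear
(partial-correlation) score test. Testing is marginal per cell type by
default; `joint=True` adds a per-CpG k-degree-of-freedom score test.

**Significance and metrics.** Calls are made jointly over all m x k tests,
Bonferroni at alpha = 0.05 by default (Benjamini–Hochberg and uncorrected
available). Sensitivity, specificity and precision are computed over
(CpG, cell type) pairs — a call is a true positive only if both coordinates
match a truth entry — and precision is recorded as missing, never zero,
when a method makes no calls. The validation rate between two association
tables is the fraction of the t smallest-p pairs shared by both (ties
broken lexicographically for determinism); the directionality diagnostic is
the same top-t overlap between the interaction regression and the latent
X|Y test, with declared verdict thresholds 0.8 (supports X|Y) and 0.2
(supports Y|X) surfaced in the output.

## Benchmark conditions shipped with the package

The acceptance study (tests and `scripts/acceptance.py`) runs the full
pipeline at n=500, m=400 CpGs, m_true=30, k=6, standardized effect 2,
Bonferroni alpha=0.05, with 12–15 replicates per scenario cell and
calibration pooled over >= 7200 effect-free tests per method and direction.
These panel sizes are the package's benchmark defaults; the generator
itself defaults to the full m=1000 panel.

## Known limitations and structural findings

Three properties of this generative recipe are worth stating explicitly,
because they bound what any method can achieve on its Y|X cohorts:

1. **Liability dilution.** With one dataset-level phenotype aggregating
   m_true independent entries, each entry's correlation with the liability
   is at most 1/sqrt(m_true) no matter how large the effect size. At
   m_true = 30–50 and n = 500 this caps per-entry association scores near
   z ~ 2.5, below a Bonferroni threshold over thousands of tests — so on
   Y|X cohorts *every* testing route, correctly directed or not, loses
   essentially all power at these defaults. Misdirection then manifests as
   powerlessness rather than as false-positive inflation.
2. **Within-CpG leakage of the plug-in Y|X test.** All k posterior-mean
   tensor columns of a CpG are affine functions of the same bulk residual,
   so a genuine bulk-level association registers, attenuated, in every
   cell type of that CpG. On X|Y cohorts the misdirected Y|X test therefore
   gains sensitivity while losing precision (calls at the right CpGs in the
   wrong cell types), and because the leakage is driven by the shared
   truth it *replicates across independent same-truth cohorts*: top-list
   replication does not imply correct cell-type localization when the
   error mechanism is systematic. For the same reason, reliable
   localization of single strong Y|X entries needs enough samples for the
   posterior to separate cell types (low-abundance cell types are heavily
   shrunken; the shipped ranking check uses n = 800).
3. **Heteroscedasticity of the interaction OLS.** The bulk variance
   sum_h W_ih^2 sigma_hj^2 + tau_j^2 varies with the sample's proportions,
   so the homoscedastic OLS t-test is mildly anticonservative when
   proportions are widely dispersed (observed ~6% at the 5% level for a
   k=3, low-concentration composition). Under the blood-like default
   composition the variation is small and the test is calibrated.

Per-component variance parameters of the latent model are weakly
identified when a cell type's proportions are uniformly small (information
scales with W^4 moments) or when tau^2 is a small share of the marginal
variance; the parameter-recovery check accordingly asserts aggregate
(median) relative error under a balanced, well-conditioned configuration,
alongside the 0.02 RMSE bound on the latent means, which holds broadly.
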