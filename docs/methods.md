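# Methods

## Model and estimation

`scoredif` works with binary logistic item response models in the
slope–intercept parameterization

    P(Y_ij = 1 | θ_i) = c_j + (1 − c_j) · logistic(a_j θ_i + d_j),

with discrimination `a_j > 0`, easiness intercept `d_j` (logits) and a
pseudo-guessing lower asymptote `c_j ∈ [0, 1)` (3PL; the 2PL model is the
`c_j = 0` restriction).  No difficulty-parameter (`a(θ − b)`) conversion is
exposed; everything, including priors, lives on this natural scale.

Abilities are integrated out over a fixed quadrature grid: 61 equally
spaced nodes on [−6, 6], with weights proportional to the group's normal
density `N(μ_g, σ²_g)` and renormalized to sum to one.  This matches the
convention of the widely used EM-based IRT packages and keeps the fitted
objective an ordinary finite-dimensional likelihood, which the score
machinery below differentiates exactly.

**Multiple-group ("impact") models.**  Item parameters are shared across
groups; the first group's ability distribution is fixed at N(0, 1) for
identification, and the other groups' `(μ_g, σ²_g)` are estimated by ML —
also under MAP, where no prior is placed on group parameters.  Only the
location *difference* between groups is identified: when the generating
distributions are N(−0.5, 1) and N(+0.5, 1) the estimate for the second
group converges to `μ̂₂ ≈ 1`.

**MAP estimation.**  The posterior mode maximizes the marginal
log-likelihood plus a log prior over item parameters, with independent
per-parameter-class priors:

* slope: log-normal `LN(μ_log, σ²_log)` or normal (both parameterized by
  mean and **variance** — `LN(0, 0.0625)` means σ_log = 0.25);
* intercept: normal;
* guessing: `Beta(α, β)`.

Two presets are shipped.  `agreeing` (slope LN(0, 0.0625), intercept
N(0, 1), guess Beta(5, 45)) matches the synthetic generating
distributions; the guessing component is configurable (e.g. Beta(4, 45))
for alternative elicitations, and Beta(5, 45) is the default because it is
the distribution the generator actually draws from.  `non_informative`
uses flat priors: slope N(1, 10), intercept N(0, 10), guess Beta(1, 1)
(whose log-density gradient is implemented as exact zeros).

**Optimization.**  Fitting is a two-stage procedure designed around the
score identities the tests rely on:

1. *EM stage* — Bock–Aitkin EM with per-item bounded L-BFGS-B M-steps
   (box constraints `a ∈ [1e-4, 50]`, `c ∈ [1e-4, 1−1e-4]`, `d` free) and
   group-parameter updates from expected sufficient statistics, run to a
   coarse parameter-change tolerance (1e-3, cap 500 cycles).  Starting
   values are deterministic: `a = 1`, `d = logit(item mean)` clipped to
   [−3, 3], `c = 0.1`.
2. *Polish stage* — joint L-BFGS-B on the full penalized marginal
   objective (item plus free group parameters) with the analytic gradient,
   run until the KKT-projected gradient satisfies `‖·‖∞ < 1e-3`.

EM alone converges linearly and a parameter-change criterion does not
bound the gradient, so the polish is what guarantees the defining
identities `Σᵢ ψ(Yᵢ; β̂) = 0` (MML) and `Σᵢ ψ(Yᵢ; β̂) = −u_prior(β̂)` (MAP)
hold to 1e-3 at the reported estimate.  One caveat: when a guessing
parameter's optimum lies on the box boundary (true `c` near 0 under a flat
guessing prior), the fit is a KKT point and the interior identity cannot
hold in that component — the total gradient then points outward at the
bound.  This is the same phenomenon that produces published `c = 0.000`
estimates; the acceptance checks treat pinned components by the KKT
condition.  Non-convergence raises an error carrying the objective trace.

## Casewise scores and the cumulative score process

Person `i`'s score contribution is `ψᵢ = ∂ log Lᵢ/∂β` for the stacked
item-parameter vector (item-major order `a₁, d₁[, c₁], a₂, …`), computed
through the posterior quadrature weights.  Scores for the group
`(μ_g, σ²_g)` parameters are available for optimality diagnostics but are
excluded from the test process: DIF detection should use item-parameter
information only.

Pipeline (identical for MML and MAP; the prior enters only through the
estimate and the centering):

1. **center** — subtract column means.  Harmless under MML (the mean is
   already ~0), required under MAP where the raw scores sum to
   `−u_prior`.  Centering uses the *global* mean even in group-wise mode:
   the null model asserts a common expectation, and group-specific
   centering would absorb exactly the DIF signal being tested.
2. **covariance** — outer-product estimate with divisor `N` (the
   asymptotic form, not `N−1`), either pooled (one k×k matrix) or
   group-wise (per impact group, still globally centered).  Inverse square
   roots come from a symmetric eigendecomposition with a 1e-10 eigenvalue
   tolerance; smaller eigenvalues raise a singular-covariance error naming
   the offending parameter.
3. **build_process** — sort persons by the covariate (stable sort,
   original order breaks ties; categorical labels sort lexicographically),
   decorrelate row-wise by `V̂_{g(i)}^{−1/2}`, and accumulate
   `Ψ(i/N) = N^{−1/2} Σ_{l≤i} V̂^{−1/2} ψ̃_l` with `Ψ(0) = 0`.

Under invariance the process converges to a k-dimensional standard
Brownian bridge.  With pooled decorrelation the finite-sample path ends
exactly at 0; with group-wise decorrelation and heterogeneous group
covariances it generally does not, which is what the simulation engine
accommodates.

One contract was genuinely open: whether the covariance under MAP should
remove `u_prior/N` from the rows before the outer product.  The package
centers by the empirical mean and takes the outer product of the centered
rows; the bridge-variance property test (process variance ≈ t(1−t))
asserts this choice behaves as the asymptotics require.

## Test statistics and p-value engines

* **DM (double maximum)** — `max_{i,j} |Ψ(i/N)_j|`, for continuous
  covariates.
* **LM_uo (unordered LM)** — sum over covariate categories of squared
  process increments.  The default *weighted* form divides each bin by its
  width `t_l − t_{l−1}`, which gives the χ²(k(m−1)) reference used by the
  standard structural-change software; the plain unweighted sum is
  available behind a flag and is valid under the simulation engine, which
  needs no closed form.

**Asymptotic engine (pooled-variance route).**  DM p-values use the
Kolmogorov distribution `p₁(x) = 2 Σ_{j≥1} (−1)^{j+1} exp(−2j²x²)`
(series truncated at a 1e-12 term or 100 terms) and component independence
after decorrelation, `p = 1 − (1 − p₁)^k`, computed via `log1p/expm1` to
avoid saturation.  LM_uo p-values are upper-tail χ²(k(m−1)).

**Simulation engine.**  R replicates (default 1000, minimum 99) of N iid
standard normal k-vectors are shifted, `s̃ᵢ = sᵢ − s̄ + Ψ(1)/√N`, so each
simulated scaled partial-sum path shares the observed path's start and end
point; the observed statistic is compared against the simulated ones with
the add-one estimator `p = (1 + #{T_sim ≥ T_obs})/(R + 1)` (smallest
attainable p is `1/(R+1)`; bit-reproducible given a seed).  The
"group-wise decorrelation" applied to the draws is the identity — iid
standard normals are their own decorrelation; this interpretation is
equivalent in distribution to re-applying group-specific factors.

Statistic defaults follow the covariate type: DM for continuous, LM_uo for
categorical.

## Synthetic data generator

The generator emulates the simulation study's conditions and its defaults
are those conditions, not tuning knobs:

* slopes `a ~ LN(0, 0.0625)`, intercepts `d ~ N(0, 1)`, guessing
  `c ~ Beta(5, 45)` (3PL);
* N ∈ {500, 1000, 2000, 5000}, J ∈ {10, 30} (a `strict=False` escape
  hatch exists for exploratory sizes);
* covariate either Bernoulli(.5) two-group labels or U(20, 70) split at
  35 (an age-like cohort variable);
* impact: abilities N(−0.5, 1) on the first side, N(+0.5, 1) on the
  second; otherwise N(0, 1) for everyone;
* DIF on a uniformly chosen one-fifth of the items, as additive shifts on
  the focal side's response function only (Δa = 0.3, Δd = 0.6, Δc = 0.1):
  unbalanced = all selected items shifted up (favouring the more able
  group under impact); balanced = half up, half down with random,
  seed-controlled sign assignment (an odd extra item gets +Δ).  A negative
  guessing delta is truncated so the shifted asymptote stays ≥ 0.005,
  since `c − 0.1` can be negative for Beta(5, 45) draws.

Every dataset is reproducible from `(master seed, cell id, replicate)` via
hashed `SeedSequence` streams, so study cells are independently
reproducible and parallelizable without changing results.

What the generator does *not* emulate: missing responses, polytomous or
multidimensional items, non-normal ability distributions, DIF on more than
one parameter class at a time, and covariate-dependent ability beyond the
two-sided impact shift.  Passing tests therefore speak to the method's
behaviour under a clean, correctly specified generating process, not to
robustness against these real-data features.

## Study driver and problem sizes

`run_study` maps a grid of cells to rejection rates (fraction of
replicates with p < .05) with binomial Monte Carlo standard errors.
Failed fits are counted per cell and enter the denominator as
non-rejections unless explicitly dropped.  The reference design uses 1000
datasets per cell and R = 1000 simulation replicates; this package's
bundled experiments run representative scaled-down cells, chosen once:

* size of the simulation engine (3PL, 10 items, categorical, N = 1000,
  MML): 150 null datasets, R = 199 in the test suite and R = 300 in
  `scripts/acceptance.py`, judged against the binomial 95% band around
  .05;
* conservativeness of the pooled engine (2PL, 10 items, N = 1000,
  categorical): 200 null datasets, rate ≤ 0.07;
* power ordering (intercept DIF Δd = 0.6, unbalanced, pooled engine):
  100 datasets per cell at N ∈ {500, 2000} with matched null cells.

## Numerical choices and limitations

* Probabilities are clipped to [1e-10, 1 − 1e-10] inside logs; the
  quadrature E-step uses a row-max log-sum-exp.
* Covariance divisor N; eigenvalue tolerance 1e-10; EM change tolerance
  1e-3 before polishing; projected-gradient tolerance 1e-3 (the same
  magnitude as the score-identity checks).
* Ties in a continuous covariate keep original row order (stable sort).
* Degenerate items (all-0/all-1 columns) and missing responses are
  rejected up front; missing data are out of scope.
* The simulation engine inherits the known small-sample liberality for
  skewed score distributions (3PL guessing parameters, long tests); the
  pooled route is conservative.  Neither engine is a per-item DIF test:
  the null is joint invariance of all item parameters.
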