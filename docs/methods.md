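# Methods

## Model

`copulagraph` estimates a conditional-independence network among p mixed
binary/ordinal/continuous variables measured on n subjects.  The model
is a Gaussian copula graphical model: a latent vector Z follows a
p-variate normal distribution N(0, Ω⁻¹) with sparse precision matrix Ω,
and each observed variable is a monotone transform of its latent
coordinate,

    X_v = F_v⁻¹(Φ(Z_v)),   v = 1..p,

with the marginals F_v treated as nuisance parameters.  Absent edges in
the graph correspond to exact zeros of Ω (pairwise Markov property);
edge weights are reported as partial correlations

    ρ_ij|rest = −ω_ij / √(ω_ii ω_jj).

Discrete variables enter through cutpoints: a K-level ordinal variable
partitions the latent axis into K intervals delimited by thresholds
c_1 < … < c_{K−1}; observing level k pins Z_v into (c_k, c_{k+1}].
Cutpoints are estimated once from the data as standard-normal quantiles
of the empirical cumulative level proportions.  Continuous variables are
reduced to ranks and mapped to normal scores z = Φ⁻¹(r/(m+1)) (the
nonparanormal transform), which makes the whole procedure invariant to
monotone marginal transformations — the reason the model needs no
distributional assumptions about, e.g., right-skewed intake variables.
Missing cells impose no constraint at all: their latent interval is
(−∞, +∞), which is how the EM algorithm below handles missing data
without imputation.

## Estimation: penalized EM

At a penalty λ ≥ 0 the estimator alternates:

- **E-step** — compute R̄ = (1/n) Σᵢ E[Z Zᵀ | Xᵢ], the conditional
  second-moment matrix of the latent vector given each subject's
  interval constraints, under the current Ω.
- **M-step** — graphical lasso on R̄: maximize
  log det Ω − tr(R̄Ω) − λ‖Ω‖₁,off.  The diagonal is unpenalized (a flag
  enables the penalized-diagonal variant).  The solver (scikit-learn's
  `graphical_lasso`, LARS mode) returns exact zeros where the penalty
  binds, so the estimated support is literal, not thresholded.

Two E-step implementations are provided and cross-checked against each
other in the test suite:

- `approx` (default, deterministic): a coordinate-wise mean-field pass —
  each free coordinate's conditional N(μ_v, 1/ω_vv) given the current
  means of the others is truncated to its interval and replaced by its
  truncated mean/variance, iterated to a fixed point (max 50 passes,
  stop when means move < 1e-4).  Mean-field alone omits the conditional
  cross-covariances between discrete coordinates, which biases R̄
  noticeably at typical ordinal resolutions, so a Gaussian covariance
  correction is added per subject: the free-block posterior covariance
  is approximated by (Ω_FF + diag(s))⁻¹ with site precisions s_v
  matched to the truncated conditional variances, then rescaled so its
  diagonal equals the truncated marginal variances exactly.  The test
  suite verifies entrywise agreement with a long Gibbs run within 0.02
  on ordinal problems.
- `gibbs`: a truncated-normal Gibbs sampler (default 500 burn-in, 1000
  retained sweeps; a seed is required).  Draws use a log-scale
  inverse-CDF so tail intervals stay exact.  This is the Monte-Carlo
  reference implementation; it is too slow for bootstrap loops but
  defines what the approximation must reproduce.

Truncated-normal moments are computed by the φ/Φ ratio formulas on the
log scale, with the interval reflected so its dominant tail is the lower
one; intervals beyond ~±8σ fall back to a point mass at the endpoint
nearer zero.  R̄ is floored at eigenvalue 1e-6 and rescaled to unit
diagonal (the mean-field construction is a Gram matrix plus a
nonnegative diagonal, so the floor rarely activates).

**Outer loop.**  EM stops when the relative Frobenius change of Ω falls
below tol = 1e-4 (max 100 iterations).  Because the approximate E-step
solves its fixed point only to finite precision, the EM map retains a
small limit cycle (~1e-3 relative) at small λ; the loop therefore also
stops, and reports convergence, once the support has been unchanged for
5 consecutive iterations and the relative change is below √tol.  All
quantities consumed downstream (the support and the refitted likelihood)
are stable well before that point.

## Penalty path and model selection

The grid is log-spaced over N = 30 values (default) from λ_max — the
largest absolute off-diagonal of the initial E-step moment matrix at
Ω = I, the smallest penalty whose fit is empty — down to 0.05·λ_max.
Fits proceed from the largest penalty with warm starts (both Ω and the
conditional means), which is what makes 200 bootstrap refits practical.

Model selection minimizes the extended BIC

    eBIC(λ) = −2 l(Ω̂_λ) + {log n + 4γ log p} df_λ,

with γ = 1/2 by default and df the number of edges, counted once per
pair (a flag provides the doubled both-triangles convention).  Two
likelihood conventions matter here and both are deliberate:

- l is evaluated at the **support-constrained unpenalized MLE**, not at
  the shrunken glasso estimate.  The l1-shrunk estimate's likelihood
  increases monotonically as λ decreases, so scoring it directly always
  selects the densest model; refitting (classic covariance selection,
  solved by the column-wise regression algorithm) scores the graph
  itself.
- every support on the path is scored against a **common moment
  matrix** — the converged R̄ of the densest fit, the latent analog of
  the sample covariance.  Per-λ moment matrices adapt to their own Ω,
  which would make likelihoods incomparable across the path.

Ties in eBIC break toward the larger penalty (sparser graph).

## Bootstrap edge certainty

Nonparametric bootstrap: B replicates (default 200) resample the n
subjects with replacement; each replicate reruns the entire procedure —
cutpoint estimation, penalty grid, EM path, eBIC selection — with child
seeds derived deterministically from the base seed.  The certainty of an
edge is the fraction of successful replicates whose selected graph
contains it, reported for the edges of the original selected graph (the
full pair-frequency matrix is kept in the JSON report).  Replicates that
fail (e.g. an ordinal level vanishing under resampling) are excluded
from the denominator and counted in a warning.  No certainty threshold
is imposed for display; the GraphML export carries a line-type class
with configurable cuts at 0.5/0.75/0.9.

## Synthetic data

The generator draws Z ~ N(0, Ω_true⁻¹) (rescaled to unit variances) and
pushes each coordinate through its declared marginal: ordinal levels via
cutpoints at Φ⁻¹ of cumulative level probabilities, continuous variables
via lognormal (default; nutrient intakes are right-skewed), normal, or
gamma marginals matched to a target mean/sd.  Missingness is completely
at random at a configurable rate.  Truth precisions are built by placing
partial correlations of requested magnitude on a random/chain/hub
support and shrinking toward the identity until the smallest eigenvalue
is ≥ 0.15; supports whose shrinkage collapses edge magnitudes below the
requested range are redrawn.  The conditioning floor is intentional:
without it, near-singular truths with extreme marginal correlations
arise easily, and under those no l1-path estimator can recover the
support — fixtures built on them would be meaningless rather than hard.

The pooled-cohort template emulates the structure of a four-study
nutrition cohort of older adults: 662 subjects in deterministic one-hot
study blocks of 252/122/81/207; 17 lognormal nutrient intakes (energy
1913 ± 469 kcal/d, folate 243 ± 85 µg/d, …); physical-functioning scores
as discretized normals on their native scales (total score 0–12 with
mean 9.6, components 0–4), with the discretization location calibrated
by root finding so the discrete mean hits the target exactly; binary sex
(61.7% female) and smoking (30.9%); and continuous anthropometric
covariates.  A default truth graph places weak-to-moderate partial
correlations (0.2–0.3) on plausible nutrient–function and
covariate–function pairs; study-dummy rows are diagonal.  The template
emulates marginal shapes and block structure only — it does not
reproduce any real cohort's joint distribution, effect sizes, or
informative missingness, so passing tests demonstrate method
correctness under the stated conditions, not field performance.

## Problem sizes and numerical defaults

Simulation studies in the test suite use p = 15, n = 1500 (recovery,
10 seeds, also under 10% MCAR), p = 10, n = 800 with B = 50 (bootstrap
discrimination), and the n = 662 cohort template; test fits use 10–15
grid points with min_ratio 0.1, which brackets the selected model in
these problems.  Library defaults remain N = 30, min_ratio = 0.05,
γ = 0.5, tol = 1e-4, max_iter = 100, B = 200.

## Known limitations

- Non-ordinal categorical variables are rejected; dummy-encode them.
- The approximate E-step is a Gaussian approximation to a truncated
  multivariate normal; its residual bias is small (bounded by the Gibbs
  cross-check in the test suite) but not exactly zero.
- The mean-field/EP moment matrix makes the monitored penalized
  objective only approximately monotone across EM iterations; it is
  asserted (within Monte-Carlo noise) only under the Gibbs E-step.
- Missingness is assumed MCAR in the generator and ignorable in the
  estimator; informative missingness is out of scope.
- eBIC consistency degrades when edges are weak relative to √(log p / n);
  the bootstrap certainty is the intended guard against over-reading
  single selected graphs.
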