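# Methods

## Model

`hierlogit` fits a Bayesian varying-intercept (partial-pooling) logistic
regression for a binary survey outcome. For student *i* in grade *j*:

```
y_ij ~ Bernoulli(pi_ij)
logit(pi_ij) = alpha_0j + sum_k beta_k x_ik
alpha_0j     = alpha_0 + mu_j,   mu_j ~ N(0, sigma_mu^2)
```

with priors `beta_k ~ N(0, 10)`, `alpha_0 ~ N(0, 10)` (scales are standard
deviations) and `sigma_mu ~ half-Cauchy(0, 2.5)`. The grade-level intercepts
partially pool the three school grades: grades with few or noisy responses
are shrunk toward the overall intercept. Covariates enter linearly on the
logit scale; ordinal survey items are treated as numeric codes, so one
coefficient per item, matching how such surveys are conventionally reported.

Internally the model is parameterized non-centered: `mu_j = sigma_mu *
mu_raw_j` with `mu_raw_j ~ N(0,1)`, and `sigma_mu` is sampled as
`log sigma_mu` with the Jacobian term added to the log-density. With only
J = 3 groups the data carry little information about `sigma_mu`, and the
centered parameterization produces a funnel that HMC handles poorly; the
non-centered form induces an identical posterior on the grade intercepts
while keeping the geometry mild. The half-Cauchy (rather than a prior on the
variance) is the standard weakly informative choice for a group-level scale.

An additive individual-level error term sometimes written into the logit
model's first line is a quasi-likelihood device; the Bernoulli likelihood
already carries that variance, so no separate error parameter exists here.

## Sampler

Posterior sampling is Hamiltonian Monte Carlo with the No-U-Turn tree-
doubling scheme (slice-sampling variant): trajectories are grown by repeated
doubling with a leapfrog integrator until either end begins to turn back
(U-turn criterion on both subtree ends), and the next state is drawn
uniformly from the slice-admissible leaves. Key numerical choices:

- **Step size**: dual averaging toward a target mean acceptance statistic of
  0.8 (γ = 0.05, t0 = 10, κ = 0.75), initialized by the double/halve
  heuristic that brackets a one-step acceptance of 1/2. Adaptation runs over
  the whole warmup and the averaged value is frozen afterwards; a step size
  collapsing below 1e-10 is a hard failure that names the scaling problem.
- **Mass matrix**: diagonal, set to the inverse per-coordinate variance of
  warmup draws collected in the window (0.5·W, 0.75·W]; the final quarter of
  warmup re-runs dual averaging under the new metric so the frozen step size
  and metric are mutually consistent. Only second-half draws feed the metric,
  which keeps the initial transient out of the variance estimate.
- **Divergences**: a transition whose energy error exceeds 1000 terminates
  the doubling and is counted; a run with more than 10% divergent retained
  transitions is marked failed. Tree depth is capped at 10 doublings
  (saturations are counted separately).
- **Chains and seeds**: default protocol is 2 chains of 4000 transitions
  with the first 2500 discarded as warmup (so 1500 retained per chain — the
  stated total is read as including burn-in). Chains start from independent
  uniform(-1, 1) points on the unconstrained scale. Per-chain RNG streams are
  spawned from a single seed, so a run is bit-reproducible.

The sampler is validated against independent oracles rather than another
NUTS implementation: dense trapezoid grid integration of a two-parameter
logit posterior (400² nodes on [-10,10]²) and a long random-walk Metropolis
chain; posterior means must agree within 3 Monte Carlo standard errors and
posterior SDs within 10%.

## Diagnostics and gating

Reporting is gated on the Gelman–Rubin potential scale reduction factor,
computed per parameter in the split-chain form (each chain halved, so
within-chain trend registers as between-chain variance): with within-chain
variance W and between-chain variance of chain means B/n, the statistic is
`sqrt(((n-1)/n·W + B/n) / W)`. The gate passes only when every parameter is
below 1.10; well-mixed runs typically sit below 1.01. The original unsplit
form is available via `split=False`; no rank-normalization is applied, to
stay close to the classical formulation. Geweke z-scores (first 10% vs last
50% of each chain, window variances from Bartlett-windowed spectral density
at zero) and effective sample sizes (autocorrelation sum with Geyer's
pairwise-positive truncation, autocorrelations averaged across chains) are
reported alongside; ESS feeds the Monte Carlo standard errors used in
oracle comparisons.

A separate weak-prior check computes, for the intercept and every slope, the
ratio of posterior SD to prior SD and requires all ratios below 10% for the
priors to count as non-informative in the fit.

## Reporting

Slopes are reported as odds ratios: the point estimate is `exp(E[beta])`
(the exponentiated posterior mean; `E[exp(beta)]` is available behind a
flag), the dispersion is the SD of the exponentiated draws (the only scale
on which an odds-ratio SD is meaningful), and the 95% equal-tailed interval
is the exponential of the 0.025/0.975 coefficient-scale quantiles (linear
interpolation between order statistics). The percentage effect is
`(OR - 1) × 100` and a slope is flagged significant exactly when its
interval excludes 1. When the convergence gate fails, the rendered report
withholds estimates unless explicitly forced; machine-readable CSVs are
always written so a failed run remains inspectable.

## Synthetic survey generator

The generator emulates the structure of a school-based adolescent smoking
survey with 640 complete-case respondents: three grades with shares
0.398/0.325/0.277, ~40 covariates at their published marginal means, and a
binary intention-to-quit outcome at 63.3% prevalence. Defaults:

- **Binary items** are independent Bernoulli draws at the published means.
- **Count-like items** (e.g. cigarettes per day) are binomial on integer
  codes 0..6 scaled to the published mean — a bounded two-parameter family,
  chosen because the source reports only means and SDs.
- **Mutually exclusive indicator sets** (age groups, parental smoking,
  cigarette brand) are single categorical draws, one-hot encoded with the
  reference level dropped. The published brand shares sum to 0.45, so the
  remainder is an implicit reference-coded level alongside "no usual brand".
- **Effect sizes** default to the natural logs of the published odds ratios;
  the between-grade scale defaults to sigma_mu = 0.3, a stipulation (the
  source never reports its group-scale posterior).
- **Intercept calibration**: with `alpha0="auto"`, bisection on a fixed
  seed-derived Monte Carlo draw of 100,000 covariate rows sets the intercept
  so expected prevalence hits the target within 0.002, conditioning on the
  realized grade deviations of the dataset being generated (so the realized
  prevalence differs from the target only by binomial noise).
- Covariates are drawn independently because the source reports marginals
  only; an equicorrelated Gaussian-copula hook exists but defaults off.

What passing tests on these data do *not* show: robustness to covariate
dependence, survey weighting (the emulated survey's two-stage cluster design
is ignored, as in the source analysis), item non-response, or measurement
error. The generator validates the machinery, not the substantive published
coefficient values, which derive from micro-data that are not distributed.

## Recovery studies

`run_recovery_study` repeats generate → fit → summarize over R replicates
(replicate r reseeds both generator and sampler with `seed + r`), keeping
only replicates that pass the convergence gate (a study with more than 20%
gate failures is flagged unreliable). It reports per-slope bias, RMSE and
empirical coverage of the equal-tailed intervals. Replicate fits use
shortened chains (2 × 1500, warmup 750) on a small three-covariate model
(N = 400): coverage assessment needs replicates more than it needs long
chains, while the full protocol remains the single-fit default.

## Known limitations

- With a 0.6% binary covariate in N = 640 rows (2–4 carriers), the
  corresponding slope is weakly identified and frequently quasi-separated;
  its posterior SD is then bounded by the prior, not the data, so the
  10%-of-prior-SD rule cannot hold for that coefficient under the default
  synthetic conditions. The check reports the honest ratio.
- The sampler is single-threaded pure NumPy; a full-protocol 44-parameter
  fit takes on the order of a minute, and the default recovery study a few
  minutes.
- Intercept-only hierarchy with a logit link: no random slopes, alternative
  link functions, or survey weights.
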