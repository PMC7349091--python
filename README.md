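# hierlogit

Bayesian varying-intercept logistic regression for survey outcomes, with a
from-scratch No-U-Turn HMC sampler, convergence-gated reporting, and a
synthetic survey generator for end-to-end validation.

The motivating application is epidemiological: modeling which adolescent
smokers *intend to quit smoking* from a school-based survey (grades 7–9),
where responses cluster by grade. The model is a partial-pooling logit

```
y_ij ~ Bernoulli(pi_ij)
logit(pi_ij) = alpha_0j + Σ_k beta_k x_ik
alpha_0j     = alpha_0 + mu_j,    mu_j ~ N(0, sigma_mu²)
beta_k ~ N(0, 10)   alpha_0 ~ N(0, 10)   sigma_mu ~ half-Cauchy(0, 2.5)
```

so each grade gets its own intercept, shrunk toward the overall mean.
Slopes are reported as odds ratios with equal-tailed 95% credible
intervals; a slope is "significant" when its interval excludes 1. Because
the original survey micro-data are not distributable, the package ships a
generator that emulates the published sample (N = 640, grade shares
0.398/0.325/0.277, ~40 covariates at their published marginal means,
outcome prevalence 63.3%), which makes every stage — generation, sampling,
diagnostics, reporting — testable and lets recovery studies verify that the
credible intervals earn their nominal coverage.

Audience: applied biostatisticians and health-economics researchers who
want a transparent, dependency-light reference implementation of this
analysis rather than a black-box probabilistic-programming stack.

## Worked example

Simulate a small survey, fit it, and check convergence (this is
`examples/02_fit_hierarchical_logit.py` and `03_convergence_diagnostics.py`):

```python
import hierlogit as hl

data, truth = hl.generate_dataset(hl.recovery_generator_config(n=400, seed=3))
draws = hl.run_chains(data, hl.PriorSpec(), hl.short_chain_config(seed=3))
```

```
chains: 2, kept draws/chain: 750
divergent transitions: 0, mean acceptance: 0.85
           parameter   mean    sd  q_low  q_high  truth
 beta[x_binary_half]  0.615 0.245  0.118   1.127   0.80
beta[x_binary_third] -0.675 0.254 -1.171  -0.165  -0.50
       beta[x_count]  0.264 0.108  0.053   0.484   0.25
```

Every posterior mean sits within its 95% interval of the generating value;
over repeated simulations those intervals cover the truth ~95% of the time
(that is exactly what the recovery study in `examples/05` measures). The
diagnostics example prints the convergence gate that all reporting is
conditioned on:

```
convergence gate PASS: max rhat 1.0291 vs threshold 1.10
           parameter  rhat  geweke_z     ess
              alpha0 1.001    -1.527 281.036
            sigma_mu 1.029     2.632 130.115
 beta[x_binary_half] 1.013     1.950 295.544
...
weak-prior rule (posterior SD < 10% of prior SD): holds; max ratio 0.041
```

`rhat` is the split-chain Gelman–Rubin statistic (gate: < 1.10 for every
parameter), `geweke_z` compares early vs late chain means, and `ess` is the
effective number of independent draws. The odds-ratio report
(`examples/04`) turns slopes into `odds_ratio = exp(E[beta])`,
`pct_effect = (OR − 1) × 100` (percent change in the odds of the outcome
per unit covariate) and the significance flag.

A thin CLI wraps the same calls:

```bash
hierlogit simulate --out out/ --seed 1          # survey.csv + truth.csv
hierlogit fit --input out/survey.csv --out fit/ # draws, diagnostics, report
hierlogit recover -R 50 --out rec/              # coverage study
```

Exit codes: 0 converged, 3 fit done but gate failed, ≥ 4 validation or
runtime errors.

## Layout

- `src/hierlogit/model.py` — data container, priors, log-posterior and its
  analytic gradient (non-centered parameterization, unconstrained scale)
- `src/hierlogit/sampler.py` — leapfrog, NUTS tree doubling, dual-averaging
  step-size and diagonal-metric adaptation, multi-chain driver
- `src/hierlogit/diagnostics.py` — split Gelman–Rubin, Geweke, ESS,
  convergence gate, weak-prior check
- `src/hierlogit/summaries.py` — coefficient and odds-ratio tables, gated
  report rendering
- `src/hierlogit/simulate.py` — the survey generator and intercept
  calibration
- `src/hierlogit/recovery.py`, `config.py`, `cli.py` — recovery harness,
  run configuration, CLI
- `docs/methods.md` — modeling and numerical choices in detail

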