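# loosematch

Monte-Carlo comparison of **unconditional** and **conditional** logistic
regression for age-matched case-control data.

Matching cases to controls on demographic variables such as age is routine in
case-control studies, and the folklore rule says matched data require a
matched analysis — conditional logistic regression. When the matching is
*loose* (a case could be rematched to many other controls without changing
the association), the sparse-data problem that motivates conditioning largely
disappears, and ordinary logistic regression with the matching variable as a
covariate is a candidate analysis. This package is for biostatisticians and
epidemiologists who want to study, by simulation, when the unmatched analysis
is safe and when the *matching distortion* — matched controls inheriting the
case's exposure through the matching variable — breaks it.

## Model

A source population has binary exposure `x_e ~ Bernoulli(p_e)` and age
`x_a ~ N(mu_i, sigma^2)` given exposure group `i`, floored to whole years.
Disease risk is logistic,

    logit pi(x_e, x_a) = beta0 + beta_e * x_e + beta_a * x_a,

with `beta0` calibrated by root search so the population prevalence equals
`K` (0.10 in the study conditions). Cases are forward-simulated; each case of
age `u` receives `k` controls drawn *exactly* from the conditional law

    P(x_e = i, x_a = j | y = 0, |j - u| <= d)
        ∝ P(x_e = i) [Phi(j+1 | mu_i) - Phi(j | mu_i)] [1 - pi(i, j)],

the analytic control distribution inside the age caliper `d` for an
unlimited population. Every replicate is analyzed twice:

* **unconditional**: logistic regression of outcome on intercept + exposure
  + age (matching sets ignored);
* **conditional**: the stratum conditional likelihood
  `sum_s [eta_case - log sum_j exp(eta_j)]`, eliminating the per-set
  intercepts (implemented from scratch, Newton-Raphson batched across
  replicates).

Models are compared by type I error / power for the Wald test of
`H0: beta_e = 0`, by bias and percent bias of `beta_e_hat`, and by the
dispersion-based 95% CI width `2 * z_0.975 * SD(beta_e_hat)` across
replicates. The Mantel-Haenszel stratified odds ratio over per-stratum 2x2
tables is provided as the classical cross-check.

## Worked example

```python
import numpy as np
from loosematch import Scenario, simulate_matched_dataset, fit_unconditional, fit_conditional

# strong confounding: exposed subjects average 20 years older than unexposed
sc = Scenario(mu0=50.0, or_exposure=1.5, or_age_per10=2.0, caliper_d=2, n_cases=900)
ds = simulate_matched_dataset(sc, np.random.default_rng(20180302))
for res in (fit_unconditional(ds), fit_conditional(ds)):
    print(res.model, round(res.beta_e_hat, 4), round(res.se, 4))
```

prints (true `beta_e = ln 1.5 = 0.4055`):

```
unconditional 0.1832 0.1326
conditional 0.2237 0.1409
```

One dataset is noisy, but the ordering is the systematic story: the
unconditional estimate sits below the conditional one because matched
controls tend to share the case's exposure (in this dataset the within-pair
exposure concordance is 0.77 against about 0.58 for independent controls).
Averaged over 1,000 replicates (`analysis/03_run_study_grid.py`) the
unconditional model underestimates `beta_e` by about −11% at the 20-year age
gap while the conditional model stays within ±2%; at a 5-year gap both are
unbiased and equally powerful.

The numbered drivers under `analysis/` walk the full study: `01` calibrates
the intercepts, `02` dissects one dataset (including the Mantel-Haenszel
check), `03` runs the scenario grid and `04` renders the study-style tables.
A `loosematch` CLI (`run`, `simulate`, `fit`, `tables`) wraps the same
functions.

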