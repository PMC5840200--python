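# Methods

## The question

In an individually matched case-control study, each case is matched to `k`
controls whose age lies within ±`d` whole years. Conditional logistic
regression is the textbook analysis because the matching sets are tiny
strata: an unconditional fit with one intercept per stratum would suffer the
sparse-data (Neyman-Scott) bias. But when matching is on a single demographic
variable, strata of similar age are statistically interchangeable — *loose
matching* — and an ordinary logistic regression adjusting for age as a
covariate is a plausible, cheaper analysis. The package quantifies, by
simulation, when the two analyses agree and how the unconditional one fails
when the exposure is strongly age-linked.

## Population and disease model

* Exposure: `x_e ~ Bernoulli(p_e)`, default `p_e = 0.3`.
* Age: `N(mu1, sigma^2)` for exposed, `N(mu0, sigma^2)` for unexposed,
  default `mu1 = 70`, `mu0 ∈ {65, 60, 50}`, `sigma = 10` (years). Simulated
  ages are **floored** to whole years — age at last birthday. (The
  alternative reading, ceiling, shifts every age by one year; the shift is
  absorbed by the intercept calibration and alters no model comparison.)
  All probability statements therefore live on the integer-age grid with
  bin mass `Phi(j+1) - Phi(j)`.
* Risk: `logit pi = beta0 + beta_e x_e + beta_a x_a` with age in years and
  `beta_a = ln(OR_age10)/10` when specified through the conventional
  per-10-year odds ratio. No exposure-age interaction.
* Prevalence: `beta0` solves `E[pi] = K` (default `K = 0.1`) where the
  expectation runs over the exposure mixture and the *discrete* integer-age
  bins — the same discretization the simulator uses, keeping calibration and
  generation internally consistent. The prevalence is strictly increasing
  and continuous in `beta0`, so a bracketing Brent search with an expanding
  initial bracket is guaranteed; the round-trip tolerance is 1e-8.
* Age grid: `[min(mu) - 8 sigma, max(mu) + 8 sigma]`, not truncated at zero.
  With the study means the sub-zero mass is < 1e-7; tails beyond 8 sigma
  contribute < 1e-10 and the grid is rejected if its mass deficit exceeds
  1e-8.

## Data generation

Cases are forward-simulated — exposure, then age, then a Bernoulli disease
indicator — keeping subjects until `n1` cases accumulate (generation is
batched for throughput; the batch size only affects speed, not law). The
source population is treated as unlimited, so controls are not drawn from a
finite pool: for a case of age `u`, each of its `k` controls is an i.i.d.
draw from the analytic conditional distribution of (exposure, age) among
controls aged within `[u-d, u+d]` — a `2 (2d+1)`-cell discrete distribution
proportional to `P(x_e=i) * binmass(j | mu_i) * (1 - pi(i,j))`. This is
distributionally identical to rejection-matching against an infinite control
pool (the test suite verifies the equivalence by brute force) and removes
failed-match handling entirely. A per-age table of cell CDFs makes sampling a
vectorized inverse-CDF lookup.

Reproducibility contract: replicate `r` of a scenario uses the independent
substream `SeedSequence([root_seed, scenario_key, r])`, with the scenario key
a stable CRC-32 of the scenario id. Results are therefore byte-identical
across chunk sizes, execution orders and worker counts.

## Fitting

Both likelihoods are maximized by Newton-Raphson with analytic gradient and
Hessian to a score max-norm below 1e-8, implemented against batched arrays
`(replicates, subjects, covariates)` so a whole Monte-Carlo chunk (default
512 replicates) is fitted in one pass. Standard errors are the observed
information at the MLE (identical to expected information for the
canonical-link logistic). P-values are two-sided Wald against the standard
normal.

Conditional model specifics:

* Interval-matched age is retained as a covariate (matching makes cases and
  controls similar on exposure, not only age, so the matching variable must
  stay in the model); exactly-matched variables and the stratum intercept
  cancel out of the conditional likelihood.
* Under `d = 0` the within-stratum age variance is exactly zero and the age
  coefficient is structurally non-identified: the term is dropped
  automatically and recorded on the fit result, which keeps either
  bookkeeping convention comparable.
* Divergence of `||beta||` beyond 15 (monotone likelihood — e.g. all
  discordant pairs pointing one way) and singular information are flagged as
  non-convergence, never as estimates.

Non-converged replicates (separation in either model) are excluded from
aggregation with a logged count; a cell whose exclusions exceed 1% of
replicates is flagged in the manifest. In the study conditions (400-900
matched sets, `p_e = 0.3`) exclusions are essentially absent.

## Metrics

* Rejection rate at `alpha = 0.05` (type I error under `OR_e = 1`, power
  under `OR_e = 1.5`, true `beta_e = ln 1.5 ≈ 0.4055`).
* Bias `mean(beta_hat) - beta_e`; percent bias `100 * bias / beta_e`, which
  is undefined under the null where plain bias is reported instead.
* CI width `2 * z_0.975 * SD(beta_hat)` with the `n_r - 1` SD across
  replicates — a *dispersion-based* width, deliberately not the average of
  per-replicate Wald widths. The mean Wald width is emitted as a secondary
  diagnostic column since that is what "CI width" conventionally means; in
  practice the two agree to ~0.02 here.
* Acceptance band for an empirical type-I error:
  `alpha ± z_0.975 sqrt(alpha(1-alpha)/n_r)` — (0.0457, 0.0543) at 10,000
  replicates.

## Study grid and problem sizes

The grid crosses `mu0 ∈ {65, 60, 50}` × `OR_age10 ∈ {1, 1.5, 2, 3}` ×
`d ∈ {0..3}` × `k ∈ {1..4}` × {null, alternative}; the study-facing default
fixes `k = 1` (96 cells), since the comparison is insensitive to the
matching ratio. Matched-set counts are tied to the mean-age gap — 400, 500,
900 sets for gaps of 5, 10, 20 years — sized for roughly 80% power.
Replicates default to 10,000 under the null and 1,000 under the
alternative. The `analysis/03` driver defaults to the two informative panels
(`mu0 ∈ {65, 50}`, `OR_age10 ∈ {1, 3}`) at 2,000/500 replicates, which shows
every qualitative conclusion in a few minutes; `--full` runs the complete
grid at the default counts. Monte-Carlo tolerances everywhere scale as
`3 sqrt(p(1-p)/n_r)`.

## What the generator does and does not emulate

It emulates: a rare-ish disease (10% prevalence), a common exposure (30%),
normally distributed ages diverging between exposure groups, exact caliper
matching with guaranteed success, and no model misspecification. It does
**not** emulate finite control pools or failed matches, frequency matching,
additional matching variables (sex, center), exposure-age interaction,
measurement error, or non-normal age distributions. Passing tests therefore
speak to the *statistical* comparison of the two estimators under clean
matching, not to the practical matching process itself.

## Known limitations

* Exact conditional inference, Firth's correction for separation and
  multiple cases per stratum are out of scope; separation is only detected
  and excluded.
* The fitting interface accepts arbitrary extra covariates, but the
  simulator only exercises exposure + age.
* With `d = 0` and `k = 1` the conditional fit reduces to the discordant-pair
  estimator `ln(n10/n01)`; its SE is infinite when either discordant count
  is zero — impossible in practice at the study sizes, flagged if it occurs.
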