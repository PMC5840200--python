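"""Source-population disease model for the matched case-control simulation.

The population has a binary exposure with frequency ``p_e`` and an age that is
normally distributed given exposure status: N(mu0, sigma^2) for the unexposed,
N(mu1, sigma^2) for the exposed.  Simulated ages are floored to integer years
(age at last birthday), so all probability calculations work on the discrete
grid of integer ages, with bin mass Phi(j+1) - Phi(j).

Disease risk follows a logistic model in exposure and age (in years),

    logit pi = beta0 + beta_e * x_e + beta_a * x_a,

and the intercept beta0 is calibrated by root search so that the population
disease prevalence equals a target K (0.10 in the study conditions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

__all__ = [
    "PopulationSpec",
    "DiseaseModel",
    "AgeGrid",
    "logistic_risk",
    "age_bin_prob",
    "population_prevalence",
    "calibrate_intercept",
]

#: half-width of the discrete age grid, in units of sigma
_GRID_SD_SPAN = 8.0

#: tolerance on |prevalence - K| for intercept calibration
_CALIBRATION_TOL = 1e-8


@dataclass(frozen=True)
class PopulationSpec:
    """Exposure frequency and exposure-specific age distributions.

    Parameters
    ----------
    p_e : float
        Proportion exposed, in (0, 1).
    mu0, mu1 : float
        Mean age (years) of unexposed and exposed subjects.
    sigma : float
        SD of age (years), shared by both exposure groups.
    """

    p_e: float
    mu0: float
    mu1: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_e < 1.0:
            raise ValueError(f"p_e must be in (0, 1), got {self.p_e}")
        if not self.sigma > 0.0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not (math.isfinite(self.mu0) and math.isfinite(self.mu1)):
            raise ValueError("mu0 and mu1 must be finite")

    def age_mean(self, exposed: int) -> float:
        return self.mu1 if exposed else self.mu0


@dataclass(frozen=True)
class DiseaseModel:
    """Logistic disease-risk coefficients and the target prevalence.

    ``beta_a`` is the log odds ratio per one-year age increase; use
    :meth:`from_odds_ratios` to construct from the conventional per-10-year
    odds ratio.
    """

    beta0: float
    beta_e: float
    beta_a: float
    prevalence: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        for name in ("beta0", "beta_e", "beta_a"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def from_odds_ratios(
        cls,
        pop: PopulationSpec,
        or_exposure: float,
        or_age_per10: float,
        prevalence: float = 0.1,
    ) -> "DiseaseModel":
        """Build a model with beta0 calibrated to the target prevalence."""
        beta_e = math.log(or_exposure)
        beta_a = math.log(or_age_per10) / 10.0
        beta0 = calibrate_intercept(pop, beta_e, beta_a, prevalence)
        return cls(beta0=beta0, beta_e=beta_e, beta_a=beta_a, prevalence=prevalence)


def logistic_risk(model: DiseaseModel, x_e, x_a):
    """Disease probability pi(x_e, x_a) = expit(beta0 + beta_e x_e + beta_a x_a).

    Accepts scalars or arrays; saturates smoothly at extreme linear predictors.
    """
    eta = model.beta0 + model.beta_e * np.asarray(x_e) + model.beta_a * np.asarray(x_a)
    return expit(eta)


def age_bin_prob(j, mu: float, sigma: float):
    """P(floor(age) = j) for age ~ N(mu, sigma^2): Phi(j+1) - Phi(j)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    j = np.asarray(j, dtype=float)
    return norm.cdf(j + 1.0, loc=mu, scale=sigma) - norm.cdf(j, loc=mu, scale=sigma)


@dataclass(frozen=True)
class AgeGrid:
    """Discrete integer-age support with per-exposure-group bin probabilities.

    ``probs[i]`` is P(floor(age) = ages) in exposure group i in {0, 1}.  The
    grid spans at least 8 sigma either side of both group means, so each row
    sums to 1 within 1e-10.  Ages may be negative in principle; with the study
    means (>= 50) and sigma = 10 the mass below zero is negligible.
    """

    ages: np.ndarray  # (n_ages,) integer
    probs: np.ndarray  # (2, n_ages), rows sum to ~1

    @classmethod
    def from_population(cls, pop: PopulationSpec, span_sd: float = _GRID_SD_SPAN) -> "AgeGrid":
        lo = math.floor(min(pop.mu0, pop.mu1) - span_sd * pop.sigma)
        hi = math.ceil(max(pop.mu0, pop.mu1) + span_sd * pop.sigma)
        ages = np.arange(lo, hi + 1)
        probs = np.stack(
            [age_bin_prob(ages, pop.mu0, pop.sigma), age_bin_prob(ages, pop.mu1, pop.sigma)]
        )
        return cls(ages=ages, probs=probs)

    def mass_deficit(self) -> float:
        return float(np.max(np.abs(1.0 - self.probs.sum(axis=1))))


def population_prevalence(
    pop: PopulationSpec, model: DiseaseModel, grid: AgeGrid | None = None
) -> float:
    """Marginal disease probability over the discrete-age population.

    Sums P(x_e = i) * P(floor(age) = j | i) * pi(i, j) over both exposure
    groups and the full age grid.  Strictly increasing in beta0.
    """
    if grid is None:
        grid = AgeGrid.from_population(pop)
    if grid.mass_deficit() > 1e-8:
        raise ValueError("age grid too narrow: probability mass deficit exceeds 1e-8")
    p_exposure = np.array([1.0 - pop.p_e, pop.p_e])
    risk = np.stack(
        [logistic_risk(model, i, grid.ages) for i in (0, 1)]
    )  # (2, n_ages)
    return float(np.sum(p_exposure[:, None] * grid.probs * risk))


def calibrate_intercept(
    pop: PopulationSpec, beta_e: float, beta_a: float, prevalence: float = 0.1
) -> float:
    """Find beta0 such that the population prevalence equals the target.

    The prevalence is continuous and strictly increasing in beta0, so a
    bracketing root search converges; the bracket is expanded until it
    straddles the target.  With beta_e = beta_a = 0 the answer is the closed
    form logit(K).
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    if beta_e == 0.0 and beta_a == 0.0:
        return float(logit(prevalence))

    grid = AgeGrid.from_population(pop)

    def deficit(beta0: float) -> float:
        model = DiseaseModel(
            beta0=beta0, beta_e=beta_e, beta_a=beta_a, prevalence=prevalence
        )
        return population_prevalence(pop, model, grid) - prevalence

    lo = hi = float(logit(prevalence)) - beta_e * pop.p_e - beta_a * (
        pop.p_e * pop.mu1 + (1 - pop.p_e) * pop.mu0
    )
    step = 1.0
    while deficit(lo) > 0.0:
        lo -= step
        step *= 2.0
    step = 1.0
    while deficit(hi) < 0.0:
        hi += step
        step *= 2.0
    assert lo < hi, "failed to bracket the calibration root"
    beta0 = brentq(deficit, lo, hi, xtol=1e-12, rtol=8.9e-16)
    assert abs(deficit(beta0)) < _CALIBRATION_TOL
    return float(beta0)
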