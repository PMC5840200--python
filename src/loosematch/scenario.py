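"""Scenario specification: one cell of the simulation study.

A scenario bundles the source population, the (calibrated) disease model and
the matching design, and is what the simulator and the replicate loop consume.
Scenarios serialize to a flat key-value mapping (YAML/CLI flags) with keys
p_e, mu0, mu1, sigma, or_exposure, or_age_per10, prevalence, caliper_d,
ratio_k, n_cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

from .population import DiseaseModel, PopulationSpec

__all__ = ["Scenario", "SCENARIO_KEYS"]

SCENARIO_KEYS = (
    "p_e",
    "mu0",
    "mu1",
    "sigma",
    "or_exposure",
    "or_age_per10",
    "prevalence",
    "caliper_d",
    "ratio_k",
    "n_cases",
)


@dataclass(frozen=True)
class Scenario:
    """One simulation-study cell.

    Defaults are the study conditions: 30% exposure frequency, exposed mean
    age 70, age SD 10, disease prevalence 10%, 1:1 matching.
    """

    mu0: float
    or_exposure: float
    or_age_per10: float
    caliper_d: int
    n_cases: int
    ratio_k: int = 1
    p_e: float = 0.3
    mu1: float = 70.0
    sigma: float = 10.0
    prevalence: float = 0.1

    def __post_init__(self) -> None:
        if self.caliper_d < 0 or int(self.caliper_d) != self.caliper_d:
            raise ValueError("caliper_d must be a non-negative integer")
        if self.ratio_k < 1 or int(self.ratio_k) != self.ratio_k:
            raise ValueError("ratio_k must be a positive integer")
        if self.n_cases < 2:
            raise ValueError("n_cases must be at least 2")
        if self.or_exposure <= 0 or self.or_age_per10 <= 0:
            raise ValueError("odds ratios must be positive")

    @cached_property
    def population(self) -> PopulationSpec:
        return PopulationSpec(p_e=self.p_e, mu0=self.mu0, mu1=self.mu1, sigma=self.sigma)

    @cached_property
    def disease_model(self) -> DiseaseModel:
        """Disease model with the intercept calibrated to the target prevalence."""
        return DiseaseModel.from_odds_ratios(
            self.population, self.or_exposure, self.or_age_per10, self.prevalence
        )

    @property
    def beta_e_true(self) -> float:
        return math.log(self.or_exposure)

    @property
    def is_null(self) -> bool:
        return self.or_exposure == 1.0

    @property
    def scenario_id(self) -> str:
        return (
            f"mu0={self.mu0:g}_orage{self.or_age_per10:g}_ore{self.or_exposure:g}"
            f"_d{self.caliper_d}_k{self.ratio_k}_n{self.n_cases}"
        )

    def to_config(self) -> dict:
        return {k: getattr(self, k) for k in SCENARIO_KEYS}

    @classmethod
    def from_config(cls, config: dict) -> "Scenario":
        unknown = set(config) - set(SCENARIO_KEYS)
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        kwargs = dict(config)
        for key in ("caliper_d", "ratio_k", "n_cases"):
            if key in kwargs:
                kwargs[key] = int(kwargs[key])
        return cls(**kwargs)
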