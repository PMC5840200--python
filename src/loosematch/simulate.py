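"""Forward simulation of age-matched case-control data.

Cases are generated by forward simulation from the source population —
exposure ~ Bernoulli(p_e), age ~ floor(Normal(mu_i, sigma^2)), disease ~
Bernoulli(pi) — keeping subjects until the requested number of cases is
collected (the source population is unlimited).

Each case's k matched controls are then drawn *exactly* from the joint
conditional distribution of (exposure, age) among controls whose age lies in
the caliper [u - d, u + d] around the case age u:

    P(x_e = i, x_a = j | y = 0, x_a in caliper)
        ∝ P(x_e = i) [Phi(j+1 | mu_i) - Phi(j | mu_i)] [1 - pi(i, j)],

a discrete distribution over 2 * (2d + 1) cells.  Sampling from the analytic
cells is distributionally identical to rejection-sampling controls from the
full population and keeping those inside the caliper, but needs no failed
match handling.  Controls are i.i.d. draws (infinite population, so no
without-replacement correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import DiseaseModel, PopulationSpec, age_bin_prob, logistic_risk
from .scenario import Scenario

__all__ = [
    "MatchingDesign",
    "Subject",
    "MatchedDataset",
    "ControlJointDistribution",
    "simulate_cases",
    "control_joint_distribution",
    "sample_matched_controls",
    "simulate_matched_dataset",
]


@dataclass(frozen=True)
class MatchingDesign:
    """Matching ratio k, age caliper d (whole years) and number of cases."""

    k: int
    d: int
    n1: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.n1 < 2:
            raise ValueError("n1 must be >= 2")


@dataclass(frozen=True)
class Subject:
    exposure: int
    age: int
    outcome: int
    stratum_id: int


@dataclass
class MatchedDataset:
    """Strata of one case plus k interval-matched controls.

    Stored as flat parallel arrays (one row per subject) in stratum-major
    order with the case first in each stratum; ``to_frame`` gives the long
    CSV layout (stratum_id, outcome, exposure, age) the fitting routines
    consume.
    """

    stratum_id: np.ndarray
    outcome: np.ndarray
    exposure: np.ndarray
    age: np.ndarray
    design: MatchingDesign
    scenario: Scenario | None = None

    def __post_init__(self) -> None:
        n = len(self.stratum_id)
        if not (len(self.outcome) == len(self.exposure) == len(self.age) == n):
            raise ValueError("field arrays must have equal length")

    @property
    def n_strata(self) -> int:
        return self.design.n1

    def validate(self) -> None:
        """Check the matched-set invariants (1 case + k controls, caliper)."""
        expo, ages = self.to_stratum_arrays()
        df = self.to_frame()
        counts = df.groupby("stratum_id")["outcome"].agg(["sum", "size"])
        if not (counts["sum"] == 1).all():
            raise ValueError("every stratum must contain exactly one case")
        if not (counts["size"] == self.design.k + 1).all():
            raise ValueError(f"every stratum must contain {self.design.k + 1} subjects")
        case_age = ages[:, 0][:, None]
        if np.abs(ages[:, 1:] - case_age).max(initial=0) > self.design.d:
            raise ValueError("control age outside the matching caliper")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum_id": self.stratum_id,
                "outcome": self.outcome,
                "exposure": self.exposure,
                "age": self.age,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scenario: Scenario | None = None) -> "MatchedDataset":
        df = df.sort_values(["stratum_id", "outcome"], ascending=[True, False], kind="stable")
        sizes = df.groupby("stratum_id").size()
        if sizes.nunique() != 1:
            raise ValueError("all strata must have the same size")
        k = int(sizes.iloc[0]) - 1
        n1 = len(sizes)
        ages = df["age"].to_numpy()
        case_ages = df.loc[df["outcome"] == 1].set_index("stratum_id")["age"]
        diffs = np.abs(ages - case_ages.loc[df["stratum_id"]].to_numpy())
        design = MatchingDesign(k=max(k, 1), d=int(diffs.max(initial=0)), n1=n1)
        return cls(
            stratum_id=df["stratum_id"].to_numpy(),
            outcome=df["outcome"].to_numpy(),
            exposure=df["exposure"].to_numpy(),
            age=df["age"].to_numpy(),
            design=design,
            scenario=scenario,
        )

    @classmethod
    def from_csv(cls, path) -> "MatchedDataset":
        return cls.from_frame(pd.read_csv(path))

    def to_stratum_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(exposure, age) reshaped to (n1, k+1) with the case in column 0.

        Robust to row order: rows are regrouped by stratum id with the case
        sorted first, so permuting subjects never changes the result.
        """
        order = np.lexsort((-self.outcome, self.stratum_id))
        m = self.design.k + 1
        expo = self.exposure[order].reshape(self.design.n1, m)
        ages = self.age[order].reshape(self.design.n1, m)
        return expo, ages


@dataclass(frozen=True)
class ControlJointDistribution:
    """Joint law of (exposure, age) for a matched control of a case aged u.

    ``probs[i, j]`` is the probability that the control has exposure i and
    age ``ages[j]``; the 2 * (2d + 1) cells sum to 1.
    """

    case_age: int
    d: int
    ages: np.ndarray  # (2d+1,)
    probs: np.ndarray  # (2, 2d+1)

    def exposure_marginal(self) -> np.ndarray:
        return self.probs.sum(axis=1)

    def age_marginal(self) -> np.ndarray:
        return self.probs.sum(axis=0)


def simulate_cases(
    pop: PopulationSpec,
    model: DiseaseModel,
    n1: int,
    rng: np.random.Generator,
    _batch_scale: float = 1.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-simulate subjects and keep the first n1 cases.

    Returns (exposure, age) integer arrays of length n1.  Generation proceeds
    in batches sized from the calibrated prevalence and repeats until enough
    cases accumulate, mirroring sampling from an unlimited population.
    """
    exposures: list[np.ndarray] = []
    ages: list[np.ndarray] = []
    collected = 0
    while collected < n1:
        need = n1 - collected
        batch = int(_batch_scale * need / model.prevalence) + 64
        x_e = (rng.random(batch) < pop.p_e).astype(np.int64)
        mu = np.where(x_e == 1, pop.mu1, pop.mu0)
        x_a = np.floor(rng.normal(mu, pop.sigma)).astype(np.int64)
        is_case = rng.random(batch) < logistic_risk(model, x_e, x_a)
        exposures.append(x_e[is_case])
        ages.append(x_a[is_case])
        collected += int(is_case.sum())
    exposure = np.concatenate(exposures)[:n1]
    age = np.concatenate(ages)[:n1]
    return exposure, age


def control_joint_distribution(
    u: int, d: int, pop: PopulationSpec, model: DiseaseModel
) -> ControlJointDistribution:
    """Analytic control distribution over the 2 * (2d + 1) caliper cells."""
    ages = np.arange(u - d, u + d + 1)
    p_exposure = np.array([1.0 - pop.p_e, pop.p_e])
    weights = np.empty((2, 2 * d + 1))
    for i in (0, 1):
        bin_mass = age_bin_prob(ages, pop.age_mean(i), pop.sigma)
        weights[i] = p_exposure[i] * bin_mass * (1.0 - logistic_risk(model, i, ages))
    total = weights.sum()
    assert total > 0.0, "degenerate control distribution: all cell weights zero"
    return ControlJointDistribution(case_age=int(u), d=int(d), ages=ages, probs=weights / total)


def sample_matched_controls(
    u: int,
    design: MatchingDesign,
    pop: PopulationSpec,
    model: DiseaseModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw k i.i.d. controls for a case aged u; returns (exposure, age)."""
    dist = control_joint_distribution(u, design.d, pop, model)
    cells = rng.choice(dist.probs.size, size=design.k, p=dist.probs.ravel())
    n_ages = 2 * design.d + 1
    exposure = cells // n_ages
    age = dist.ages[cells % n_ages]
    return exposure.astype(np.int64), age.astype(np.int64)


class _ControlSampler:
    """Vectorized control sampler with the caliper cells precomputed per age.

    For every integer case age u on an extended grid the 2 * (2d + 1) cell
    probabilities of the analytic control distribution are tabulated once;
    sampling for a whole vector of case ages is then a batched inverse-CDF
    lookup.  Numerically identical in law to ``sample_matched_controls``.
    """

    def __init__(self, pop: PopulationSpec, model: DiseaseModel, d: int, span_sd: float = 9.0):
        self.d = d
        lo = int(np.floor(min(pop.mu0, pop.mu1) - span_sd * pop.sigma)) - d
        hi = int(np.ceil(max(pop.mu0, pop.mu1) + span_sd * pop.sigma)) + d
        self.lo = lo
        grid = np.arange(lo - d, hi + d + 1)
        p_exposure = np.array([1.0 - pop.p_e, pop.p_e])
        # per-age ingredients of the cell weight, on the extended grid
        w = np.stack(
            [
                p_exposure[i]
                * age_bin_prob(grid, pop.age_mean(i), pop.sigma)
                * (1.0 - logistic_risk(model, i, grid))
                for i in (0, 1)
            ]
        )  # (2, len(grid))
        n_u = hi - lo + 1
        offs = np.arange(-d, d + 1)
        win = (np.arange(n_u)[:, None] + d) + offs[None, :]  # indices into grid
        cells = np.concatenate([w[0][win], w[1][win]], axis=1)  # (n_u, 2*(2d+1))
        # rows in the far tails can underflow to zero total mass; they are
        # unreachable for case ages inside the grid and stay NaN on purpose
        with np.errstate(invalid="ignore", divide="ignore"):
            cells /= cells.sum(axis=1, keepdims=True)
        self.cum = np.cumsum(cells, axis=1)
        self.n_ages = 2 * d + 1

    def sample(
        self, case_ages: np.ndarray, k: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw k controls per case; returns (exposure, age) of shape (n1, k)."""
        idx = case_ages - self.lo
        assert idx.min() >= 0 and idx.max() < self.cum.shape[0], "case age outside sampler grid"
        cum = self.cum[idx]  # (n1, ncells)
        unif = rng.random((len(case_ages), k))
        cell = (cum[:, None, :] < unif[:, :, None]).sum(axis=2)
        exposure = cell // self.n_ages
        age = case_ages[:, None] + (cell % self.n_ages) - self.d
        return exposure.astype(np.int64), age.astype(np.int64)


def simulate_matched_dataset(
    scenario: Scenario,
    rng: np.random.Generator,
    _sampler: _ControlSampler | None = None,
) -> MatchedDataset:
    """Simulate one matched case-control dataset for a scenario.

    Cases come from the forward simulation; each case's k controls are drawn
    from the analytic caliper distribution keyed to that case's age.
    """
    pop, model = scenario.population, scenario.disease_model
    design = MatchingDesign(k=scenario.ratio_k, d=scenario.caliper_d, n1=scenario.n_cases)
    case_expo, case_age = simulate_cases(pop, model, design.n1, rng)
    sampler = _sampler if _sampler is not None else _ControlSampler(pop, model, design.d)
    ctrl_expo, ctrl_age = sampler.sample(case_age, design.k, rng)

    m = design.k + 1
    exposure = np.column_stack([case_expo, ctrl_expo]).reshape(-1)
    age = np.column_stack([case_age, ctrl_age]).reshape(-1)
    outcome = np.tile(np.r_[1, np.zeros(design.k, dtype=np.int64)], design.n1)
    stratum_id = np.repeat(np.arange(1, design.n1 + 1), m)
    return MatchedDataset(
        stratum_id=stratum_id,
        outcome=outcome,
        exposure=exposure,
        age=age,
        design=design,
        scenario=scenario,
    )
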