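"""Unconditional and conditional logistic fits, Wald p-values, MH odds ratio.

Independent oracles: statsmodels Logit / ConditionalLogit as general-purpose
cross-solvers, the classical pair-difference equivalence for 1:1 conditional
fits, exhaustive enumeration of the stratum conditional likelihood, and grid
search of the likelihood surface.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit

import statsmodels.api as sm
from statsmodels.discrete.conditional_models import ConditionalLogit

from loosematch import (
    CovariateSpec,
    MatchedDataset,
    Scenario,
    StratumTable,
    conditional_loglik,
    fit_conditional,
    fit_unconditional,
    mantel_haenszel_or,
    simulate_matched_dataset,
    wald_p,
)


def _pooled_2x2_dataset(a, b, c, d):
    """Long-format frame for a single 2x2 table (age constant)."""
    df = pd.DataFrame(
        {
            "outcome": [1] * a + [0] * b + [1] * c + [0] * d,
            "exposure": [1] * (a + b) + [0] * (c + d),
            "age": 60,
            "stratum_id": 1,
        }
    )
    return df


def _random_small_frame(rng, n=60):
    age = rng.integers(40, 80, n)
    expo = rng.integers(0, 2, n)
    eta = -1.0 + 0.5 * expo + 0.02 * (age - 60)
    y = (rng.random(n) < expit(eta)).astype(int)
    return pd.DataFrame({"outcome": y, "exposure": expo, "age": age, "stratum_id": 1})


class TestWaldP:
    def test_zero_statistic_gives_one(self):
        assert wald_p(0.0, 1.0) == pytest.approx(1.0)

    def test_normal_quantile(self):
        assert wald_p(1.959964, 1.0) == pytest.approx(0.05, abs=1e-6)

    def test_unit_statistic_cdf_oracle(self):
        assert wald_p(0.5, 0.5) == pytest.approx(0.31731050786291415, rel=1e-9)

    def test_rejects_nonpositive_se(self):
        with pytest.raises(ValueError):
            wald_p(1.0, 0.0)

    @given(st.floats(0.01, 10.0), st.floats(0.01, 10.0))
    def test_monotone_in_z(self, z1, z2):
        lo, hi = sorted([z1, z2])
        assert wald_p(hi, 1.0) <= wald_p(lo, 1.0) + 1e-15


class TestMantelHaenszel:
    def test_symmetric_table_is_null(self):
        assert mantel_haenszel_or([StratumTable(10, 10, 10, 10)]) == pytest.approx(1.0)

    def test_hand_evaluated_single_table(self):
        assert mantel_haenszel_or([StratumTable(20, 10, 10, 20)]) == pytest.approx(4.0)

    def test_homogeneity_invariance(self):
        t = StratumTable(20, 10, 10, 20)
        assert mantel_haenszel_or([t, t]) == pytest.approx(mantel_haenszel_or([t]))

    def test_zero_denominator_signalled(self):
        with pytest.raises(ZeroDivisionError):
            mantel_haenszel_or([StratumTable(5, 0, 3, 7)])

    @given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30), st.integers(1, 30))
    def test_single_stratum_equals_pooled_odds_ratio(self, a, b, c, d):
        assert mantel_haenszel_or([StratumTable(a, b, c, d)]) == pytest.approx(
            (a * d) / (b * c), rel=1e-12
        )


class TestFitUnconditional:
    def test_collapsible_2x2_closed_form(self):
        df = _pooled_2x2_dataset(20, 10, 10, 20)
        res = fit_unconditional(df, CovariateSpec(covariates=()))
        assert res.converged
        assert res.beta_e_hat == pytest.approx(math.log(4.0), abs=1e-8)

    def test_null_recovery(self):
        sc = Scenario(mu0=65.0, or_exposure=1.0, or_age_per10=1.0, caliper_d=1, n_cases=2000)
        ds = simulate_matched_dataset(sc, np.random.default_rng(21))
        res = fit_unconditional(ds)
        assert res.converged
        assert abs(res.beta_e_hat) < 3 * res.se

    def test_cross_solver_oracle(self):
        """Agree with statsmodels Logit to 1e-6 on 50 random small datasets."""
        rng = np.random.default_rng(22)
        checked = 0
        while checked < 50:
            df = _random_small_frame(rng)
            res = fit_unconditional(df)
            if not res.converged:
                continue
            X = sm.add_constant(df[["exposure", "age"]].astype(float))
            ref = sm.Logit(df["outcome"], X).fit(disp=0, method="newton", tol=1e-12)
            assert res.beta_e_hat == pytest.approx(ref.params["exposure"], abs=1e-6)
            assert res.se == pytest.approx(ref.bse["exposure"], abs=1e-6)
            checked += 1

    def test_separation_flagged_not_crashed(self):
        df = pd.DataFrame(
            {
                "outcome": [1] * 10 + [0] * 10,
                "exposure": [1] * 10 + [0] * 10,
                "age": list(range(50, 60)) * 2,
                "stratum_id": 1,
            }
        )
        res = fit_unconditional(df)
        assert not res.converged
        assert math.isnan(res.p_two_sided)

    def test_rejects_single_class(self):
        df = pd.DataFrame({"outcome": [1, 1], "exposure": [0, 1], "age": [50, 51]})
        with pytest.raises(ValueError):
            fit_unconditional(df)


def _enumerated_conditional_loglik(beta, Z):
    """Independent slow oracle: per stratum, probability that the observed
    case (position 0) is the case among all members, by explicit loops."""
    total = 0.0
    for stratum in Z:
        terms = [math.exp(sum(b * z for b, z in zip(beta, member))) for member in stratum]
        total += math.log(terms[0] / sum(terms))
    return total


class TestConditionalLoglik:
    def test_zero_beta_is_uniform(self, small_matched_dataset):
        n1 = small_matched_dataset.design.n1
        k = small_matched_dataset.design.k
        ll = conditional_loglik([0.0, 0.0], small_matched_dataset)
        assert ll == pytest.approx(-n1 * math.log(k + 1), rel=1e-12)

    def test_concordant_strata_are_flat(self):
        df = pd.DataFrame(
            {
                "stratum_id": [1, 1, 2, 2],
                "outcome": [1, 0, 1, 0],
                "exposure": [1, 1, 0, 0],
                "age": [60, 60, 70, 70],
            }
        )
        lls = [conditional_loglik([b, 0.1 * b], df) for b in (-2.0, 0.0, 3.0)]
        assert max(lls) - min(lls) < 1e-12
        assert lls[0] == pytest.approx(-2 * math.log(2))

    def test_enumeration_oracle_on_toy_strata(self):
        rng = np.random.default_rng(23)
        S, m = 5, 3
        expo = rng.integers(0, 2, (S, m))
        ages = rng.integers(55, 75, (S, m))
        df = pd.DataFrame(
            {
                "stratum_id": np.repeat(np.arange(S), m),
                "outcome": np.tile([1, 0, 0], S),
                "exposure": expo.ravel(),
                "age": ages.ravel(),
            }
        )
        Z = np.stack([expo, ages], axis=-1).astype(float)
        for beta in ([0.3, -0.05], [1.2, 0.08], [-0.7, 0.0]):
            assert conditional_loglik(beta, df) == pytest.approx(
                _enumerated_conditional_loglik(beta, Z), rel=1e-12
            )


class TestFitConditional:
    def test_pair_difference_equivalence(self, small_matched_dataset):
        """1:1 conditional MLE equals an intercept-free logistic fit of a
        constant-1 outcome on within-pair (case - control) differences."""
        res = fit_conditional(small_matched_dataset)
        assert res.converged
        expo, ages = small_matched_dataset.to_stratum_arrays()
        D = np.stack([expo[:, 0] - expo[:, 1], ages[:, 0] - ages[:, 1]], axis=1).astype(float)

        def nll(beta):
            return np.sum(np.logaddexp(0.0, -D @ beta))

        ref = minimize(nll, np.zeros(2), method="BFGS", options={"gtol": 1e-12})
        assert res.beta_e_hat == pytest.approx(ref.x[0], abs=1e-6)
        beta_age = res.beta[res.covariate_names.index("age")]
        assert beta_age == pytest.approx(ref.x[1], abs=1e-6)

    def test_degenerate_caliper_drops_age(self):
        sc = Scenario(mu0=60.0, or_exposure=1.5, or_age_per10=2.0, caliper_d=0, n_cases=300)
        ds = simulate_matched_dataset(sc, np.random.default_rng(24))
        res = fit_conditional(ds)
        assert res.dropped_covariates == ("age",)
        assert res.converged
        assert math.isfinite(res.beta_e_hat)
        # closed form for 1:1 exposure-only pairs: log of discordant ratio
        expo, _ = ds.to_stratum_arrays()
        n10 = int(np.sum((expo[:, 0] == 1) & (expo[:, 1] == 0)))
        n01 = int(np.sum((expo[:, 0] == 0) & (expo[:, 1] == 1)))
        assert res.beta_e_hat == pytest.approx(math.log(n10 / n01), abs=1e-8)

    def test_grid_search_oracle(self):
        rng = np.random.default_rng(25)
        S = 10
        df = pd.DataFrame(
            {
                "stratum_id": np.repeat(np.arange(S), 2),
                "outcome": np.tile([1, 0], S),
                "exposure": rng.integers(0, 2, 2 * S),
                "age": 60,
            }
        )
        res = fit_conditional(df)
        grid = np.arange(-3.0, 3.0, 1e-3)
        lls = [conditional_loglik([b], df, CovariateSpec(covariates=())) for b in grid]
        assert res.beta_e_hat == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)

    def test_cross_solver_oracle_k3(self):
        """Agree with statsmodels ConditionalLogit on a 1:3 matched dataset."""
        sc = Scenario(
            mu0=65.0, or_exposure=1.5, or_age_per10=2.0, caliper_d=2, ratio_k=3, n_cases=200
        )
        ds = simulate_matched_dataset(sc, np.random.default_rng(26))
        res = fit_conditional(ds)
        df = ds.to_frame()
        ref = ConditionalLogit(
            df["outcome"], df[["exposure", "age"]].astype(float), groups=df["stratum_id"]
        ).fit(disp=0, method="bfgs", gtol=1e-10, maxiter=500)
        assert res.beta_e_hat == pytest.approx(ref.params.iloc[0], abs=1e-5)
        assert res.se == pytest.approx(ref.bse.iloc[0], abs=1e-5)

    def test_no_discordant_strata_not_converged(self):
        df = pd.DataFrame(
            {
                "stratum_id": [1, 1, 2, 2],
                "outcome": [1, 0, 1, 0],
                "exposure": [1, 1, 0, 0],
                "age": [60, 60, 70, 70],
            }
        )
        res = fit_conditional(df)
        assert not res.converged
        assert res.n_informative_strata == 0

    def test_monotone_likelihood_flagged(self):
        # all discordant pairs point the same way: the MLE diverges
        df = pd.DataFrame(
            {
                "stratum_id": np.repeat(np.arange(8), 2),
                "outcome": np.tile([1, 0], 8),
                "exposure": np.tile([1, 0], 8),
                "age": 60,
            }
        )
        res = fit_conditional(df)
        assert not res.converged


class TestInvariances:
    def test_row_permutation_and_stratum_relabeling(self, small_matched_dataset):
        base_u = fit_unconditional(small_matched_dataset)
        base_c = fit_conditional(small_matched_dataset)
        df = small_matched_dataset.to_frame()
        rng = np.random.default_rng(27)
        shuffled = df.sample(frac=1.0, random_state=28).reset_index(drop=True)
        relabel = {s: i + 1 for i, s in enumerate(rng.permutation(df["stratum_id"].unique()))}
        shuffled["stratum_id"] = shuffled["stratum_id"].map(relabel)
        perm_u = fit_unconditional(shuffled)
        perm_c = fit_conditional(MatchedDataset.from_frame(shuffled))
        assert perm_u.beta_e_hat == pytest.approx(base_u.beta_e_hat, abs=1e-10)
        assert perm_c.beta_e_hat == pytest.approx(base_c.beta_e_hat, abs=1e-10)

    def test_per_stratum_age_shift_leaves_conditional_invariant(self, small_matched_dataset):
        base = fit_conditional(small_matched_dataset)
        df = small_matched_dataset.to_frame().copy()
        rng = np.random.default_rng(29)
        shifts = {s: int(rng.integers(-30, 30)) for s in df["stratum_id"].unique()}
        df["age"] = df["age"] + df["stratum_id"].map(shifts)
        shifted = fit_conditional(MatchedDataset.from_frame(df))
        assert shifted.beta_e_hat == pytest.approx(base.beta_e_hat, abs=1e-8)
        assert shifted.se == pytest.approx(base.se, abs=1e-8)

    def test_single_stratum_collapsible_agreement(self):
        """On one pooled 2x2 table the unconditional fit and the MH estimator
        agree with the pooled-table log odds ratio."""
        df = _pooled_2x2_dataset(20, 10, 10, 20)
        res = fit_unconditional(df, CovariateSpec(covariates=()))
        mh = mantel_haenszel_or([StratumTable(20, 10, 10, 20)])
        assert res.beta_e_hat == pytest.approx(math.log(mh), abs=1e-8)
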