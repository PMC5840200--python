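"""Unconditional and conditional logistic regression for matched data.

The unconditional model is ordinary maximum-likelihood logistic regression of
the outcome on intercept + exposure + matching covariates (matching sets
ignored, matching variable adjusted as a covariate).  The conditional model
eliminates the per-stratum intercepts by conditioning on one case per
matching set; its log-likelihood is

    sum_s [ eta_case(s) - log sum_{j in s} exp(eta_j) ],

with eta = beta_e * x_e + beta_a * x_a (interval-matched age retained; the
stratum intercept and any exactly-matched variable cancel).  Both likelihoods
are maximized by Newton-Raphson with analytic gradient and Hessian, written
against batched arrays so a whole stack of Monte-Carlo replicates is fitted
in one call; standard errors come from the observed information at the MLE.

Also provides the two-sided Wald p-value and the Mantel-Haenszel stratified
odds ratio for per-stratum 2x2 exposure-by-outcome tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .simulate import MatchedDataset

__all__ = [
    "FitResult",
    "CovariateSpec",
    "StratumTable",
    "fit_unconditional",
    "fit_conditional",
    "conditional_loglik",
    "wald_p",
    "mantel_haenszel_or",
]

_GRAD_TOL = 1e-8
_MAX_ITER = 40
#: |beta| beyond this is treated as a monotone likelihood / separation
_DIVERGENCE_BOUND = 15.0


@dataclass(frozen=True)
class CovariateSpec:
    """Covariates fitted alongside exposure.

    ``covariates`` are column names entering the linear predictor in addition
    to the exposure (for this study: age in years).  Exactly-matched and
    unmatched extra covariates are supported through the same list; in the
    conditional model any covariate with zero within-stratum variance is
    structurally non-identified and dropped automatically.
    """

    covariates: tuple[str, ...] = ("age",)

    def columns(self) -> tuple[str, ...]:
        return ("exposure", *self.covariates)


@dataclass(frozen=True)
class FitResult:
    """Exposure-coefficient inference for one fitted model."""

    model: str  # "unconditional" | "conditional"
    beta_e_hat: float
    se: float
    p_two_sided: float
    converged: bool
    loglik: float
    beta: np.ndarray
    covariate_names: tuple[str, ...]
    n_informative_strata: int | None = None
    dropped_covariates: tuple[str, ...] = ()


@dataclass(frozen=True)
class StratumTable:
    """2x2 exposure-by-outcome counts: a=exposed cases, b=exposed controls,
    c=unexposed cases, d=unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def wald_p(beta_hat: float, se: float) -> float:
    """Two-sided p-value for H0: beta = 0 against the standard normal."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return float(2.0 * norm.sf(abs(beta_hat / se)))


def mantel_haenszel_or(tables: list[StratumTable]) -> float:
    """Mantel-Haenszel stratified odds ratio: (sum a_i d_i/n_i)/(sum b_i c_i/n_i)."""
    num = sum(t.a * t.d / t.n for t in tables if t.n > 0)
    den = sum(t.b * t.c / t.n for t in tables if t.n > 0)
    if den == 0.0:
        raise ZeroDivisionError("Mantel-Haenszel odds ratio undefined: zero denominator")
    return num / den


# ---------------------------------------------------------------------------
# batched Newton solvers
# ---------------------------------------------------------------------------


def _newton_step(H: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Solve H delta = grad per replicate; least-squares fallback for
    replicates with a singular information matrix."""
    try:
        return np.linalg.solve(H, grad[..., None])[..., 0]
    except np.linalg.LinAlgError:
        return np.stack(
            [np.linalg.lstsq(h, g, rcond=None)[0] for h, g in zip(H, grad)]
        )


def batch_logistic_mle(X: np.ndarray, y: np.ndarray):
    """Batched logistic-regression MLE by Newton-Raphson.

    Parameters
    ----------
    X : (R, n, p) design matrices (intercept column included).
    y : (R, n) or (n,) binary outcomes.

    Returns
    -------
    beta : (R, p), se : (R, p), loglik : (R,), converged : (R,) bool
    Convergence requires max-norm of the score below 1e-8; runs that diverge
    (separation) are flagged non-converged.
    """
    X = np.asarray(X, dtype=float)
    R, n, p = X.shape
    y = np.broadcast_to(np.asarray(y, dtype=float), (R, n))
    beta = np.zeros((R, p))
    ybar = np.clip(y.mean(axis=1), 1e-9, 1 - 1e-9)
    beta[:, 0] = np.log(ybar / (1 - ybar))
    active = np.ones(R, dtype=bool)
    diverged = np.zeros(R, dtype=bool)

    for _ in range(_MAX_ITER):
        if not active.any():
            break
        Xa, ya, ba = X[active], y[active], beta[active]
        eta = np.einsum("rnp,rp->rn", Xa, ba)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = np.einsum("rnp,rn->rp", Xa, ya - mu)
        H = np.einsum("rnp,rnq->rpq", Xa * w[:, :, None], Xa)
        delta = _newton_step(H, grad)
        ba = ba + delta
        beta[active] = ba
        bad = ~np.isfinite(ba).all(axis=1) | (np.abs(ba).max(axis=1) > _DIVERGENCE_BOUND)
        done = np.abs(grad).max(axis=1) < _GRAD_TOL
        idx = np.flatnonzero(active)
        diverged[idx[bad]] = True
        active[idx[done | bad]] = False

    converged = ~diverged & ~active
    eta = np.einsum("rnp,rp->rn", X, np.where(np.isfinite(beta), beta, 0.0))
    loglik = np.sum(y * eta - np.logaddexp(0.0, eta), axis=1)
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = np.einsum("rnp,rnq->rpq", X * w[:, :, None], X)
    se = np.full((R, p), np.nan)
    ok = np.flatnonzero(converged)
    if ok.size:
        cov = np.linalg.inv(H[ok])
        se[ok] = np.sqrt(np.einsum("rpp->rp", cov))
    return beta, se, loglik, converged


def batch_conditional_mle(Z: np.ndarray):
    """Batched conditional-logistic MLE over fixed-size matched sets.

    Parameters
    ----------
    Z : (R, S, m, p) covariate arrays — S strata of m subjects with the case
        at position 0 along the m axis.

    Returns
    -------
    beta : (R, p), se : (R, p), loglik : (R,), converged : (R,) bool

    The score is sum_s (z_case - E_w[z]) and the observed information is the
    sum of within-stratum covariance matrices of z under the softmax weights.
    A diverging ||beta|| (monotone likelihood, e.g. no discordant strata in
    one direction) is flagged non-converged.
    """
    Z = np.asarray(Z, dtype=float)
    R, S, m, p = Z.shape
    beta = np.zeros((R, p))
    active = np.ones(R, dtype=bool)
    diverged = np.zeros(R, dtype=bool)

    for _ in range(_MAX_ITER):
        if not active.any():
            break
        Za, ba = Z[active], beta[active]
        eta = np.einsum("rsmp,rp->rsm", Za, ba)
        eta = eta - eta.max(axis=2, keepdims=True)
        w = np.exp(eta)
        w /= w.sum(axis=2, keepdims=True)
        zbar = np.einsum("rsm,rsmp->rsp", w, Za)
        grad = (Za[:, :, 0, :] - zbar).sum(axis=1)
        H = np.einsum("rsmp,rsmq->rpq", Za * w[:, :, :, None], Za) - np.einsum(
            "rsp,rsq->rpq", zbar, zbar
        )
        delta = _newton_step(H, grad)
        ba = ba + delta
        beta[active] = ba
        bad = ~np.isfinite(ba).all(axis=1) | (np.abs(ba).max(axis=1) > _DIVERGENCE_BOUND)
        done = np.abs(grad).max(axis=1) < _GRAD_TOL
        idx = np.flatnonzero(active)
        diverged[idx[bad]] = True
        active[idx[done | bad]] = False

    converged = ~diverged & ~active
    beta_safe = np.where(np.isfinite(beta), beta, 0.0)
    eta = np.einsum("rsmp,rp->rsm", Z, beta_safe)
    shift = eta.max(axis=2, keepdims=True)
    lse = shift[:, :, 0] + np.log(np.exp(eta - shift).sum(axis=2))
    loglik = (eta[:, :, 0] - lse).sum(axis=1)
    w = np.exp(eta - shift)
    w /= w.sum(axis=2, keepdims=True)
    zbar = np.einsum("rsm,rsmp->rsp", w, Z)
    H = np.einsum("rsmp,rsmq->rpq", Z * w[:, :, :, None], Z) - np.einsum(
        "rsp,rsq->rpq", zbar, zbar
    )
    se = np.full((R, p), np.nan)
    ok = np.flatnonzero(converged)
    if ok.size:
        cov = np.linalg.inv(H[ok])
        se[ok] = np.sqrt(np.einsum("rpp->rp", cov))
    return beta, se, loglik, converged


# ---------------------------------------------------------------------------
# single-dataset interface
# ---------------------------------------------------------------------------


def _as_frame(dataset) -> pd.DataFrame:
    if isinstance(dataset, MatchedDataset):
        return dataset.to_frame()
    return pd.DataFrame(dataset)


def fit_unconditional(dataset, covariates: CovariateSpec | None = None) -> FitResult:
    """Ordinary logistic regression of outcome on exposure + covariates.

    Matching is ignored; the matching variable enters as a covariate.
    Separation or non-convergence is reported via ``converged=False`` with
    NaN standard error.
    """
    covariates = covariates or CovariateSpec()
    df = _as_frame(dataset)
    y = df["outcome"].to_numpy(dtype=float)
    if len(df) == 0 or y.min() == y.max():
        raise ValueError("dataset must contain both cases and controls")
    names = ("intercept",) + covariates.columns()
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covariates.columns()])
    beta, se, loglik, conv = batch_logistic_mle(X[None], y[None])
    converged = bool(conv[0])
    b_e, se_e = float(beta[0, 1]), float(se[0, 1])
    return FitResult(
        model="unconditional",
        beta_e_hat=b_e,
        se=se_e,
        p_two_sided=wald_p(b_e, se_e) if converged else float("nan"),
        converged=converged,
        loglik=float(loglik[0]),
        beta=beta[0],
        covariate_names=names,
    )


def _stratum_design(dataset, covariates: CovariateSpec) -> tuple[np.ndarray, tuple[str, ...]]:
    """(S, m, p) covariate array with the case first in each stratum."""
    if isinstance(dataset, MatchedDataset):
        expo, ages = dataset.to_stratum_arrays()
        base = {"exposure": expo, "age": ages}
        cols = covariates.columns()
        missing = [c for c in cols if c not in base]
        if missing:
            raise ValueError(f"covariates not in dataset: {missing}")
        Z = np.stack([base[c] for c in cols], axis=-1).astype(float)
        return Z, cols
    df = _as_frame(dataset).sort_values(
        ["stratum_id", "outcome"], ascending=[True, False], kind="stable"
    )
    sizes = df.groupby("stratum_id").size()
    if sizes.nunique() != 1:
        raise ValueError("conditional fit requires equal-size strata")
    if not (df.groupby("stratum_id")["outcome"].sum() == 1).all():
        raise ValueError("conditional fit requires exactly one case per stratum")
    S, m = len(sizes), int(sizes.iloc[0])
    cols = covariates.columns()
    Z = np.stack(
        [df[c].to_numpy(dtype=float).reshape(S, m) for c in cols], axis=-1
    )
    return Z, cols


def conditional_loglik(beta, dataset, covariates: CovariateSpec | None = None) -> float:
    """Stratum conditional log-likelihood at a coefficient vector.

    With all coefficients zero every stratum contributes -log(k+1); strata in
    which all subjects share identical covariates contribute that constant at
    any beta.
    """
    covariates = covariates or CovariateSpec()
    Z, _ = _stratum_design(dataset, covariates)
    beta = np.asarray(beta, dtype=float)
    eta = np.einsum("smp,p->sm", Z, beta)
    shift = eta.max(axis=1, keepdims=True)
    lse = shift[:, 0] + np.log(np.exp(eta - shift).sum(axis=1))
    return float((eta[:, 0] - lse).sum())


def fit_conditional(dataset, covariates: CovariateSpec | None = None) -> FitResult:
    """Conditional logistic regression via the stratum conditional likelihood.

    Covariates with exactly zero within-stratum variance (e.g. age under a
    d=0 caliper, or an exactly-matched variable) are structurally
    non-identified and dropped; the dropped names are recorded on the result.
    """
    covariates = covariates or CovariateSpec()
    Z, cols = _stratum_design(dataset, covariates)
    within_var = np.ptp(Z, axis=1).max(axis=0)  # (p,) max within-stratum range
    keep = within_var > 0.0
    dropped = tuple(c for c, k in zip(cols, keep) if not k)
    if "exposure" in dropped:
        # exposure concordant in every stratum: nothing to estimate
        return FitResult(
            model="conditional",
            beta_e_hat=float("nan"),
            se=float("nan"),
            p_two_sided=float("nan"),
            converged=False,
            loglik=-Z.shape[0] * math.log(Z.shape[1]),
            beta=np.full(len(cols), np.nan),
            covariate_names=cols,
            n_informative_strata=0,
            dropped_covariates=dropped,
        )
    Zk = Z[:, :, :, ][..., keep]
    n_informative = int((np.ptp(Zk, axis=1).max(axis=1) > 0).sum())
    beta_k, se_k, loglik, conv = batch_conditional_mle(Zk[None])
    converged = bool(conv[0])
    kept_cols = tuple(c for c, k in zip(cols, keep) if k)
    e_idx = kept_cols.index("exposure")
    b_e, se_e = float(beta_k[0, e_idx]), float(se_k[0, e_idx])
    beta_full = np.full(len(cols), np.nan)
    beta_full[keep] = beta_k[0]
    return FitResult(
        model="conditional",
        beta_e_hat=b_e,
        se=se_e,
        p_two_sided=wald_p(b_e, se_e) if converged and se_e > 0 else float("nan"),
        converged=converged,
        loglik=float(loglik[0]),
        beta=beta_full,
        covariate_names=cols,
        n_informative_strata=n_informative,
        dropped_covariates=dropped,
    )
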