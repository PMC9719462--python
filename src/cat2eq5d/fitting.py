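"""Model fitting for repeated-measures CAT / EQ-5D data.

The response-mapping models are per-dimension multinomial logits (levels
1/2/3, level 1 reference) fitted to clustered data: each patient contributes
several visits.  Estimation follows the estimating-equation approach with an
independence working correlation — under that working model the estimating
equations coincide with the pooled multinomial likelihood score, so point
estimates are pooled maximum likelihood and uncertainty comes from the
cluster-robust (sandwich) covariance with scores summed within patients.

Model selection uses QIC, the quasi-likelihood information criterion

    QIC = -2 QL(beta; y) + 2 trace(A V_R)

with QL the pooled multinomial log likelihood, A the model-based information
and V_R the robust covariance; for independent data and a correct model the
trace reduces to the parameter count and QIC reduces to AIC.  Covariate
selection is backward elimination on joint 2-df robust Wald tests (a
covariate enters both the level-2 and level-3 logits; the two coefficients
are tested together), dropping the least significant covariate until all
remaining ones reach the chosen type-I error rate (default 0.05).

Linear (direct-to-utility) equations are re-estimated by ordinary least
squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .core_data import CAT_ITEMS, Observation
from .models import DirectOlsSpec, LinearEquation, MlrResponseSpec, MnlDimensionModel
from .tariff import DIMENSIONS

GRADIENT_TOL = 1e-8
MAX_ITER = 100
SEPARATION_BOUND = 50.0


class FitError(RuntimeError):
    pass


def _design(
    obs: Sequence[Observation], covariates: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray]:
    """Design matrix (intercept column first) and cluster codes."""
    cols = []
    for name in covariates:
        if name == "intercept":
            cols.append(np.ones(len(obs)))
        elif name == "cat_total":
            cols.append(np.array([o.cat.total for o in obs], dtype=float))
        elif name in CAT_ITEMS:
            idx = CAT_ITEMS.index(name)
            cols.append(np.array([o.cat.items()[idx] for o in obs], dtype=float))
        elif name == "age":
            cols.append(np.array([o.age for o in obs], dtype=float))
        elif name == "sex":
            cols.append(np.array([o.sex for o in obs], dtype=float))
        else:
            raise FitError(f"unknown covariate {name!r}")
    X = np.column_stack(cols)
    _, clusters = np.unique([o.patient_id for o in obs], return_inverse=True)
    return X, clusters


@dataclass
class FitResult:
    """A fitted per-dimension multinomial logit with robust inference.

    Coefficients are stacked ``[beta2, beta3]`` in ``theta``; covariance
    matrices follow the same ordering.
    """

    dimension: str
    covariates: List[str]
    beta2: np.ndarray
    beta3: np.ndarray
    cov_robust: np.ndarray
    cov_model: np.ndarray
    info_model: np.ndarray
    loglik: float
    qic: float
    wald_p: Dict[str, float]
    n_obs: int
    n_clusters: int
    converged: bool
    n_iter: int
    separation_flag: bool

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.beta2, self.beta3])

    def robust_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_robust))

    def to_dimension_model(self) -> MnlDimensionModel:
        return MnlDimensionModel(
            covariates=list(self.covariates),
            beta2=[float(b) for b in self.beta2],
            beta3=[float(b) for b in self.beta3],
        )


def _mnl_loglik_parts(theta: np.ndarray, X: np.ndarray, Y: np.ndarray):
    """Log likelihood, per-observation score matrix and information."""
    n, p = X.shape
    b2, b3 = theta[:p], theta[p:]
    eta = np.column_stack([np.zeros(n), X @ b2, X @ b3])
    m = eta.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(eta - m).sum(axis=1))
    ll = float((eta[np.arange(n), Y] - lse).sum())
    P = np.exp(eta - lse[:, None])
    r2 = (Y == 1).astype(float) - P[:, 1]
    r3 = (Y == 2).astype(float) - P[:, 2]
    scores = np.hstack([r2[:, None] * X, r3[:, None] * X])  # (n, 2p)
    # information blocks: sum_i w * x x'
    w22 = P[:, 1] * (1 - P[:, 1])
    w33 = P[:, 2] * (1 - P[:, 2])
    w23 = -P[:, 1] * P[:, 2]
    A = np.empty((2 * p, 2 * p))
    A[:p, :p] = X.T @ (w22[:, None] * X)
    A[p:, p:] = X.T @ (w33[:, None] * X)
    A[:p, p:] = X.T @ (w23[:, None] * X)
    A[p:, :p] = A[:p, p:].T
    return ll, scores, A


def fit_mnl_independence(
    obs: Sequence[Observation],
    dimension: str,
    covariates: Sequence[str],
    *,
    tol: float = GRADIENT_TOL,
    max_iter: int = MAX_ITER,
    separation_bound: float = SEPARATION_BOUND,
) -> FitResult:
    """Fit one EQ-5D dimension's multinomial logit on clustered visits.

    Point estimates are pooled maximum likelihood (Newton iterations with
    step halving, gradient norm below ``tol``); the covariance is the
    cluster sandwich.  Coefficients beyond ``separation_bound`` in absolute
    value raise a quasi-separation flag without failing the fit.
    """
    if dimension not in DIMENSIONS:
        raise FitError(f"unknown EQ-5D dimension {dimension!r}")
    if any(o.eq5d is None for o in obs):
        raise FitError("all observations need an observed EQ-5D state")
    covariates = list(covariates)
    if covariates[0] != "intercept":
        covariates = ["intercept"] + covariates
    X, clusters = _design(obs, covariates)
    y = np.array([getattr(o.eq5d, dimension) for o in obs])
    present = set(np.unique(y))
    if present != {1, 2, 3}:
        missing = sorted({1, 2, 3} - present)
        raise FitError(
            f"dimension {dimension!r}: level(s) {missing} absent from the data; "
            "the three-level logit is not estimable"
        )
    Y = y - 1  # 0-based
    n, p = X.shape

    theta = np.zeros(2 * p)
    ll, scores, A = _mnl_loglik_parts(theta, X, Y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = scores.sum(axis=0)
        if np.linalg.norm(g) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(A, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(A, g, rcond=None)[0]
        # step halving: never accept a decrease in log likelihood
        scale = 1.0
        for _ in range(30):
            ll_new, scores_new, A_new = _mnl_loglik_parts(theta + scale * step, X, Y)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        theta = theta + scale * step
        ll, scores, A = ll_new, scores_new, A_new
    else:
        g = scores.sum(axis=0)
        converged = bool(np.linalg.norm(g) < tol)

    # cluster sandwich: scores summed within patients
    n_clusters = int(clusters.max()) + 1
    S = np.zeros((n_clusters, 2 * p))
    np.add.at(S, clusters, scores)
    B = S.T @ S
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        A_inv = np.linalg.pinv(A)
    cov_robust = A_inv @ B @ A_inv
    qic_val = -2.0 * ll + 2.0 * float(np.trace(A @ cov_robust))

    beta2, beta3 = theta[:p], theta[p:]
    wald_p = _wald_pvalues(theta, cov_robust, covariates)
    return FitResult(
        dimension=dimension,
        covariates=covariates,
        beta2=beta2,
        beta3=beta3,
        cov_robust=cov_robust,
        cov_model=A_inv,
        info_model=A,
        loglik=ll,
        qic=qic_val,
        wald_p=wald_p,
        n_obs=n,
        n_clusters=n_clusters,
        converged=converged,
        n_iter=it,
        separation_flag=bool(np.abs(theta).max() > separation_bound),
    )


def _wald_pvalues(
    theta: np.ndarray, cov: np.ndarray, covariates: Sequence[str]
) -> Dict[str, float]:
    """Joint 2-df robust Wald p-value per non-intercept covariate."""
    p = len(covariates)
    out: Dict[str, float] = {}
    for j, name in enumerate(covariates):
        if name == "intercept":
            continue
        idx = [j, p + j]
        th = theta[idx]
        C = cov[np.ix_(idx, idx)]
        try:
            w = float(th @ np.linalg.solve(C, th))
        except np.linalg.LinAlgError:
            w = float(th @ np.linalg.pinv(C) @ th)
        out[name] = float(chi2.sf(w, df=2))
    return out


def qic(fit: FitResult) -> float:
    """QIC of a converged fit: ``-2 QL + 2 trace(A V_R)``."""
    if not fit.converged:
        raise FitError("QIC is only defined for a converged fit")
    return fit.qic


def backward_eliminate(
    obs: Sequence[Observation],
    dimension: str,
    full_covariates: Sequence[str],
    alpha: float = 0.05,
    **fit_kwargs,
) -> FitResult:
    """Backward elimination on joint 2-df robust Wald tests.

    Starting from the full covariate set, repeatedly drop the covariate with
    the largest p-value above ``alpha`` and refit; stop when every remaining
    covariate is significant at ``alpha``.  The intercept is never dropped.
    """
    covs = list(full_covariates)
    if not covs or covs[0] != "intercept":
        covs = ["intercept"] + covs
    fit = fit_mnl_independence(obs, dimension, covs, **fit_kwargs)
    while len(covs) > 1:
        worst = max(fit.wald_p, key=fit.wald_p.get)
        if fit.wald_p[worst] <= alpha:
            break
        covs.remove(worst)
        fit = fit_mnl_independence(obs, dimension, covs, **fit_kwargs)
    return fit


def fit_response_mapping(
    obs: Sequence[Observation],
    covariates: Sequence[str],
    *,
    backward: bool = True,
    alpha: float = 0.05,
    name: str = "fitted_mlr",
    **fit_kwargs,
) -> Tuple[MlrResponseSpec, Dict[str, FitResult]]:
    """Fit all five EQ-5D dimensions and assemble a response-mapping spec."""
    fits: Dict[str, FitResult] = {}
    dims: Dict[str, MnlDimensionModel] = {}
    for dim in DIMENSIONS:
        if backward:
            fit = backward_eliminate(obs, dim, covariates, alpha=alpha, **fit_kwargs)
        else:
            fit = fit_mnl_independence(obs, dim, covariates, **fit_kwargs)
        fits[dim] = fit
        dims[dim] = fit.to_dimension_model()
    spec = MlrResponseSpec(name=name, dimensions=dims)
    return spec, fits


def fit_ols(
    obs: Sequence[Observation],
    covariates: Sequence[str],
    *,
    response: str = "utility",
    name: str = "fitted_ols",
) -> DirectOlsSpec:
    """Ordinary least squares of observed utility on the stated covariates.

    This regenerates "modified" linear mapping equations on a new cohort.
    Delegates to statsmodels OLS.
    """
    import statsmodels.api as sm

    covs = [c for c in covariates if c != "intercept"]
    X, _ = _design(obs, ["intercept"] + covs)
    if response != "utility":
        raise FitError(f"unsupported response {response!r}")
    y = np.array(
        [o.utility for o in obs if o.utility is not None], dtype=float
    )
    if y.size != len(obs):
        raise FitError("all observations need an observed utility")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    params = res.params
    return DirectOlsSpec(
        name=name,
        note=f"OLS refit on {len(obs)} observations",
        equation=LinearEquation(
            intercept=float(params[0]),
            slopes={c: float(b) for c, b in zip(covs, params[1:])},
        ),
    )
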