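"""Goodness-of-fit measures for probit models.

The central quantity is the surrogate R-squared: the OLS R-squared of a
linear regression of the simulated surrogate response on the covariates.
For a submodel the regression reuses the *common* surrogate generated from
the full model — the surrogate is never regenerated from a refitted
submodel.  This common-surrogate rule is what restores the nested-model
monotonicity that a continuous response gives the ordinary R-squared, and
it is mandatory here: a submodel request that is not a subset of the
surrogate's full model raises.

Also provided: the classical competitors (McKelvey–Zavoina's
latent-variance ratio and McFadden's likelihood-ratio index), the
closed-form asymptotic surrogate R-squared, the population limit
``beta' Sigma beta / (beta' Sigma beta + 1)``, and the exact F-statistic
correspondence ``R^2 = pF / (pF + n - p - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr

from .probit import OrdinalDataset, ProbitFit, ProbitParams
from .surrogate import generate_surrogate_batch

__all__ = [
    "R2Result",
    "ols_r2",
    "surrogate_r2",
    "mz_r2",
    "mcfadden_r2",
    "asymptotic_surrogate_r2",
    "r2_from_f",
    "f_from_r2",
    "population_limit_r2",
    "CommonSurrogate",
]


@dataclass(frozen=True)
class R2Result:
    """A pseudo-R-squared value tagged by measure and covariate subset."""

    value: float
    measure: str
    var_subset: tuple[str, ...]
    full_model_ref: str | None = None
    M: int | None = None
    draw_values: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not (-1e-12 <= self.value <= 1.0 + 1e-12):
            raise ValueError(f"R2 value {self.value} outside [0, 1]")
        object.__setattr__(self, "value", float(min(max(self.value, 0.0), 1.0)))

    def __float__(self):
        return self.value


def _name_collinear(Xc, names):
    """Identify dependent columns of a centered, rank-deficient matrix."""
    _, R, piv = qr(Xc, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(Xc.shape) * np.finfo(float).eps if d.size else 0.0
    rank = int(np.sum(d > tol))
    return [names[j] for j in sorted(piv[rank:])]


def ols_r2(response, X, var_names=None) -> float:
    """OLS R-squared (SSR/SST) of ``response`` on ``X`` with an intercept.

    An empty design (zero columns) returns 0.0 — the intercept-only model
    explains nothing.  Rank-deficient designs and a constant response are
    rejected.
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if y.shape[0] != n:
        raise ValueError("response and X have different numbers of rows")
    yc = y - y.mean()
    sst = float(yc @ yc)
    if sst <= 0.0:
        raise ValueError("response has zero variance; R2 undefined")
    if k == 0:
        return 0.0
    if n <= k + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={k})")
    Xc = X - X.mean(axis=0)
    coef, _, rank, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    if rank < k:
        names = list(var_names) if var_names is not None else [f"column {j}" for j in range(k)]
        raise ValueError(f"design matrix is rank deficient; collinear: {_name_collinear(Xc, names)}")
    fitted = Xc @ coef
    ssr = float(fitted @ fitted)
    return min(ssr / sst, 1.0)


class CommonSurrogate:
    """A bundle of ``M`` surrogate draws from one full model, reusable for
    R-squared evaluation of any nested subset (the common-surrogate rule).
    """

    def __init__(self, full_fit: ProbitFit, data: OrdinalDataset, M: int = 30, seed: int = 0):
        params = full_fit.params if isinstance(full_fit, ProbitFit) else full_fit
        if isinstance(full_fit, ProbitFit):
            self.full_subset = tuple(full_fit.var_subset)
            self.full_model_ref = f"{full_fit.dataset_ref}:{'+'.join(full_fit.var_subset)}"
        else:
            self.full_subset = tuple(data.var_names[: params.p])
            self.full_model_ref = f"{data.name}:true-params"
        self.data = data
        self.M = int(M)
        self.seed = int(seed)
        draws = generate_surrogate_batch(params, data, M, seed, subset=self.full_subset)
        self.S = np.column_stack([d.s for d in draws])  # (n, M)

    def r2(self, subset) -> R2Result:
        subset = tuple(subset)
        if not set(subset) <= set(self.full_subset):
            extra = sorted(set(subset) - set(self.full_subset))
            raise ValueError(
                f"subset {extra} not in the surrogate's full model {list(self.full_subset)}; "
                "surrogate R2 for a submodel must reuse the full-model surrogate"
            )
        cols = self.data.columns(subset)
        Xs = self.data.X[:, cols]
        vals = np.array([ols_r2(self.S[:, m], Xs, var_names=subset) for m in range(self.M)])
        return R2Result(
            value=float(vals.mean()),
            measure="surrogate_avg" if self.M > 1 else "surrogate",
            var_subset=subset,
            full_model_ref=self.full_model_ref,
            M=self.M,
            draw_values=vals,
        )


def surrogate_r2(full_fit, data: OrdinalDataset, subset=None, M: int = 30,
                 seed: int = 0) -> R2Result:
    """Surrogate R-squared of ``subset``, averaged over ``M`` draws.

    ``full_fit`` may be a :class:`ProbitFit` (surrogate from estimated
    parameters) or a :class:`ProbitParams` (surrogate from known/true
    parameters, as in the simulation benchmarks).  The surrogate is always
    generated from this full model; ``subset`` only selects regressors in
    the linear step.  Per-draw values are kept in ``draw_values``.
    """
    common = CommonSurrogate(full_fit, data, M=M, seed=seed)
    if subset is None:
        subset = common.full_subset
    return common.r2(subset)


def _linear_predictor(fit: ProbitFit, data: OrdinalDataset) -> np.ndarray:
    cols = data.columns(fit.var_subset)
    return data.X[:, cols] @ fit.params.beta


def mz_r2(fit: ProbitFit, data: OrdinalDataset) -> R2Result:
    """McKelvey–Zavoina R-squared of a (re)fitted model:
    ``sum (zhat - mean)^2 / (sum (zhat - mean)^2 + n)`` from the fitted
    latent linear predictor ``zhat = x' betahat``."""
    zhat = _linear_predictor(fit, data)
    ssr = float(np.sum((zhat - zhat.mean()) ** 2))
    return R2Result(value=ssr / (ssr + data.n), measure="mz", var_subset=tuple(fit.var_subset))


def mcfadden_r2(fit: ProbitFit) -> R2Result:
    """McFadden's likelihood-ratio index ``1 - loglik / null_loglik``."""
    if not fit.null_loglik < 0:
        raise ValueError("null log-likelihood must be negative")
    value = 1.0 - fit.loglik / fit.null_loglik
    return R2Result(value=value, measure="mcfadden", var_subset=tuple(fit.var_subset))


def asymptotic_surrogate_r2(full_fit: ProbitFit, data: OrdinalDataset, subset=None) -> R2Result:
    """Closed-form large-sample surrogate R-squared of a submodel.

    With ``X0`` the centered full design, ``Xr`` the centered subset
    columns, and ``betahat`` from the full model only:

    ``betahat' X0' Xr (Xr' Xr)^{-1} Xr' X0 betahat /
    (betahat' X0' X0 betahat + n)``.

    For ``subset`` equal to the full model this reduces exactly to the
    McKelvey–Zavoina value of the full fit.
    """
    full_subset = tuple(full_fit.var_subset)
    if subset is None:
        subset = full_subset
    subset = tuple(subset)
    if not set(subset) <= set(full_subset):
        raise ValueError("subset must be contained in the full model")
    X0 = data.X[:, data.columns(full_subset)]
    X0 = X0 - X0.mean(axis=0)
    v = X0 @ full_fit.params.beta
    denom = float(v @ v) + data.n
    if not subset:
        return R2Result(value=0.0, measure="surrogate_asymptotic", var_subset=())
    Xr = data.X[:, data.columns(subset)]
    Xr = Xr - Xr.mean(axis=0)
    G = Xr.T @ Xr
    try:
        w = np.linalg.solve(G, Xr.T @ v)
    except np.linalg.LinAlgError:
        raise ValueError("subset design Xr'Xr is singular") from None
    num = float((Xr.T @ v) @ w)
    return R2Result(value=num / denom, measure="surrogate_asymptotic", var_subset=subset,
                    full_model_ref=f"{full_fit.dataset_ref}:{'+'.join(full_subset)}")


def r2_from_f(F: float, p: int, n: int) -> float:
    """Map the regression F-statistic to R-squared: ``pF / (pF + n - p - 1)``."""
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    if F < 0:
        raise ValueError("F must be nonnegative")
    if np.isinf(F):
        return 1.0
    return p * F / (p * F + (n - p - 1))


def f_from_r2(r2: float, p: int, n: int) -> float:
    """Inverse map: ``F = (n - p - 1) r2 / (p (1 - r2))``; ``r2 = 1`` maps
    to ``+inf``."""
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    if not 0.0 <= r2 <= 1.0:
        raise ValueError("r2 must lie in [0, 1]")
    if r2 == 1.0:
        return np.inf
    return (n - p - 1) * r2 / (p * (1.0 - r2))


def population_limit_r2(beta, sigma, subset=None) -> float:
    """In-probability limit of the latent OLS and surrogate R-squared.

    Full model: ``beta' Sigma beta / (beta' Sigma beta + 1)``.  For a
    subset ``S`` of covariate indices, the numerator is the variance of the
    best linear predictor of the latent mean from ``X_S`` alone:
    ``beta' Sigma[:, S] Sigma[S, S]^{-1} Sigma[S, :] beta``.
    """
    beta = np.asarray(beta, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (beta.size, beta.size) or not np.allclose(sigma, sigma.T):
        raise ValueError("sigma must be a symmetric matrix matching beta")
    eigmin = np.linalg.eigvalsh(sigma)[0]
    if eigmin <= 0:
        raise ValueError("sigma must be positive definite")
    total = float(beta @ sigma @ beta)
    if subset is None:
        explained = total
    else:
        idx = np.asarray(list(subset), dtype=np.intp)
        if idx.size == 0:
            return 0.0
        cross = sigma[np.ix_(idx, range(beta.size))] @ beta
        explained = float(cross @ np.linalg.solve(sigma[np.ix_(idx, idx)], cross))
    return explained / (total + 1.0)
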