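"""Cumulative (ordinal) probit model: data container, parameters, and ML fitting.

The model for an ordered response :math:`Y \\in \\{1, \\dots, J\\}` with
covariate row :math:`x` is

.. math::

    \\Pr(Y \\le j) = \\Phi(\\alpha_j - x'\\beta), \\qquad j = 1, \\dots, J,

with strictly increasing cutpoints :math:`\\alpha_1 < \\dots < \\alpha_{J-1}`
(:math:`\\alpha_J = +\\infty`) and a standard-normal latent error, i.e. the
latent outcome is :math:`Z = x'\\beta + \\varepsilon`,
:math:`\\varepsilon \\sim N(0, 1)`, and :math:`Y = j` iff
:math:`\\alpha_{j-1} < Z \\le \\alpha_j`.  An equivalent formulation moves an
intercept into the linear predictor and shifts every cutpoint by the same
amount; all quantities computed downstream (surrogate and pseudo R-squared
values) are invariant to that location shift, so the standard form above is
used throughout.

Fitting is by Newton's method on the exact log-likelihood, which is concave
in :math:`(\\alpha, \\beta)` for cumulative models with a log-concave link
(Pratt, 1981), so Newton with step-halving is globally reliable and fast —
the bootstrap machinery elsewhere in the package refits this model hundreds
of thousands of times and warm-starts from a previous solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri

__all__ = [
    "OrdinalDataset",
    "ProbitParams",
    "ProbitFit",
    "SeparationError",
    "fit_probit",
    "cumulative_probs",
    "log_likelihood",
]

#: floor applied to category probabilities before taking logs, so that a
#: degenerate fitted probability yields a large negative log-likelihood
#: instead of -inf (keeps McFadden's R-squared finite on extreme fits).
PROB_FLOOR = 1e-300

# floor used inside score/Hessian ratios only (numerical safeguard; the
# log-likelihood itself uses PROB_FLOOR).
_RATIO_FLOOR = 1e-12

_LOG2 = float(np.log(2.0))


class SeparationError(RuntimeError):
    """Raised when the likelihood has no finite maximizer (complete or
    quasi-complete separation drives slopes to infinity)."""


@dataclass(frozen=True)
class OrdinalDataset:
    """An ordered categorical response with its numeric covariates.

    Attributes
    ----------
    X : ndarray, shape (n, p)
        Covariate matrix.
    y : ndarray, shape (n,)
        Integer responses in ``{1, ..., J}``.
    var_names : list of str
        Names of the ``p`` covariate columns.
    J : int
        Number of response categories.
    name : str
        Identifier used for provenance in fit objects.
    """

    X: np.ndarray
    y: np.ndarray
    var_names: tuple[str, ...]
    J: int
    name: str = "data"

    @classmethod
    def from_arrays(cls, X, y, var_names=None, name="data", J=None):
        """Build and validate a dataset.

        Binary responses coded ``{0, 1}`` are normalized to ``{1, 2}``.
        Every integer level between 1 and ``J`` must be observed.
        """
        X = np.ascontiguousarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-d matrix")
        y = np.asarray(y)
        if y.ndim != 1 or y.shape[0] != X.shape[0]:
            raise ValueError("y must be a vector with one entry per row of X")
        yi = np.asarray(np.rint(y), dtype=np.int64)
        if not np.allclose(y, yi):
            raise ValueError("response values must be integers")
        if yi.min() == 0:
            yi = yi + 1  # accept {0,...,J-1} coding, e.g. binary {0,1}
        levels = np.unique(yi)
        if levels.min() < 1:
            raise ValueError("response levels must be positive integers")
        J_obs = int(levels.max())
        if J is None:
            J = J_obs
        elif J < J_obs:
            raise ValueError(f"J={J} smaller than the largest observed level {J_obs}")
        if levels.size < 2:
            raise ValueError("response has a single observed category; need at least 2")
        missing = sorted(set(range(1, J + 1)) - set(levels.tolist()))
        if missing:
            raise ValueError(f"unobserved response categories {missing}: cutpoints not identified")
        if var_names is None:
            var_names = tuple(f"X{l + 1}" for l in range(X.shape[1]))
        else:
            var_names = tuple(str(v) for v in var_names)
        if len(var_names) != X.shape[1]:
            raise ValueError("var_names length must match number of covariate columns")
        if len(set(var_names)) != len(var_names):
            raise ValueError("covariate names must be unique")
        return cls(X=X, y=yi, var_names=var_names, J=J, name=name)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def columns(self, subset) -> np.ndarray:
        """Indices of the named covariates, in the order given."""
        if subset is None:
            return np.arange(self.p)
        lookup = {v: i for i, v in enumerate(self.var_names)}
        try:
            return np.array([lookup[v] for v in subset], dtype=np.intp)
        except KeyError as err:
            raise KeyError(f"unknown covariate {err.args[0]!r}; have {list(self.var_names)}") from None


@dataclass(frozen=True)
class ProbitParams:
    """Cutpoints and slopes of the cumulative probit model."""

    alpha: np.ndarray  # (J-1,) strictly increasing
    beta: np.ndarray  # (p,)

    def __post_init__(self):
        object.__setattr__(self, "alpha", np.atleast_1d(np.asarray(self.alpha, dtype=float)))
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float)))
        if self.alpha.size >= 2 and not np.all(np.diff(self.alpha) > 0):
            raise ValueError("cutpoints alpha must be strictly increasing")

    @property
    def J(self) -> int:
        return self.alpha.size + 1

    @property
    def p(self) -> int:
        return self.beta.size


@dataclass
class ProbitFit:
    """Result of a maximum-likelihood probit fit."""

    params: ProbitParams
    loglik: float
    null_loglik: float
    converged: bool
    dataset_ref: str
    var_subset: tuple[str, ...]
    n_obs: int
    beta_se: np.ndarray = field(default=None, repr=False)

    def wald_pvalues(self) -> np.ndarray:
        """Two-sided normal-approximation p-values for each slope."""
        z = np.abs(self.params.beta) / self.beta_se
        return 2.0 * ndtr(-z)


# ---------------------------------------------------------------------------
# likelihood internals


def _log_interval_prob_tail(u_lo, u_hi):
    """log(Phi(u_hi) - Phi(u_lo)) in log space, for intervals deep in a
    tail where the plain CDF difference underflows."""
    # reflect right-tail intervals into the left tail
    left = u_hi <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(left, u_hi, -u_lo)
        b = np.where(left, u_lo, -u_hi)
        la = log_ndtr(a)
        lb = log_ndtr(b)
        diff = np.where(np.isneginf(lb), 0.0, np.exp(np.minimum(lb - la, 0.0)))
        out = la + np.log1p(-diff)
    return out


def _log_interval_prob(u_lo, u_hi):
    """log(Phi(u_hi) - Phi(u_lo)), stable for endpoints far in either tail
    (u_lo < u_hi; either end may be +-inf)."""
    u_lo = np.asarray(u_lo, dtype=float)
    u_hi = np.asarray(u_hi, dtype=float)
    p = ndtr(u_hi) - ndtr(u_lo)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(p)
    # right-tail intervals cancel catastrophically in the plain difference
    # (both CDFs ~ 1); deep left-tail intervals eventually underflow
    tiny = (u_lo >= 5.0) | (p <= 1e-300)
    if np.any(tiny):
        out[tiny] = _log_interval_prob_tail(u_lo[tiny], u_hi[tiny])
    return np.maximum(out, np.log(PROB_FLOOR))


def _phi(u):
    out = np.zeros_like(u)
    fin = np.isfinite(u)
    out[fin] = np.exp(-0.5 * u[fin] ** 2) / np.sqrt(2.0 * np.pi)
    return out


def _loglik_grad_hess(theta, X, y0, J):
    """Exact log-likelihood, score, and Hessian at theta = (alpha, beta).

    Per observation the log-likelihood depends on the two interval
    endpoints ``u_hi = alpha_{y} - x'beta`` and ``u_lo = alpha_{y-1} -
    x'beta``; the Hessian is assembled blockwise from the second
    derivatives in (u_hi, u_lo).  Weights attached to a nonexistent
    endpoint (first/last category) are identically zero because the normal
    density vanishes at +-inf, so no masking is needed.
    """
    n, p = X.shape
    K = J - 1
    alpha = theta[:K]
    if K >= 2 and np.any(np.diff(alpha) <= 0):
        return -np.inf, None, None
    beta = theta[K:]
    eta = X @ beta
    a_ext = np.concatenate(([-np.inf], alpha, [np.inf]))
    u_hi = a_ext[y0 + 1] - eta
    u_lo = a_ext[y0] - eta

    logp = _log_interval_prob(u_lo, u_hi)
    ll = float(np.sum(logp))
    P = np.maximum(np.exp(logp), _RATIO_FLOOR)

    phi_hi = _phi(u_hi)
    phi_lo = _phi(u_lo)
    gh = phi_hi / P
    gl = phi_lo / P

    k1 = np.minimum(y0, K - 1)  # alpha index of u_hi (weight 0 when y0 == K)
    k0 = np.maximum(y0 - 1, 0)  # alpha index of u_lo (weight 0 when y0 == 0)

    grad = np.empty(K + p)
    grad[:K] = np.bincount(k1, gh, minlength=K) - np.bincount(k0, gl, minlength=K)
    grad[K:] = -X.T @ (gh - gl)

    t_hi = np.where(np.isfinite(u_hi), u_hi, 0.0) * phi_hi
    t_lo = np.where(np.isfinite(u_lo), u_lo, 0.0) * phi_lo
    w_hh = -t_hi / P - gh * gh
    w_ll = t_lo / P - gl * gl
    w_hl = gh * gl  # nonzero only for interior categories (both endpoints finite)

    H = np.empty((K + p, K + p))
    # alpha-alpha block: w_hh at (k1, k1), w_ll at (k0, k0), w_hl at (y0, y0-1)
    A = np.zeros((K, K))
    diag = np.bincount(k1, w_hh, minlength=K) + np.bincount(k0, w_ll, minlength=K)
    A[np.diag_indices(K)] = diag
    if K >= 2:
        sub = np.bincount(k0, w_hl, minlength=K)[: K - 1]
        A[np.arange(1, K), np.arange(K - 1)] += sub
        A[np.arange(K - 1), np.arange(1, K)] += sub
    H[:K, :K] = A
    # alpha-beta block: row k gets -sum_i [ (w_hh + w_hl) 1{k1=k} + (w_ll + w_hl) 1{k0=k} ] x_i
    r_hi = w_hh + w_hl
    r_lo = w_ll + w_hl
    B = np.empty((K, p))
    for k in range(K):
        w = np.where(k1 == k, r_hi, 0.0) + np.where(k0 == k, r_lo, 0.0)
        B[k] = -(w @ X)
    H[:K, K:] = B
    H[K:, :K] = B.T
    # beta-beta block
    wsum = w_hh + w_ll + 2.0 * w_hl
    H[K:, K:] = X.T @ (X * wsum[:, None])
    return ll, grad, H


def _start_values(X, y0, J):
    n = y0.size
    cum = np.cumsum(np.bincount(y0, minlength=J))[:-1] / n
    cum = np.clip(cum, 1.0 / (n + 1), 1.0 - 1.0 / (n + 1))
    alpha = ndtri(cum)
    # strictly increasing even with near-empty categories
    for k in range(1, alpha.size):
        if alpha[k] <= alpha[k - 1]:
            alpha[k] = alpha[k - 1] + 1e-6
    return np.concatenate([alpha, np.zeros(X.shape[1])])


def _newton(X, y0, J, start=None, gtol_scale=1e-9, max_iter=100):
    """Maximize the cumulative-probit log-likelihood by damped Newton.

    Returns ``(theta, loglik, hessian, converged)``.
    """
    n, p = X.shape
    K = J - 1
    theta = _start_values(X, y0, J) if start is None else np.array(start, dtype=float)
    ll, grad, H = _loglik_grad_hess(theta, X, y0, J)
    if grad is None:
        raise ValueError("start values have non-increasing cutpoints")
    gtol = max(gtol_scale * n, 1e-10)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < gtol:
            converged = True
            break
        Hn = -H
        ridge = 0.0
        for _attempt in range(6):
            try:
                delta = np.linalg.solve(Hn + ridge * np.eye(K + p), grad)
                break
            except np.linalg.LinAlgError:
                ridge = max(ridge * 10.0, 1e-8 * max(1.0, np.trace(Hn) / (K + p)))
        else:  # pragma: no cover - pathological
            break
        step = 1.0
        accepted = False
        while step > 1e-12:
            cand = theta + step * delta
            ll_c, grad_c, H_c = _loglik_grad_hess(cand, X, y0, J)
            if grad_c is not None and ll_c > ll - 1e-12:
                theta, ll, grad, H = cand, ll_c, grad_c, H_c
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
    return theta, ll, H, converged


def null_log_likelihood(y, J=None) -> float:
    """Log-likelihood of the intercepts-only model: the multinomial MLE
    ``sum_j f_j log(f_j / n)`` over observed category frequencies."""
    y = np.asarray(y)
    n = y.size
    freq = np.bincount(y - 1, minlength=(J or y.max()))
    freq = freq[freq > 0]
    return float(np.sum(freq * np.log(freq / n)))


def fit_probit(data: OrdinalDataset, subset=None, *, start=None, max_iter=100) -> ProbitFit:
    """Fit the cumulative probit model by maximum likelihood.

    Parameters
    ----------
    data : OrdinalDataset
    subset : sequence of str, optional
        Covariate names to include.  ``None`` uses all columns; an empty
        list fits the intercepts-only (null) model, whose cutpoints have the
        closed form ``Phi^{-1}(cumulative frequency)``.
    start : ndarray, optional
        Warm-start parameter vector ``(alpha, beta)`` matching the subset;
        used heavily by the bootstrap machinery.

    Raises
    ------
    SeparationError
        If the slopes diverge (complete separation).
    """
    if subset is None:
        subset = list(data.var_names)
    cols = data.columns(subset)
    J = data.J
    n = data.n
    y0 = data.y - 1
    ll0 = null_log_likelihood(data.y, J)

    if cols.size == 0:
        cum = np.cumsum(np.bincount(y0, minlength=J))[:-1] / n
        alpha = ndtri(np.clip(cum, 1e-12, 1 - 1e-12))
        params = ProbitParams(alpha=alpha, beta=np.zeros(0))
        return ProbitFit(
            params=params, loglik=ll0, null_loglik=ll0, converged=True,
            dataset_ref=data.name, var_subset=(), n_obs=n,
            beta_se=np.zeros(0),
        )

    if n < cols.size + J:
        raise ValueError(f"n={n} too small to identify {cols.size} slopes and {J - 1} cutpoints")

    Xs = data.X[:, cols]
    theta, ll, H, converged = _newton(Xs, y0, J, start=start, max_iter=max_iter)
    K = J - 1
    beta = theta[K:]

    # a standardized slope this large means an essentially deterministic
    # category boundary on the unit-scale latent variable
    col_scale = Xs.std(axis=0)
    col_scale[col_scale == 0] = 1.0
    if np.max(np.abs(beta) * col_scale) > 40.0:
        worst = data.var_names[cols[int(np.argmax(np.abs(beta) * col_scale))]]
        raise SeparationError(
            f"slope for {worst!r} diverged: data are (quasi-)completely separated"
        )

    beta_se = np.full(beta.shape, np.nan)
    try:
        cov = np.linalg.inv(-H)
        d = np.diag(cov)[K:]
        beta_se = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        pass

    return ProbitFit(
        params=ProbitParams(alpha=theta[:K], beta=beta),
        loglik=ll,
        null_loglik=ll0,
        converged=converged,
        dataset_ref=data.name,
        var_subset=tuple(data.var_names[c] for c in cols),
        n_obs=n,
        beta_se=beta_se,
    )


def cumulative_probs(params: ProbitParams, X) -> np.ndarray:
    """Category probabilities ``Pr(Y = j | x)`` for each row of ``X``.

    Returns an ``(n, J)`` matrix whose column ``j-1`` is
    ``Phi(alpha_j - x'beta) - Phi(alpha_{j-1} - x'beta)``; rows sum to 1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.p:
        raise ValueError(f"X has {X.shape[1]} columns but params expect {params.p}")
    eta = X @ params.beta
    cdf = ndtr(params.alpha[None, :] - eta[:, None])
    cdf = np.concatenate([np.zeros((X.shape[0], 1)), cdf, np.ones((X.shape[0], 1))], axis=1)
    return np.diff(cdf, axis=1)


def log_likelihood(params: ProbitParams, data: OrdinalDataset, subset=None) -> float:
    """Log-likelihood of ``params`` on ``data`` (category probabilities are
    floored at :data:`PROB_FLOOR`, so the result is finite)."""
    cols = data.columns(subset if subset is not None else None)
    Xs = data.X[:, cols] if subset is not None else data.X
    if Xs.shape[1] != params.p:
        raise ValueError("parameter dimension does not match covariate columns")
    eta = Xs @ params.beta
    a_ext = np.concatenate(([-np.inf], params.alpha, [np.inf]))
    y0 = data.y - 1
    return float(np.sum(_log_interval_prob(a_ext[y0] - eta, a_ext[y0 + 1] - eta)))
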