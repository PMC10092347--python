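"""Percentile-bootstrap interval for the surrogate R-squared.

For each of ``B`` bootstrap replicates: resample rows with replacement,
refit the full probit model, draw *one* surrogate response from the
replicate fit, and compute the OLS R-squared of that surrogate on the
evaluation subset.  The interval is the pair of empirical
``alpha/2`` / ``1 - alpha/2`` quantiles of the B copies (inverse-CDF /
type-1 quantiles, so results are bit-reproducible given seeds).  One draw
per replicate suffices because the resampling itself already averages over
the surrogate noise.

The same resampling skeleton with the McKelvey–Zavoina statistic
substituted (refitting the evaluation submodel per replicate) is provided
for comparison experiments; its coverage collapses in designs where the MZ
measure violates nested-model monotonicity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .probit import OrdinalDataset, fit_probit, _newton
from .rsq import ols_r2
from .sim_designs import SimulationDesign
from .surrogate import _truncnorm_std, child_rng

__all__ = ["IntervalResult", "CoverageResult", "bootstrap_interval", "coverage_experiment"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntervalResult:
    """Percentile interval with its underlying bootstrap copies."""

    lower: float
    upper: float
    level: float
    B: int
    copies: np.ndarray = field(repr=False)
    seed: int = 0
    measure: str = "surrogate"
    redraws: int = 0

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


def _quantiles(copies: np.ndarray, level: float):
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(copies, [a, 1.0 - a], method="inverted_cdf")
    return float(lo), float(hi)


def _fast_r2(yc: np.ndarray, Xc: np.ndarray) -> float:
    """Centered-inputs OLS R-squared via the normal equations (hot path)."""
    g = Xc.T @ Xc
    b = Xc.T @ yc
    try:
        coef = np.linalg.solve(g, b)
    except np.linalg.LinAlgError:
        return ols_r2(yc, Xc)
    sst = float(yc @ yc)
    return min(max(float(b @ coef) / sst, 0.0), 1.0) if sst > 0 else 0.0


def bootstrap_interval(data: OrdinalDataset, full_subset=None, eval_subset=None,
                       B: int = 2000, level: float = 0.95, seed: int = 0,
                       measure: str = "surrogate",
                       max_redraw_rate: float = 0.05) -> IntervalResult:
    """Percentile-bootstrap interval for an R-squared measure.

    ``full_subset`` names the full model refit on every replicate;
    ``eval_subset`` (a subset of it) names the model whose R-squared is
    evaluated.  ``measure`` is ``"surrogate"`` (common surrogate from the
    replicate's full fit) or ``"mz"`` (McKelvey–Zavoina of the refitted
    evaluation submodel).  Replicates in which a response category vanishes
    are redrawn and counted; a redraw rate above ``max_redraw_rate`` raises.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if full_subset is None:
        full_subset = list(data.var_names)
    if eval_subset is None:
        eval_subset = list(full_subset)
    if not set(eval_subset) <= set(full_subset):
        raise ValueError("eval_subset must be contained in full_subset")
    if measure not in ("surrogate", "mz"):
        raise ValueError("measure must be 'surrogate' or 'mz'")

    n = data.n
    J = data.J
    full_cols = data.columns(full_subset)
    eval_cols = data.columns(eval_subset)
    K = J - 1

    # warm starts: fit on the original sample once
    fit_full = fit_probit(data, full_subset)
    theta_full0 = np.concatenate([fit_full.params.alpha, fit_full.params.beta])
    if measure == "mz":
        fit_eval = fit_probit(data, eval_subset)
        theta_eval0 = np.concatenate([fit_eval.params.alpha, fit_eval.params.beta])

    Xf = data.X[:, full_cols]
    Xe = data.X[:, eval_cols]
    y = data.y
    a_pad = np.empty(J + 1)
    a_pad[0], a_pad[-1] = -np.inf, np.inf

    copies = np.empty(B)
    redraws = 0
    for b in range(B):
        rng = child_rng(seed, 1, b)
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if np.bincount(yb - 1, minlength=J).min() > 0:
                break
            redraws += 1
            if redraws > max(10, max_redraw_rate * B):
                raise RuntimeError(
                    f"more than {max_redraw_rate:.0%} of bootstrap replicates lost a "
                    "response category; sample too small for this bootstrap")
        y0b = yb - 1
        if measure == "surrogate":
            Xb = Xf[idx]
            theta, _, _, _ = _newton(Xb, y0b, J, start=theta_full0)
            beta_b = theta[K:]
            a_pad[1:J] = theta[:K]
            mu = Xb @ beta_b
            s = mu + _truncnorm_std(rng, a_pad[y0b] - mu, a_pad[yb] - mu)
            Xeb = Xe[idx] if eval_cols.size else None
            if Xeb is None:
                copies[b] = 0.0
            else:
                copies[b] = _fast_r2(s - s.mean(), Xeb - Xeb.mean(axis=0))
        else:
            Xeb = Xe[idx]
            theta, _, _, _ = _newton(Xeb, y0b, J, start=theta_eval0)
            zhat = Xeb @ theta[K:]
            ssr = float(np.sum((zhat - zhat.mean()) ** 2))
            copies[b] = ssr / (ssr + n)

    if redraws:
        logger.info("bootstrap_interval: %d replicates redrawn (vanished category)", redraws)
    lo, hi = _quantiles(copies, level)
    return IntervalResult(lower=lo, upper=hi, level=level, B=B, copies=copies,
                          seed=int(seed), measure=measure, redraws=redraws)


@dataclass(frozen=True)
class CoverageResult:
    """Outcome of a repeated-interval experiment against an analytic target."""

    coverage: float
    mean_lower: float
    mean_upper: float
    target: float
    reps: int
    level: float
    measure: str


def coverage_experiment(design: SimulationDesign, eval_subset=None, reps: int = 100,
                        B: int = 2000, level: float = 0.95, seed: int = 0,
                        measure: str = "surrogate", n=None) -> CoverageResult:
    """Fraction of replications whose bootstrap interval contains the
    design's population-limit R-squared, plus the mean endpoints."""
    target = design.limit_r2(eval_subset)
    lowers = np.empty(reps)
    uppers = np.empty(reps)
    hits = 0
    for r in range(reps):
        data, _ = design.draw((int(seed), 4, r), n=n)
        ci = bootstrap_interval(data, full_subset=None, eval_subset=eval_subset,
                                B=B, level=level, seed=(int(seed) * 1000003 + r) % (2**31),
                                measure=measure)
        lowers[r], uppers[r] = ci.lower, ci.upper
        hits += ci.contains(target)
    return CoverageResult(coverage=hits / reps, mean_lower=float(lowers.mean()),
                          mean_upper=float(uppers.mean()), target=target,
                          reps=reps, level=level, measure=measure)
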