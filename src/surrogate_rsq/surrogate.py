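"""Surrogate-response generation for probit models.

Given fitted (or true) parameters, the surrogate response for observation
``i`` with category ``y_i = j`` is a draw from the latent normal
``N(x_i' beta, 1)`` truncated to that category's interval
``(alpha_{j-1}, alpha_j]``.  Pooled over observations the surrogate
reproduces the unconditional latent distribution, and every draw falls in
the interval implied by its observed category — the two properties that
make it a faithful continuous stand-in for the discrete response.

Sampling is by inverse-CDF on a uniform rescaled to
``[Phi(a - mu), Phi(b - mu)]``, switching to log-CDF arithmetic when the
whole interval sits more than 8 standard deviations into a tail, where the
plain CDF difference underflows to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri, ndtri_exp

from .probit import OrdinalDataset, ProbitFit, ProbitParams

__all__ = ["SurrogateSample", "generate_surrogate", "generate_surrogate_batch", "child_rng"]

_TAIL = 8.0


def child_rng(seed, *key) -> np.random.Generator:
    """Deterministic, order-independent sub-stream ``(seed, *key)``.

    ``seed`` may itself be a tuple (a parent key); every stochastic routine
    in the package derives its generator this way (draw index, bootstrap
    replicate index, replication index), so results do not depend on
    execution order.
    """
    base = tuple(seed) if isinstance(seed, (tuple, list)) else (seed,)
    return np.random.default_rng(
        np.random.SeedSequence(tuple(int(k) for k in base) + tuple(int(k) for k in key)))


@dataclass(frozen=True)
class SurrogateSample:
    """One surrogate draw: a continuous vector consistent with the observed
    categories under ``source_params``."""

    s: np.ndarray
    source_params: ProbitParams
    seed: object
    draw_index: int


def _truncnorm_std(rng: np.random.Generator, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Standard-normal draws truncated to (a, b], elementwise, a < b."""
    n = a.shape[0]
    u = rng.random(n)
    out = np.empty(n)

    # intervals entirely in the right tail are reflected into the left tail
    right = a >= _TAIL
    left = b <= -_TAIL
    mid = ~(right | left)

    if np.any(mid):
        lo = ndtr(a[mid])
        hi = ndtr(b[mid])
        out[mid] = ndtri(lo + u[mid] * (hi - lo))

    for mask, flip in ((left, False), (right, True)):
        if not np.any(mask):
            continue
        aa = -b[mask] if flip else a[mask]
        bb = -a[mask] if flip else b[mask]
        # log-space interpolation of the CDF over [Phi(aa), Phi(bb)], bb <= -_TAIL
        la = log_ndtr(aa)
        lb = log_ndtr(bb)
        uu = u[mask]
        with np.errstate(divide="ignore"):
            # log(Phi(aa) + u (Phi(bb) - Phi(aa))) done relative to lb
            ratio = np.where(np.isneginf(la), 0.0, np.exp(la - lb))
            logc = lb + np.log(ratio + uu * (1.0 - ratio))
        draw = ndtri_exp(logc)
        out[mask] = -draw if flip else draw

    # floating-point rounding can land exactly on a boundary; nudge inward
    at_lo = out <= a
    if np.any(at_lo):
        out[at_lo] = np.nextafter(a[at_lo], np.inf)
    at_hi = out > b
    if np.any(at_hi):
        out[at_hi] = np.nextafter(b[at_hi], -np.inf)
    return out


def _draw(params: ProbitParams, X: np.ndarray, y: np.ndarray, rng) -> np.ndarray:
    if X.shape[1] != params.p:
        raise ValueError("params dimension does not match covariates")
    if params.alpha.size >= 2 and np.any(np.diff(params.alpha) <= 0):
        raise ValueError("tied cutpoints give an empty category interval")
    mu = X @ params.beta
    a_ext = np.concatenate(([-np.inf], params.alpha, [np.inf]))
    lo = a_ext[y - 1] - mu
    hi = a_ext[y] - mu
    return mu + _truncnorm_std(rng, lo, hi)


def _resolve(params_or_fit) -> ProbitParams:
    return params_or_fit.params if isinstance(params_or_fit, ProbitFit) else params_or_fit


def generate_surrogate(params, data: OrdinalDataset, seed, draw_index: int = 0,
                       subset=None) -> SurrogateSample:
    """Draw one surrogate response vector.

    Parameters
    ----------
    params : ProbitParams or ProbitFit
        Model generating the surrogate (the *full* model, when the result
        will be used for nested comparisons).
    data : OrdinalDataset
    seed : int
        Master seed; the actual stream is the sub-stream ``(seed, 0,
        draw_index)`` so a batch draw with ``M=1`` is identical to this call.
    subset : sequence of str, optional
        Covariate columns the params refer to (default: all columns).
    """
    params = _resolve(params)
    cols = data.columns(subset) if subset is not None else np.arange(data.p)
    rng = child_rng(seed, 0, draw_index)
    s = _draw(params, data.X[:, cols], data.y, rng)
    return SurrogateSample(s=s, source_params=params, seed=seed, draw_index=draw_index)


def generate_surrogate_batch(params, data: OrdinalDataset, M: int, seed,
                             subset=None) -> list[SurrogateSample]:
    """``M`` independent surrogate draws with reproducible per-draw streams."""
    if M < 1:
        raise ValueError("M must be >= 1")
    return [generate_surrogate(params, data, seed, draw_index=m, subset=subset)
            for m in range(int(M))]
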