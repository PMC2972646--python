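"""Multivariate-normal rectangle probabilities.

Liability-threshold twin likelihoods reduce to probabilities of axis-aligned
rectangles under a correlated standard-normal vector: dimension 1 for a
singleton with one trait, 2 for a complete pair with one trait (or a
singleton with two), and 4 for a complete pair with two traits.

Dimensions 1 and 2 are computed exactly (error function / Owen's T);
dimension 3 and above use a batched, deterministic Genz-type quasi-Monte
Carlo algorithm with a fixed scrambled-Sobol sequence, so repeated
evaluations of a log-likelihood agree to the digit.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky
from scipy.special import ndtr, ndtri, owens_t
from scipy.stats import qmc

__all__ = ["bvn_cdf", "norm_rect", "bvn_rect", "genz_rect", "mvn_rect"]

_TINY = 1e-15


def bvn_cdf(h, k, rho):
    """Standard bivariate normal CDF  P(X <= h, Y <= k)  with correlation rho.

    Exact (to double precision) via Owen's T function.  ``h``, ``k`` and
    ``rho`` broadcast; infinite limits are handled.
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(rho, float)
    )
    out = np.empty(h.shape, float)

    # Degenerate correlation: comonotone / antithetic limits.
    hi_r = rho >= 1.0 - 1e-14
    lo_r = rho <= -1.0 + 1e-14
    if hi_r.any():
        out[hi_r] = ndtr(np.minimum(h[hi_r], k[hi_r]))
    if lo_r.any():
        out[lo_r] = np.clip(ndtr(h[lo_r]) + ndtr(k[lo_r]) - 1.0, 0.0, 1.0)

    m = ~(hi_r | lo_r)
    if m.any():
        hm, km, rm = h[m], k[m], rho[m]
        # Nudge exact zeros: the Owen formula is continuous in h, k, so a
        # 1e-15 offset costs nothing and avoids the 0/0 corner cases.
        hz = np.where(hm == 0.0, _TINY, hm)
        kz = np.where(km == 0.0, _TINY, km)
        s = np.sqrt(1.0 - rm * rm)
        with np.errstate(divide="ignore", invalid="ignore"):
            ah = (kz - rm * hz) / (hz * s)
            ak = (hz - rm * kz) / (kz * s)
        # Infinite h or k: reduce to the univariate marginal.
        inf_mask = np.isinf(hm) | np.isinf(km)
        ah = np.where(np.isnan(ah), 0.0, ah)
        ak = np.where(np.isnan(ak), 0.0, ak)
        delta = np.where(hz * kz < 0.0, 0.5, 0.0)
        val = (
            0.5 * (ndtr(hm) + ndtr(km))
            - owens_t(hz, ah)
            - owens_t(kz, ak)
            - delta
        )
        if inf_mask.any():
            # P(X<=h, Y<=inf) = Phi(h); any -inf limit gives 0.
            alt = np.where(
                (hm == -np.inf) | (km == -np.inf),
                0.0,
                np.where(hm == np.inf, ndtr(km), ndtr(hm)),
            )
            val = np.where(inf_mask, alt, val)
        out[m] = np.clip(val, 0.0, 1.0)
    return out if out.shape else float(out)


def norm_rect(lower, upper):
    """P(lower < Z <= upper) for a standard normal, elementwise."""
    return np.clip(ndtr(upper) - ndtr(lower), 0.0, 1.0)


def bvn_rect(lower, upper, rho):
    """Exact rectangle probability for a standard bivariate normal.

    Parameters
    ----------
    lower, upper : arrays of shape (..., 2); -inf/+inf allowed.
    rho : scalar or array broadcastable to the leading shape.
    """
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    p = (
        bvn_cdf(upper[..., 0], upper[..., 1], rho)
        - bvn_cdf(lower[..., 0], upper[..., 1], rho)
        - bvn_cdf(upper[..., 0], lower[..., 1], rho)
        + bvn_cdf(lower[..., 0], lower[..., 1], rho)
    )
    return np.clip(p, 0.0, 1.0)


from functools import lru_cache


@lru_cache(maxsize=32)
def _sobol_points(d: int, n_points: int, seed: int) -> np.ndarray:
    # Power-of-two Sobol draws; scrambling seeded so results are fixed.
    # Cached: likelihood optimization re-uses the same point set thousands
    # of times, and a fixed set keeps -2lnL deterministic to the digit.
    m = max(1, int(np.ceil(np.log2(max(n_points, 2)))))
    eng = qmc.Sobol(d, scramble=True, seed=seed)
    return eng.random_base2(m)


def genz_rect(lower, upper, corr, n_points: int = 4096, seed: int = 0):
    """Batched Genz sequential-conditioning QMC rectangle probabilities.

    All rectangles share one correlation matrix, which is the structure the
    twin likelihood produces (one matrix per zygosity).

    Parameters
    ----------
    lower, upper : (B, d) arrays of rectangle bounds (+-inf allowed).
    corr : (d, d) correlation matrix, positive definite.
    n_points : QMC sample size (rounded up to a power of two).
    seed : scrambling seed; fixed default makes results deterministic.

    Returns
    -------
    (B,) array of probabilities.
    """
    lower = np.atleast_2d(np.asarray(lower, float))
    upper = np.atleast_2d(np.asarray(upper, float))
    d = lower.shape[1]
    if d == 1:
        return norm_rect(lower[:, 0], upper[:, 0])
    if d == 2:
        return bvn_rect(lower, upper, float(np.asarray(corr)[0, 1]))
    corr = np.asarray(corr, float)
    # Jitter guard: tiny ridge keeps Cholesky alive at near-singular corners
    # (e.g. MZ pairs with a2 -> 1) without visibly moving the probability.
    try:
        L = cholesky(corr, lower=True)
    except np.linalg.LinAlgError:
        L = cholesky(corr + 1e-10 * np.eye(d), lower=True)

    w = _sobol_points(d - 1, n_points, seed)  # (n, d-1)
    n = w.shape[0]
    B = lower.shape[0]

    dlo = ndtr(lower[:, 0] / L[0, 0])[:, None] * np.ones((1, n))
    dhi = ndtr(upper[:, 0] / L[0, 0])[:, None] * np.ones((1, n))
    f = dhi - dlo
    y = np.empty((B, n, d - 1))
    for i in range(1, d):
        z = dlo + w[None, :, i - 1] * (dhi - dlo)
        y[:, :, i - 1] = ndtri(np.clip(z, _TINY, 1.0 - 1e-16))
        t = np.einsum("j,bnj->bn", L[i, : i], y[:, :, : i])
        with np.errstate(invalid="ignore"):
            dlo = ndtr((lower[:, i][:, None] - t) / L[i, i])
            dhi = ndtr((upper[:, i][:, None] - t) / L[i, i])
        f = f * np.clip(dhi - dlo, 0.0, 1.0)
    return np.clip(f.mean(axis=1), 0.0, 1.0)


def mvn_rect(lower, upper, corr, n_points: int = 4096, seed: int = 0):
    """Rectangle probability of a correlated standard-normal vector.

    Dispatches on dimension: exact formulas for d <= 2, batched Genz QMC
    otherwise.  ``lower``/``upper`` may be a single rectangle (d,) or a
    batch (B, d) sharing ``corr``.
    """
    lower = np.asarray(lower, float)
    single = lower.ndim == 1
    lower = np.atleast_2d(lower)
    upper = np.atleast_2d(np.asarray(upper, float))
    p = genz_rect(lower, upper, corr, n_points=n_points, seed=seed)
    return float(p[0]) if single else p
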