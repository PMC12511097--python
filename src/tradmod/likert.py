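"""Threshold discretization of latent scores onto 1-5 Likert items.

An item response is produced by cutting a standard-normal *propensity*

    y* = shift + lambda * z_construct + sqrt(1 - lambda^2) * noise

at fixed z-scale thresholds (default: equal-probability quintile cuts).  The
``shift`` moves probability mass across categories and is solved so the
expected item score equals the construct mean.

Because categorisation attenuates product-moment correlations, the module
also provides exact first/second moments of discretized items (via the
bivariate normal CDF) and solvers that *calibrate* generation parameters so
that observed moments - within-construct item correlations (convergent
validity) and between-construct composite correlations - land on requested
targets.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import owens_t
from scipy.stats import norm

__all__ = [
    "bvn_cdf", "discretize", "item_mean", "solve_shift", "item_moments",
    "item_cross_cov", "item_cont_cov", "solve_within_loading",
    "solve_latent_corr", "solve_pair_latent_corr", "solve_cont_latent_corr",
    "composite_variance",
]

_CATS = np.arange(1, 6)


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    Owen's-T formula; handles infinite bounds and |rho| -> 1 degeneracies.
    """
    if np.isneginf(h) or np.isneginf(k):
        return 0.0
    if np.isposinf(h):
        return float(norm.cdf(k))
    if np.isposinf(k):
        return float(norm.cdf(h))
    if abs(rho) >= 1 - 1e-12:
        if rho > 0:
            return float(norm.cdf(min(h, k)))
        return float(max(norm.cdf(h) + norm.cdf(k) - 1, 0.0))
    if rho == 0.0:
        return float(norm.cdf(h) * norm.cdf(k))
    denom = np.sqrt(1 - rho * rho)
    # Owen (1956): Phi2 = (Phi(h)+Phi(k))/2 - T(h,ah) - T(k,ak) - delta
    eps = 1e-15
    hh = h if abs(h) > eps else eps
    kk = k if abs(k) > eps else eps
    ah = (kk - rho * hh) / (denom * hh)
    ak = (hh - rho * kk) / (denom * kk)
    val = 0.5 * (norm.cdf(h) + norm.cdf(k)) - owens_t(hh, ah) - owens_t(kk, ak)
    if hh * kk < 0 or (hh * kk == 0 and hh + kk < 0):
        val -= 0.5
    return float(min(max(val, 0.0), 1.0))


def discretize(propensity: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Map propensities to integer categories 1..len(thresholds)+1."""
    return 1 + np.searchsorted(thresholds, propensity, side="left")


def _cat_probs(shift: float, thresholds: np.ndarray) -> np.ndarray:
    edges = np.concatenate([[-np.inf], np.asarray(thresholds), [np.inf]])
    return norm.cdf(edges[1:] - shift) - norm.cdf(edges[:-1] - shift)


def item_mean(shift: float, thresholds: np.ndarray) -> float:
    return float((_cat_probs(shift, thresholds) * _CATS[: len(thresholds) + 1]).sum())


def solve_shift(target_mean: float, thresholds: np.ndarray) -> float:
    """Propensity shift giving the requested expected item score."""
    lo, hi = 1.0 + 1e-9, len(thresholds) + 1 - 1e-9
    if not (lo < target_mean < hi):
        raise ValueError(f"target item mean {target_mean} unreachable on this scale")
    return brentq(lambda s: item_mean(s, thresholds) - target_mean,
                  -8.0, 8.0, xtol=1e-12)


def item_moments(shift: float, thresholds: np.ndarray):
    """(mean, variance) of a discretized item."""
    p = _cat_probs(shift, thresholds)
    cats = _CATS[: len(p)]
    m = float((p * cats).sum())
    return m, float((p * cats ** 2).sum() - m * m)


def item_cross_cov(rho: float, shift1: float, shift2: float,
                   thresholds: np.ndarray) -> float:
    """Covariance of two discretized items whose propensities correlate rho."""
    t = np.asarray(thresholds)
    u1 = np.concatenate([[-np.inf], t - shift1, [np.inf]])
    u2 = np.concatenate([[-np.inf], t - shift2, [np.inf]])
    n = len(u1)
    cdf = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            cdf[i, j] = bvn_cdf(u1[i], u2[j], rho)
    P = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    cats = _CATS[: n - 1]
    exy = float((P * np.outer(cats, cats)).sum())
    m1 = item_mean(shift1, t)
    m2 = item_mean(shift2, t)
    return exy - m1 * m2


def composite_variance(k: int, item_var: float, within_cov: float) -> float:
    """Variance of the unit-weighted mean of k exchangeable items."""
    return (item_var + (k - 1) * within_cov) / k


def solve_within_loading(target_ave: float, shift: float,
                         thresholds: np.ndarray) -> float:
    """Generation loading such that the observed inter-item correlation of a
    construct equals ``target_ave`` (the convergent-validity target).

    Discretization shrinks correlations, so the solved loading exceeds
    sqrt(target_ave); values are clamped just below 1 when the target is not
    reachable.
    """
    _, v = item_moments(shift, thresholds)

    def f(lam):
        return item_cross_cov(lam * lam, shift, shift, thresholds) / v - target_ave

    hi = 0.9995
    if f(hi) < 0:      # unreachable: strongest feasible loading
        return hi
    return brentq(f, 1e-6, hi, xtol=1e-10)


def item_cont_cov(rho: float, shift: float, thresholds: np.ndarray) -> float:
    """Covariance between a discretized item and a continuous N(0,1) covariate
    whose correlation with the item propensity is rho (exactly linear in rho)."""
    t = np.asarray(thresholds)
    return float(rho * norm.pdf(t - shift).sum())


def solve_pair_latent_corr(target: float, lam1: float, lam2: float,
                           shift1: float, shift2: float,
                           thresholds: np.ndarray) -> float:
    """Latent correlation such that a factor analysis of the discretized
    items *recovers* ``target``.

    The recovered inter-construct correlation is (cross item covariance) /
    sqrt(within-covariance product); this inverts that map.
    """
    if target == 0.0:
        return 0.0
    w1 = item_cross_cov(lam1 * lam1, shift1, shift1, thresholds)
    w2 = item_cross_cov(lam2 * lam2, shift2, shift2, thresholds)
    goal = target * np.sqrt(w1 * w2)

    def f(phi):
        return item_cross_cov(lam1 * lam2 * phi, shift1, shift2, thresholds) - goal

    lo, hi = -0.9995, 0.9995
    if f(hi) < 0:
        return hi
    if f(lo) > 0:
        return lo
    return brentq(f, lo, hi, xtol=1e-10)


def solve_cont_latent_corr(target: float, lam: float, shift: float,
                           thresholds: np.ndarray) -> float:
    """Latent correlation with a *continuous* covariate (e.g. a dummy) such
    that the factor-analytic recovery lands on ``target``."""
    if target == 0.0:
        return 0.0
    w = item_cross_cov(lam * lam, shift, shift, thresholds)
    c1 = norm.pdf(np.asarray(thresholds) - shift).sum()
    return float(np.clip(target * np.sqrt(w) / (lam * c1), -0.9995, 0.9995))


def solve_latent_corr(target_composite_corr: float,
                      lam1: float, lam2: float,
                      shift1: float, shift2: float,
                      k1: int, k2: int,
                      thresholds: np.ndarray) -> float:
    """Latent construct correlation reproducing a target composite correlation.

    Inverts the exact moment map latent-corr -> observed composite corr for
    two constructs with k1/k2 exchangeable items.
    """
    if target_composite_corr == 0.0:
        return 0.0
    _, v1 = item_moments(shift1, thresholds)
    _, v2 = item_moments(shift2, thresholds)
    w1 = item_cross_cov(lam1 * lam1, shift1, shift1, thresholds)
    w2 = item_cross_cov(lam2 * lam2, shift2, shift2, thresholds)
    cv1 = composite_variance(k1, v1, w1)
    cv2 = composite_variance(k2, v2, w2)
    target_cov = target_composite_corr * np.sqrt(cv1 * cv2)

    def f(phi):
        return item_cross_cov(lam1 * lam2 * phi, shift1, shift2, thresholds) - target_cov

    lo, hi = -0.9995, 0.9995
    if f(hi) < 0:
        return hi
    if f(lo) > 0:
        return lo
    return brentq(f, lo, hi, xtol=1e-10)
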