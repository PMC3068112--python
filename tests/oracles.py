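"""Independent oracles used to cross-check the implementation.

Each oracle recomputes a quantity by a different route than the package:
numeric maximum-likelihood for two-point linkage, exhaustive enumeration
for marker ordering and interval overlap, and an EM normal-mixture fit for
interval-mapping LOD scores.  They are deliberately slow and simple.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize_scalar


def two_point_lod_numeric(k: int, n: int) -> tuple[float, float]:
    """(theta_hat, LOD) by numeric maximisation of the binomial likelihood
    ratio against theta = 0.5."""
    def nll(t: float) -> float:
        t = min(max(t, 1e-12), 0.5)
        return -(k * math.log(t) + (n - k) * math.log(1.0 - t))

    if k == 0:
        theta = 0.0
    else:
        theta = float(minimize_scalar(nll, bounds=(1e-12, 0.5), method="bounded").x)
    ll_hat = 0.0
    if k > 0:
        ll_hat += k * math.log(theta)
    if n - k > 0:
        ll_hat += (n - k) * math.log(1.0 - theta)
    lod = (ll_hat - n * math.log(0.5)) / math.log(10.0)
    return theta, max(lod, 0.0)


def best_order_exhaustive(theta: np.ndarray) -> tuple[list[int], float]:
    """Minimum sum of adjacent recombination fractions over all orders."""
    m = theta.shape[0]
    best, best_cost = None, np.inf
    for perm in itertools.permutations(range(m)):
        if perm[0] > perm[-1]:
            continue
        cost = sum(theta[a, b] for a, b in zip(perm[:-1], perm[1:]))
        if cost < best_cost - 1e-12:
            best, best_cost = list(perm), cost
    return best, best_cost


def overlap_proportion_brute(intervals_a, intervals_b) -> float:
    """Literal enumeration of the co-location overlap proportion."""
    def overlaps(x, y):
        return x[0] == y[0] and x[1] <= y[2] and y[1] <= x[2]

    count = 0
    for iv in intervals_a:
        if any(overlaps(iv, jv) for jv in intervals_b):
            count += 1
    for jv in intervals_b:
        if any(overlaps(jv, iv) for iv in intervals_a):
            count += 1
    return count / (len(intervals_a) + len(intervals_b))


def em_mixture_lod(weights: np.ndarray, y: np.ndarray,
                   n_iter: int = 200, tol: float = 1e-10) -> float:
    """Interval-mapping LOD from an EM fit of the two-component normal
    mixture y_i ~ w_i N(mu1, s2) + (1 - w_i) N(mu0, s2).

    ``weights`` are the prior P(genotype = 1 | flanking markers).  The null
    is a single normal.  This is the likelihood the regression scan
    approximates, fitted by a different algorithm.
    """
    y = np.asarray(y, dtype=float)
    w = np.clip(np.asarray(weights, dtype=float), 1e-9, 1.0 - 1e-9)
    mu0, mu1 = np.quantile(y, 0.25), np.quantile(y, 0.75)
    s2 = np.var(y)
    ll_old = -np.inf
    for _ in range(n_iter):
        d1 = np.exp(-0.5 * (y - mu1) ** 2 / s2)
        d0 = np.exp(-0.5 * (y - mu0) ** 2 / s2)
        num = w * d1
        den = num + (1.0 - w) * d0
        den = np.where(den > 0, den, 1e-300)
        p = num / den
        mu1 = float(np.sum(p * y) / max(np.sum(p), 1e-12))
        mu0 = float(np.sum((1 - p) * y) / max(np.sum(1 - p), 1e-12))
        s2 = float(np.sum(p * (y - mu1) ** 2 + (1 - p) * (y - mu0) ** 2) / len(y))
        s2 = max(s2, 1e-12)
        ll = float(np.sum(np.log(
            w * np.exp(-0.5 * (y - mu1) ** 2 / s2) / math.sqrt(2 * math.pi * s2)
            + (1 - w) * np.exp(-0.5 * (y - mu0) ** 2 / s2) / math.sqrt(2 * math.pi * s2)
        )))
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    mu = float(np.mean(y))
    s2n = float(np.var(y))
    ll_null = float(np.sum(
        -0.5 * (y - mu) ** 2 / s2n - 0.5 * math.log(2 * math.pi * s2n)))
    return max((ll - ll_null) / math.log(10.0), 0.0)
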