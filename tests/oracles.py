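"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where possible, the libraries)
used by the implementation: exact integer arithmetic for the discrete tests,
explicit dense matrix algebra for GLS, and a literal step-up loop for BH.
"""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration with integer weights.

    Point probabilities share the denominator C(N, n), so the minimum-
    likelihood comparison is exact on integers.
    """
    N, K, n = a + b + c + d, a + b, a + c
    lo, hi = max(0, K + n - N), min(K, n)
    weights = {k: comb(K, k) * comb(N - K, n - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    total = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(total, comb(N, n)))


def binomial_two_sided_oracle(k: int, n: int, num: int, den: int) -> float:
    """Two-sided binomial p at success probability num/den, exact integers.

    Point probabilities share the denominator den**n, leaving integer weights
    C(n,j) * num**j * (den-num)**(n-j).
    """
    weights = [comb(n, j) * num**j * (den - num) ** (n - j) for j in range(n + 1)]
    w_obs = weights[k]
    total = sum(w for w in weights if w <= w_obs)
    return float(Fraction(total, den**n))


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the literal step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def gls_oracle(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Generalized least squares by explicit whitening with the known covariance.

    Returns (beta, unit covariance of beta, residual variance estimate).
    """
    L = np.linalg.cholesky(V)
    Linv = np.linalg.inv(L)
    Xw, yw = Linv @ X, Linv @ y
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    n, p = X.shape
    s2 = float(resid @ resid / (n - p))
    cov_unit = np.linalg.inv(Xw.T @ Xw)
    return beta, cov_unit, s2
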