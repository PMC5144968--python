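"""Site-frequency-spectrum diversity estimators and neutrality tests.

This is the mathematical core of the package: per-site estimators of the
population mutation rate theta (pi, Watterson, and the linear/quadratic
derived-frequency weightings theta_L / theta_H) and the variance-normalized
neutrality tests built from their differences:

* Tajima's D        = (theta_pi - theta_W) / sd  — rare-allele excess.
* Fay & Wu's H      = (theta_pi - theta_L) / sd  — high-frequency-derived
  excess, the hitchhiking signature (normalized form of Zeng et al. 2006;
  the unnormalized theta_pi - theta_H is also exposed).
* Zeng's E          = (theta_L - theta_W) / sd   — post-sweep recovery.

All estimators operate on per-site allele counts: ``(m, n)`` minor/called
counts for the polarization-invariant quantities (theta_pi, theta_W, D) and
``(d, n)`` derived/called counts for the polarized ones (theta_L, theta_H,
H, E).  Monomorphic sites contribute zero; a statistic whose input has no
segregating sites is undefined and returned as NaN, never as 0.

With missing genotypes the per-site called-allele count n varies; per-site
contributions use each site's own n, while the variance constants of the
test statistics use a single representative n (the caller usually passes
the window median, see :func:`constants`).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np

__all__ = [
    "SfsConstants",
    "constants",
    "site_contributions",
    "watterson",
    "tajimas_d",
    "fay_wu_h",
    "faywu_h_raw",
    "zengs_e",
    "brute_force_pi",
]


@dataclass(frozen=True)
class SfsConstants:
    """Normalization constants for a sample of ``n`` sequences.

    a_n and b_n are the partial harmonic sums sum(1/i) and sum(1/i^2) for
    i in 1..n-1; b_n1 extends b_n by 1/n^2 (needed by the H variance).
    e1, e2 are Tajima's variance coefficients.
    """

    n: int
    a_n: float
    b_n: float
    b_n1: float
    e1: float
    e2: float


@lru_cache(maxsize=1024)
def constants(n: int) -> SfsConstants:
    """Harmonic sums and Tajima variance coefficients for ``n`` sequences."""
    n = int(n)
    if n < 2:
        raise ValueError(f"need at least 2 sequences, got n={n}")
    i = np.arange(1, n, dtype=float)
    a_n = float(np.sum(1.0 / i))
    b_n = float(np.sum(1.0 / i**2))
    b_n1 = b_n + 1.0 / n**2
    bb1 = (n + 1) / (3.0 * (n - 1))
    bb2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = bb1 - 1.0 / a_n
    c2 = bb2 - (n + 2) / (a_n * n) + b_n / a_n**2
    e1 = c1 / a_n
    e2 = c2 / (a_n**2 + b_n)
    return SfsConstants(n=n, a_n=a_n, b_n=b_n, b_n1=b_n1, e1=e1, e2=e2)


def site_contributions(d, n):
    """Per-site contributions (pi, L, H) for derived count ``d`` of ``n``.

    pi = 2 d (n-d) / (n (n-1)),  L = d/(n-1),  H = 2 d^2 / (n (n-1)).
    Monomorphic sites (d=0 or d=n) contribute zero to all three.
    """
    d = np.asarray(d, dtype=float)
    n = np.asarray(n, dtype=float)
    seg = (d > 0) & (d < n)
    denom = np.where(n > 1, n * (n - 1), np.nan)
    pi = np.where(seg, 2.0 * d * (n - d) / denom, 0.0)
    L = np.where(seg, d / np.where(n > 1, n - 1, np.nan), 0.0)
    H = np.where(seg, 2.0 * d * d / denom, 0.0)
    return pi, L, H


def watterson(S: float, const: SfsConstants) -> float:
    """Watterson's estimator theta_W = S / a_n (per window, not per bp)."""
    return S / const.a_n


def _median_n(n, seg) -> int:
    return int(np.median(np.asarray(n)[seg]))


def tajimas_d(m, n, const: SfsConstants | None = None) -> float:
    """Tajima's D from minor-allele counts ``m`` and called counts ``n``.

    Polarization-invariant: minor/major orientation gives the same value as
    derived/ancestral.  Returns NaN when there are no segregating sites.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    seg = (m > 0) & (m < n) & (n >= 2)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    if const is None:
        const = constants(_median_n(n, seg))
    pi, _, _ = site_contributions(m, n)
    pi_sum = float(pi[seg].sum())
    tw = S / const.a_n
    var = const.e1 * S + const.e2 * S * (S - 1)
    return (pi_sum - tw) / np.sqrt(var)


def _var_fay_wu_h(S: int, const: SfsConstants) -> float:
    n, a, b, b1 = const.n, const.a_n, const.b_n, const.b_n1
    th = S / a
    th2 = S * (S - 1) / (a**2 + b)
    t1 = th * (n - 2) / (6.0 * (n - 1))
    t2 = th2 * (
        18.0 * n**2 * (3.0 * n + 2.0) * b1 - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
    ) / (9.0 * n * (n - 1.0) ** 2)
    return t1 + t2


def _var_zeng_e(S: int, const: SfsConstants) -> float:
    n, a, b = const.n, const.a_n, const.b_n
    th = S / a
    th2 = S * (S - 1) / (a**2 + b)
    t1 = th * (n / (2.0 * (n - 1.0)) - 1.0 / a)
    t2 = th2 * (
        b / a**2
        + 2.0 * (n / (n - 1.0)) ** 2 * b
        - 2.0 * (n * b - n + 1.0) / ((n - 1.0) * a)
        - (3.0 * n + 1.0) / (n - 1.0)
    )
    return t1 + t2


def _polarized_seg(d, n):
    d = np.asarray(d, dtype=float)
    n = np.asarray(n, dtype=float)
    # d < 0 encodes "ancestral state unknown": excluded from polarized stats
    return d, n, (d > 0) & (d < n) & (n >= 2)


def fay_wu_h(d, n, const: SfsConstants | None = None) -> float:
    """Variance-normalized Fay & Wu's H = (theta_pi - theta_L)/sd.

    Uses polarized sites only (``d >= 0``); S in the variance counts
    polarized segregating sites.  NaN when no site is polarized-segregating.
    """
    d, n, seg = _polarized_seg(d, n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    if const is None:
        const = constants(_median_n(n, seg))
    pi, L, _ = site_contributions(d, n)
    num = float(pi[seg].sum() - L[seg].sum())
    var = _var_fay_wu_h(S, const)
    return num / np.sqrt(var)


def faywu_h_raw(d, n) -> float:
    """Unnormalized Fay & Wu's H = theta_pi - theta_H (= 2(theta_pi - theta_L))."""
    d, n, seg = _polarized_seg(d, n)
    if not seg.any():
        return float("nan")
    pi, _, H = site_contributions(d, n)
    return float(pi[seg].sum() - H[seg].sum())


def zengs_e(d, n, const: SfsConstants | None = None) -> float:
    """Zeng's E = (theta_L - theta_W)/sd on polarized sites."""
    d, n, seg = _polarized_seg(d, n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    if const is None:
        const = constants(_median_n(n, seg))
    _, L, _ = site_contributions(d, n)
    num = float(L[seg].sum()) - S / const.a_n
    var = _var_zeng_e(S, const)
    return num / np.sqrt(var)


def brute_force_pi(haplotypes) -> float:
    """Mean pairwise difference count over all C(n,2) haplotype pairs.

    Independent oracle for the formula-based theta_pi: enumerates pairs
    explicitly instead of using the per-site closed form.
    """
    h = np.asarray(haplotypes)
    nhap = h.shape[0]
    if nhap < 2:
        raise ValueError("need at least two haplotypes")
    total = 0
    for i, j in combinations(range(nhap), 2):
        total += int(np.sum(h[i] != h[j]))
    return total / (nhap * (nhap - 1) / 2)
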