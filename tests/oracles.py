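"""Independent brute-force oracles used to check the pipeline's statistics.

Everything here is computed from first principles (exact rational
combinatorics, explicit step-up recursion), deliberately sharing no code
path with the implementation under test.
"""

from fractions import Fraction
from math import comb

import numpy as np


def hypergeom_pmf_exact(x: int, N: int, K: int, n: int) -> Fraction:
    """P(X = x) for X ~ Hypergeom(N, K, n), exact rational."""
    return Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))


def fisher_two_tailed_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher p by exhaustive enumeration over fixed margins.

    Minimum-likelihood convention: sum the probabilities of every table with
    the same margins whose probability is at most that of the observed table
    (with the customary tiny relative guard for probability ties evaluated
    in floating point).
    """
    r1, c1, N = a + b, a + c, a + b + c + d
    if min(r1, c1, N - r1, N - c1) == 0:
        return 1.0
    p_obs = hypergeom_pmf_exact(a, N, c1, r1)
    lo = max(0, r1 + c1 - N)
    hi = min(r1, c1)
    total = Fraction(0)
    guard = Fraction(10**7 + 1, 10**7)
    for x in range(lo, hi + 1):
        p_x = hypergeom_pmf_exact(x, N, c1, r1)
        if p_x <= p_obs * guard:
            total += p_x
    return float(min(total, Fraction(1)))


def bh_step_up(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted values straight from the definition:
    adj_(i) = min_{j >= i} min(1, p_(j) * m / j), mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, min(1.0, p[order[rank - 1]] * m / rank))
        adj_sorted[rank - 1] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def hypergeom_upper_tail_enum(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct summation with exact rational arithmetic."""
    if k <= 0:
        return 1.0
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += hypergeom_pmf_exact(x, N, K, n)
    return float(min(total, Fraction(1)))


def welch_formulas(x, y) -> tuple[float, float]:
    """(t, df) from the Welch/Satterthwaite formulas written out directly."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / se2**0.5
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return float(t), float(df)
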