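"""Independent oracles the test suite checks the implementation against.

Deliberately naive: exhaustive enumeration and closed forms, written
without reference to the implementation they verify.
"""

from __future__ import annotations

import math

import numpy as np


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive enumeration of all 2x2
    tables with the observed margins, summing hypergeometric point
    probabilities no larger than the observed table's."""
    r1, r2 = a + b, c + d
    n1 = a + c
    total = r1 + r2
    if min(r1, r2, n1, b + d) == 0:
        return 1.0

    def point(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(r2, n1 - x) / math.comb(total, n1)
        )

    p_obs = point(a)
    acc = 0.0
    for x in range(max(0, n1 - r2), min(r1, n1) + 1):
        px = point(x)
        if px <= p_obs * (1.0 + 1e-9):  # float-safe comparison
            acc += px
    return min(acc, 1.0)


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up by direct application of the rule:
    q_(i) = min over j >= i of p_(j) * m / j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fst_nei(table) -> float:
    """Uncorrected Nei F_ST from a 2x2 (pool x allele) count table."""
    (a, b), (c, d) = table
    f1, f2 = a / (a + b), c / (c + d)
    hs = 0.5 * (2 * f1 * (1 - f1) + 2 * f2 * (1 - f2))
    fbar = 0.5 * (f1 + f2)
    ht = 2 * fbar * (1 - fbar)
    if ht == 0:
        return float("nan")
    return (ht - hs) / ht


def inflection_count_dense(spline, lo: float, hi: float) -> int:
    """Sign changes of the spline's second derivative sampled every 1 bp
    (brute force; zeros below numeric noise suppressed)."""
    grid = np.arange(lo, hi + 1.0, 1.0)
    vals = spline.derivative(2)(grid)
    tol = 1e-9 * max(np.max(np.abs(vals)), 1e-30)
    signs = np.where(np.abs(vals) <= tol, 0.0, np.sign(vals))
    nz = signs[signs != 0]
    return int(np.sum(nz[:-1] * nz[1:] < 0))
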