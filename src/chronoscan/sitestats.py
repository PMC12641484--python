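"""Per-site population-genetic statistics for a pool pair.

Allele frequencies, allele-frequency difference (AFD), the classical
pool-seq F_ST estimator with a finite-sample min(coverage, haploid pool
size) correction, two-sided Fisher's exact tests of allele-count
differences, Benjamini-Hochberg FDR adjustment, and the genome-wide
two-sample Z-contrast used to compare seasonal comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from chronoscan.syncio import BiallelicSite, FilterSettings, SyncRecord, filter_sites

#: Two-sided 97.5% standard-normal quantile used for the 95% CI.
Z_975 = 1.959964


@dataclass(frozen=True)
class SiteStat:
    """Per-site differentiation summary for one pool pair.

    ``f1``/``f2`` are the major-allele frequencies in each pool, ``afd``
    their absolute difference, ``fst`` the pool-seq fixation index (NaN
    when undefined), ``p_fisher`` the exact-test p-value and ``q_value``
    its BH-adjusted counterpart.
    """

    scaffold: str
    position: int
    f1: float
    f2: float
    afd: float
    fst: float
    p_fisher: float
    q_value: float


@dataclass(frozen=True)
class ContrastSummary:
    """Two-sample Z-test of means, with sds treated as known.

    Applicable for large samples (both n >= 30). ``z`` is signed like
    ``mean_a - mean_b``; the CI bounds the mean difference.
    """

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    z: float
    p_two_sided: float
    ci95_low: float
    ci95_high: float


def pool_allele_frequency(table, pool_index: int) -> float:
    """Major-allele frequency of one pool from a 2x2 (pool x allele) table."""
    major, minor = table[pool_index]
    coverage = major + minor
    if coverage == 0:
        raise ValueError("zero coverage: site should have been filtered")
    return major / coverage


def afd(f1: float, f2: float) -> float:
    """Allele frequency difference |f1 - f2| for the shared major allele."""
    return abs(f1 - f2)


def fst_site(
    table,
    z1: int = 18,
    z2: int = 18,
    corrected: bool = True,
) -> float:
    """Classical pool-seq F_ST for one biallelic site.

    With ``f_j`` the major-allele frequency of pool j, the within-pool gene
    diversity is ``h_j = 1 - f_j**2 - (1-f_j)**2``; the total diversity
    ``H_T`` uses the unweighted mean frequencies. F_ST = (H_T - H_S)/H_T
    with ``H_S = (h_1 + h_2)/2``.

    In corrected mode each ``h_j`` is multiplied by ``c_j/(c_j - 1)`` with
    ``c_j = min(coverage_j, Z_j)`` (the effective number of sampled
    chromosomes cannot exceed either the read depth or the haploid pool
    size), and the total term by ``c_T/(c_T - 1)``, ``c_T = min(c_1, c_2)``.
    When ``c_1 = c_2 = c_T`` the corrections cancel and the corrected value
    equals the plain Nei formula.

    Returns NaN when undefined (``H_T = 0``, or any ``c_j < 2`` in
    corrected mode).
    """
    (a, b), (c, d) = table
    cov1, cov2 = a + b, c + d
    if cov1 == 0 or cov2 == 0:
        return float("nan")
    f1, f2 = a / cov1, c / cov2
    h1 = 2.0 * f1 * (1.0 - f1)
    h2 = 2.0 * f2 * (1.0 - f2)
    fbar = 0.5 * (f1 + f2)
    ht = 2.0 * fbar * (1.0 - fbar)
    if corrected:
        c1, c2 = min(cov1, z1), min(cov2, z2)
        ct = min(c1, c2)
        if c1 < 2 or c2 < 2:
            return float("nan")
        h1 *= c1 / (c1 - 1.0)
        h2 *= c2 / (c2 - 1.0)
        ht *= ct / (ct - 1.0)
    hs = 0.5 * (h1 + h2)
    if ht == 0.0:
        return float("nan")
    return (ht - hs) / ht


# Exact-test p-values repeat heavily across sites at pool-seq depths, so
# memoize on the table. Unbounded cache: distinct tables with entries <= 57
# are few relative to genome scan sizes.
_FISHER_CACHE: dict[tuple[int, int, int, int], float] = {}


def fisher_site(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 allele-count table.

    Point-probability method: the sum of hypergeometric probabilities of
    all tables (at fixed margins) no more probable than the observed one.
    A zero margin gives p = 1 by convention (only one table is possible).
    """
    (a, b), (c, d) = (int(table[0][0]), int(table[0][1])), (
        int(table[1][0]),
        int(table[1][1]),
    )
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0
    key = (a, b, c, d)
    p = _FISHER_CACHE.get(key)
    if p is None:
        p = float(stats.fisher_exact([[a, b], [c, d]]).pvalue)
        p = min(p, 1.0)
        _FISHER_CACHE[key] = p
    return p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def contrast_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
) -> ContrastSummary:
    """Two-sample Z-test from summary statistics (sds treated as known).

    z = (mean_a - mean_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b); two-sided p from
    the standard normal; 95% CI = difference +/- 1.959964 * SE. Degenerate
    case of zero variance in both groups with equal means: z = 0, p = 1.
    """
    diff = mean_a - mean_b
    se = float(np.sqrt(sd_a**2 / n_a + sd_b**2 / n_b))
    if se == 0.0:
        if diff == 0.0:
            z = 0.0
        else:
            z = float(np.inf) if diff > 0 else float(-np.inf)
    else:
        z = diff / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return ContrastSummary(
        mean_a=float(mean_a),
        sd_a=float(sd_a),
        n_a=int(n_a),
        mean_b=float(mean_b),
        sd_b=float(sd_b),
        n_b=int(n_b),
        z=float(z),
        p_two_sided=p,
        ci95_low=diff - Z_975 * se,
        ci95_high=diff + Z_975 * se,
    )


def z_contrast(values_a: Sequence[float], values_b: Sequence[float]) -> ContrastSummary:
    """Z-contrast of two per-site statistic vectors (e.g. spring vs autumn
    F_ST). Sample standard deviations (n-1 denominator) are computed here
    so z and the CI are reproducible from raw pipeline output.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 30 or b.size < 30:
        raise ValueError(
            f"Z-test requires n >= 30 in both groups, got {a.size} and {b.size}"
        )
    return contrast_from_summary(
        float(a.mean()), float(a.std(ddof=1)), a.size,
        float(b.mean()), float(b.std(ddof=1)), b.size,
    )


def site_scan(
    records: Sequence[SyncRecord],
    settings: FilterSettings | None = None,
    pools: tuple[int, int] = (0, 1),
    haploid_sizes: tuple[int, int] = (18, 18),
    corrected: bool = True,
) -> pd.DataFrame:
    """Filter sites for one pool pair and compute all per-site statistics.

    Returns a DataFrame with columns scaffold, position, f1, f2, afd, fst,
    p_fisher, q_value (BH across all kept sites of this comparison), sorted
    by (scaffold, position).
    """
    kept, _ = filter_sites(records, settings, pools)
    rows = []
    z1, z2 = haploid_sizes
    for record, bi in kept:
        f1 = pool_allele_frequency(bi.table, 0)
        f2 = pool_allele_frequency(bi.table, 1)
        rows.append(
            (
                record.scaffold,
                record.position,
                f1,
                f2,
                afd(f1, f2),
                fst_site(bi.table, z1, z2, corrected),
                fisher_site(bi.table),
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["scaffold", "position", "f1", "f2", "afd", "fst", "p_fisher"],
    )
    if df.empty:
        df["q_value"] = pd.Series(dtype=float)
        return df
    df = df.sort_values(["scaffold", "position"], kind="mergesort").reset_index(
        drop=True
    )
    df["q_value"] = bh_adjust(df["p_fisher"].to_numpy())
    return df
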