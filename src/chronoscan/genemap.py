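"""Candidate genes near outlier windows and functional-term
overrepresentation.

A gene is a candidate when its interval lies within a flank distance
(default 25 kb) of any outlier window on the same scaffold; overlap counts
as distance zero and the candidate set is deduplicated across windows.
Overrepresentation of each functional term among candidates relative to
the gene universe is tested with a one-sided hypergeometric (Fisher
enrichment-direction) test, BH-adjusted across terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from chronoscan.sitestats import bh_adjust
from chronoscan.syncio import GeneFeature


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term overrepresentation counts and statistics.

    ``k`` of ``n`` candidate genes carry the term; ``K`` of ``N`` universe
    genes do. ``fold`` = (k/n)/(K/N); ``p`` is the one-sided
    hypergeometric tail P(X >= k); ``fdr`` is BH-adjusted across terms.
    """

    term_id: str
    k: int
    n: int
    K: int
    N: int
    fold: float
    p: float
    fdr: float


def candidate_genes(
    outlier_windows: pd.DataFrame,
    genes: Sequence[GeneFeature],
    flank: int = 25_000,
) -> pd.DataFrame:
    """Genes within ``flank`` bp of any outlier window.

    ``outlier_windows`` needs columns scaffold, start, end (1-based
    closed). A gene qualifies iff its interval intersects
    [window.start - flank, window.end + flank] on the same scaffold.
    Returns one row per (gene, nearest qualifying window) with the
    edge-to-edge distance (0 for overlap), deduplicated to each gene's
    nearest window; results do not depend on input ordering.
    """
    rows = []
    by_scaffold: dict[str, list[GeneFeature]] = {}
    for gene in genes:
        by_scaffold.setdefault(gene.scaffold, []).append(gene)
    windows = outlier_windows.sort_values(["scaffold", "start", "end"])
    for w_idx, win in windows.iterrows():
        for gene in by_scaffold.get(win["scaffold"], ()):
            # closed-interval gap; 0 when the intervals intersect
            distance = max(
                0, int(win["start"]) - gene.end, gene.start - int(win["end"])
            )
            if distance <= flank:
                rows.append(
                    (gene.gene_id, gene.scaffold, gene.start, gene.end, w_idx, distance)
                )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "scaffold", "start", "end", "window_id", "distance"],
    )
    if df.empty:
        return df
    df = df.sort_values(
        ["gene_id", "distance", "window_id"], kind="mergesort"
    ).drop_duplicates("gene_id", keep="first")
    return df.sort_values(["scaffold", "start"], kind="mergesort").reset_index(
        drop=True
    )


def overrepresentation(
    candidates: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, set[str]],
    fdr_cut: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Test every functional term for overrepresentation among candidates.

    The universe is the full supplied gene set (genes without any term
    count in N, mirroring a whole-proteome reference). Per term with at
    least one universe gene: fold = (k/n)/(K/N) and a one-sided
    hypergeometric p = P(X >= k) (or the two-sided Fisher p when
    ``alternative='two-sided'``, for parity experiments); BH across terms.

    Returns a DataFrame sorted by p with columns term_id, k, n, K, N,
    fold, p, fdr, retained — retained iff fdr < ``fdr_cut`` and fold > 1.
    """
    cand = set(candidates)
    univ = set(universe)
    stray = cand - univ
    if stray:
        raise ValueError(
            "candidate genes missing from universe: " + ", ".join(sorted(stray))
        )
    N, n = len(univ), len(cand)
    term_members: dict[str, set[str]] = {}
    for gene in univ:
        for term in term_map.get(gene, ()):
            term_members.setdefault(term, set()).add(gene)
    rows = []
    for term in sorted(term_members):
        members = term_members[term]
        K = len(members)
        k = len(members & cand)
        fold = (k / n) / (K / N) if n > 0 and K > 0 else 0.0
        if alternative == "greater":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        elif alternative == "two-sided":
            table = [[k, n - k], [K - k, (N - n) - (K - k)]]
            p = float(stats.fisher_exact(table).pvalue)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
        rows.append((term, k, n, K, N, fold, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "fold", "p"])
    if df.empty:
        df["fdr"] = pd.Series(dtype=float)
        df["retained"] = pd.Series(dtype=bool)
        return df
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    df["retained"] = (df["fdr"] < fdr_cut) & (df["fold"] > 1.0)
    return df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
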