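"""Analysis windows from inflection points of a smoothing spline.

Instead of fixed-width windows, a cubic smoothing spline is fitted to the
per-site F_ST series of each scaffold and windows are cut where the
spline's curvature changes sign (its inflection points). This lets window
sizes adapt to the local structure of the differentiation landscape, so a
contiguous elevated region is not split arbitrarily.

Window boundaries are placed at the midpoints between the two SNPs
flanking each inflection point, which makes SNP membership unambiguous
and the windows reproducible across evaluation-grid resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

#: Minimum SNPs per scaffold for a cubic GCV smoothing spline fit; below
#: this the scaffold becomes a single "unsplined" window.
MIN_SNPS_FOR_SPLINE = 5


@dataclass(frozen=True)
class Window:
    """A spline-defined genomic interval with summary statistics."""

    scaffold: str
    start: int  # 1-based closed
    end: int
    n_snps: int
    mean_fst: float
    n_significant: int
    outlier: bool
    unsplined: bool = False


def _inflection_points(
    spline, lo: float, hi: float, grid_step: float
) -> list[float]:
    """Sign changes of the spline's second derivative on [lo, hi], refined
    by bisection to < 1 bp."""
    d2 = spline.derivative(2)
    n = max(int(np.ceil((hi - lo) / grid_step)) + 1, 2)
    grid = np.linspace(lo, hi, n)
    vals = d2(grid)
    # suppress numerical noise around an exactly-flat fit
    tol = 1e-9 * max(np.max(np.abs(vals)), 1e-30)
    signs = np.where(np.abs(vals) <= tol, 0.0, np.sign(vals))
    points: list[float] = []
    nz = np.flatnonzero(signs != 0)
    for i, j in zip(nz[:-1], nz[1:]):
        if signs[i] * signs[j] < 0:
            a, b = grid[i], grid[j]
            fa = vals[i]
            while b - a > 1.0:
                m = 0.5 * (a + b)
                fm = d2(m)
                if fa * fm <= 0:
                    b = m
                else:
                    a, fa = m, fm
            points.append(0.5 * (a + b))
    return points


def spline_windows(
    positions,
    fst_values,
    smoothness: float | None = None,
    grid_step: float | None = None,
) -> tuple[list[tuple[int, int]], bool]:
    """Cut one scaffold's SNPs into windows at spline inflection points.

    Parameters
    ----------
    positions
        Strictly increasing 1-based SNP positions.
    fst_values
        Per-SNP F_ST (NaN allowed; such SNPs still belong to windows but a
        nominal 0 is used for fitting).
    smoothness
        Smoothing parameter ``lam`` of the penalized spline; ``None``
        selects it by generalized cross-validation.
    grid_step
        Spacing (bp) of the dense grid used to locate curvature sign
        changes; defaults to 1 bp for spans up to 200 kb, coarser above.

    Returns
    -------
    (windows, unsplined)
        ``windows`` is a list of 1-based closed (start, end) intervals
        tiling [first SNP, last SNP]; ``unsplined`` is True when the
        scaffold had too few SNPs for a spline fit and a single window was
        returned.
    """
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size == 0:
        raise ValueError("no SNPs on scaffold")
    if positions.size > 1 and not (np.diff(positions) > 0).all():
        raise ValueError("positions must be strictly increasing")
    fst = np.nan_to_num(np.asarray(fst_values, dtype=float), nan=0.0)
    if fst.size != positions.size:
        raise ValueError("positions and fst_values must have equal length")

    first, last = int(positions[0]), int(positions[-1])
    if positions.size < MIN_SNPS_FOR_SPLINE or first == last:
        return [(first, last)], True

    x = positions.astype(float)
    spline = make_smoothing_spline(x, fst, lam=smoothness)
    # an (effectively) constant fit has no curvature structure, only float
    # noise in its coefficients: one window, no inflection hunt
    fitted = spline(x)
    flat_tol = 1e3 * np.finfo(float).eps * max(1.0, float(np.max(np.abs(fitted))))
    if float(np.ptp(fitted)) <= flat_tol:
        return [(first, last)], False
    if grid_step is None:
        span = last - first
        grid_step = 1.0 if span <= 200_000 else span / 200_000.0
    inflections = _inflection_points(spline, float(first), float(last), grid_step)

    # boundary = midpoint of the SNP pair flanking each inflection point
    boundaries: list[int] = []
    for point in inflections:
        idx = int(np.searchsorted(positions, point))
        if 0 < idx < positions.size:
            mid = int((int(positions[idx - 1]) + int(positions[idx])) // 2)
            boundaries.append(mid)
    boundaries = sorted(set(b for b in boundaries if first <= b < last))

    windows: list[tuple[int, int]] = []
    start = first
    for b in boundaries:
        windows.append((start, b))
        start = b + 1
    windows.append((start, last))
    return windows, False


def assign_windows(
    sites: pd.DataFrame,
    smoothness: float | None = None,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.Series]:
    """Window every scaffold of a per-site statistics table.

    ``sites`` must have columns scaffold, position, fst, q_value (as
    produced by :func:`chronoscan.sitestats.site_scan`). Returns the
    window table (scaffold, start, end, n_snps, mean_fst, n_significant,
    unsplined) and a per-site Series of window row indices — every
    analyzed SNP belongs to exactly one window.

    ``mean_fst`` is the arithmetic mean over member SNPs with defined
    F_ST; members with undefined F_ST still count in ``n_snps``.
    ``n_significant`` counts members with q_value < ``alpha``.
    """
    win_rows = []
    membership = np.full(len(sites), -1, dtype=np.int64)
    for scaffold, group in sites.groupby("scaffold", sort=True):
        pos = group["position"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        idx = group.index.to_numpy()[order]
        pos = pos[order]
        fst = group["fst"].to_numpy()[order]
        qv = group["q_value"].to_numpy()[order]
        intervals, unsplined = spline_windows(pos, fst, smoothness)
        starts = np.array([w[0] for w in intervals])
        # windows tile [first, last]: member window by start position
        which = np.searchsorted(starts, pos, side="right") - 1
        for w, (start, end) in enumerate(intervals):
            member = which == w
            if not member.any():
                continue  # empty window: dropped
            member_fst = fst[member]
            defined = member_fst[~np.isnan(member_fst)]
            win_rows.append(
                (
                    scaffold,
                    int(start),
                    int(end),
                    int(member.sum()),
                    float(defined.mean()) if defined.size else float("nan"),
                    int((qv[member] < alpha).sum()),
                    unsplined,
                )
            )
            membership[idx[member]] = len(win_rows) - 1
    windows = pd.DataFrame(
        win_rows,
        columns=[
            "scaffold",
            "start",
            "end",
            "n_snps",
            "mean_fst",
            "n_significant",
            "unsplined",
        ],
    )
    return windows, pd.Series(membership, index=sites.index, name="window_id")


def call_outliers(
    windows: pd.DataFrame, min_significant: int = 2
) -> tuple[pd.DataFrame, dict]:
    """Flag outlier windows and summarize them.

    A window is an outlier iff it contains at least ``min_significant``
    SNPs significant after FDR correction (its ``n_significant`` column,
    counted at the scan's alpha). Returns the window table with an
    ``outlier`` column and a summary dict: outlier count, mean of outlier
    window mean F_ST, combined span in bp, genome-wide mean window F_ST,
    and the outlier-to-genome-wide ratio.
    """
    windows = windows.copy()
    windows["outlier"] = windows["n_significant"] >= min_significant
    out = windows[windows["outlier"]]
    mean_all = float(windows["mean_fst"].mean())
    mean_out = float(out["mean_fst"].mean()) if len(out) else float("nan")
    summary = {
        "n_windows": int(len(windows)),
        "n_outlier_windows": int(len(out)),
        "mean_window_fst": mean_all,
        "mean_outlier_fst": mean_out,
        "combined_outlier_bp": int((out["end"] - out["start"] + 1).sum()),
        "outlier_to_genome_ratio": (
            mean_out / mean_all if len(out) and mean_all > 0 else float("nan")
        ),
    }
    return windows, summary
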