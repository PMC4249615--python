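"""Adaptive-partitioning mutual information on rank-transformed data.

The estimator follows the Darbellay–Vajda adaptive partitioning scheme used by
relevance-network tools: both variables are rank-transformed (average ranks
for ties), and the rank square is partitioned recursively into quadrants.  A
cell containing ``n_c`` points is split at its rank-midpoints when
``n_c >= min_split`` and the quadrant counts reject uniformity by a chi-square
test with 3 degrees of freedom at level ``alpha_split``; otherwise it becomes
a leaf contributing

    (n_c/n) * ln[ (n_c/n) / ((w_x/n) * (w_y/n)) ]

where ``w_x`` and ``w_y`` are the numbers of marginal ranks falling inside the
cell's x- and y-intervals.  For untied data the marginal occupancy equals the
geometric interval width; under ties it equals the total multiplicity of the
tie blocks inside the cell, which makes the estimator agree with the plug-in
discrete MI when the partition isolates tie blocks.  The total is floored at
zero.  All MI values are in nats.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import stats as sps

__all__ = ["estimate_mi", "mi_from_ranks", "rank_rows", "chi2_critical"]

_MAX_DEPTH = 64


def chi2_critical(alpha_split: float = 0.05) -> float:
    """Chi-square(3 df) critical value for the quadrant-uniformity split test."""
    return float(sps.chi2.ppf(1.0 - alpha_split, df=3))


_CHI2_DEFAULT = 7.814727903251179  # chi2.ppf(0.95, 3)


@njit(cache=True)
def _ap_mi(rx, ry, sx, sy, min_split, chi_crit):  # pragma: no cover - compiled
    n = rx.shape[0]
    idx = np.empty(n, np.int64)
    for i in range(n):
        idx[i] = i
    buf = np.empty(n, np.int64)
    cap = 4 * _MAX_DEPTH + 8
    lo_s = np.empty(cap, np.int64)
    hi_s = np.empty(cap, np.int64)
    xlo_s = np.empty(cap, np.float64)
    xhi_s = np.empty(cap, np.float64)
    ylo_s = np.empty(cap, np.float64)
    yhi_s = np.empty(cap, np.float64)
    dp_s = np.empty(cap, np.int64)

    lo_s[0] = 0
    hi_s[0] = n
    xlo_s[0] = 0.5
    xhi_s[0] = n + 0.5
    ylo_s[0] = 0.5
    yhi_s[0] = n + 0.5
    dp_s[0] = 0
    top = 1
    mi = 0.0
    fn = float(n)

    while top > 0:
        top -= 1
        lo = lo_s[top]
        hi = hi_s[top]
        xlo = xlo_s[top]
        xhi = xhi_s[top]
        ylo = ylo_s[top]
        yhi = yhi_s[top]
        depth = dp_s[top]
        nc = hi - lo
        if nc == 0:
            continue
        xm = 0.5 * (xlo + xhi)
        ym = 0.5 * (ylo + yhi)
        do_split = False
        if nc >= min_split and depth < _MAX_DEPTH:
            c0 = 0
            c1 = 0
            c2 = 0
            c3 = 0
            i0 = idx[lo]
            xmin = rx[i0]
            xmax = xmin
            ymin = ry[i0]
            ymax = ymin
            for t in range(lo, hi):
                i = idx[t]
                vx = rx[i]
                vy = ry[i]
                if vx < xmin:
                    xmin = vx
                if vx > xmax:
                    xmax = vx
                if vy < ymin:
                    ymin = vy
                if vy > ymax:
                    ymax = vy
                if vx <= xm:
                    if vy <= ym:
                        c0 += 1
                    else:
                        c1 += 1
                else:
                    if vy <= ym:
                        c2 += 1
                    else:
                        c3 += 1
            e = nc / 4.0
            chi = ((c0 - e) ** 2 + (c1 - e) ** 2 + (c2 - e) ** 2 + (c3 - e) ** 2) / e
            if chi > chi_crit:
                if xmin == xmax and ymin == ymax:
                    # all points share one (x, y) coordinate (a tie block);
                    # further splits cannot separate them, but they do narrow
                    # the cell interval around the block so that the marginal
                    # occupancy converges to the block multiplicity — keep
                    # splitting only while that still makes progress
                    wx = np.searchsorted(sx, xhi, side="right") - np.searchsorted(
                        sx, xlo, side="right"
                    )
                    wy = np.searchsorted(sy, yhi, side="right") - np.searchsorted(
                        sy, ylo, side="right"
                    )
                    mx = np.searchsorted(sx, xmin, side="right") - np.searchsorted(
                        sx, xmin, side="left"
                    )
                    my = np.searchsorted(sy, ymin, side="right") - np.searchsorted(
                        sy, ymin, side="left"
                    )
                    do_split = wx > mx or wy > my
                else:
                    do_split = True
        if do_split:
            p = lo
            for t in range(lo, hi):
                i = idx[t]
                if rx[i] <= xm and ry[i] <= ym:
                    buf[p] = i
                    p += 1
            b0 = p
            for t in range(lo, hi):
                i = idx[t]
                if rx[i] <= xm and ry[i] > ym:
                    buf[p] = i
                    p += 1
            b1 = p
            for t in range(lo, hi):
                i = idx[t]
                if rx[i] > xm and ry[i] <= ym:
                    buf[p] = i
                    p += 1
            b2 = p
            for t in range(lo, hi):
                i = idx[t]
                if rx[i] > xm and ry[i] > ym:
                    buf[p] = i
                    p += 1
            for t in range(lo, hi):
                idx[t] = buf[t]
            d1 = depth + 1
            # child 0: x<=xm, y<=ym
            lo_s[top] = lo
            hi_s[top] = b0
            xlo_s[top] = xlo
            xhi_s[top] = xm
            ylo_s[top] = ylo
            yhi_s[top] = ym
            dp_s[top] = d1
            top += 1
            # child 1: x<=xm, y>ym
            lo_s[top] = b0
            hi_s[top] = b1
            xlo_s[top] = xlo
            xhi_s[top] = xm
            ylo_s[top] = ym
            yhi_s[top] = yhi
            dp_s[top] = d1
            top += 1
            # child 2: x>xm, y<=ym
            lo_s[top] = b1
            hi_s[top] = b2
            xlo_s[top] = xm
            xhi_s[top] = xhi
            ylo_s[top] = ylo
            yhi_s[top] = ym
            dp_s[top] = d1
            top += 1
            # child 3: x>xm, y>ym
            lo_s[top] = b2
            hi_s[top] = hi
            xlo_s[top] = xm
            xhi_s[top] = xhi
            ylo_s[top] = ym
            yhi_s[top] = yhi
            dp_s[top] = d1
            top += 1
        else:
            wx = np.searchsorted(sx, xhi, side="right") - np.searchsorted(
                sx, xlo, side="right"
            )
            wy = np.searchsorted(sy, yhi, side="right") - np.searchsorted(
                sy, ylo, side="right"
            )
            pc = nc / fn
            px = wx / fn
            py = wy / fn
            mi += pc * np.log(pc / (px * py))
    if mi < 0.0:
        mi = 0.0
    return mi


@njit(cache=True)
def _ap_mi_one_vs_rows(rx, sx, R, S, rows, min_split, chi_crit, out):  # pragma: no cover
    for k in range(rows.shape[0]):
        j = rows[k]
        out[k] = _ap_mi(rx, R[j], sx, S[j], min_split, chi_crit)


def rank_rows(values: np.ndarray) -> np.ndarray:
    """Average ranks per row (ties share their mean rank)."""
    return sps.rankdata(np.asarray(values, dtype=float), axis=-1).astype(np.float64)


def mi_from_ranks(rx, ry, min_split: int = 8, chi_crit: float = _CHI2_DEFAULT) -> float:
    """MI (nats) from pre-computed rank vectors."""
    rx = np.ascontiguousarray(rx, dtype=np.float64)
    ry = np.ascontiguousarray(ry, dtype=np.float64)
    return float(_ap_mi(rx, ry, np.sort(rx), np.sort(ry), min_split, chi_crit))


def estimate_mi(x, y, min_split: int = 8, alpha_split: float = 0.05) -> float:
    """Adaptive-partitioning MI estimate between two samples, in nats.

    Parameters
    ----------
    x, y : 1-D sequences of equal length ``n >= 8``.
    min_split : int
        Minimum number of points in a cell for the split test (default 8).
    alpha_split : float
        Significance level of the chi-square(3 df) quadrant-uniformity test
        that decides whether a cell is partitioned further (default 0.05).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 8:
        raise ValueError("need at least 8 observations to estimate MI")
    crit = _CHI2_DEFAULT if alpha_split == 0.05 else chi2_critical(alpha_split)
    return mi_from_ranks(sps.rankdata(x), sps.rankdata(y), min_split, crit)


def mi_one_vs_many(
    rx: np.ndarray,
    ranks: np.ndarray,
    rows: np.ndarray,
    sorted_ranks: np.ndarray | None = None,
    min_split: int = 8,
    chi_crit: float = _CHI2_DEFAULT,
) -> np.ndarray:
    """MI of one rank vector against selected rows of a rank matrix.

    Batched driver used by the network builder; ``sorted_ranks`` caches
    ``np.sort(ranks, axis=1)`` across calls.
    """
    rx = np.ascontiguousarray(rx, dtype=np.float64)
    ranks = np.ascontiguousarray(ranks, dtype=np.float64)
    if sorted_ranks is None:
        sorted_ranks = np.sort(ranks, axis=1)
    rows = np.asarray(rows, dtype=np.int64)
    out = np.empty(rows.size, dtype=np.float64)
    _ap_mi_one_vs_rows(rx, np.sort(rx), ranks, sorted_ranks, rows, min_split, chi_crit, out)
    return out
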