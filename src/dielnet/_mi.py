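"""Numba kernels for adaptive-partitioning mutual information.

Values are rank-transformed to (0, 1) and the unit square is partitioned
recursively into quadrants at the cell midpoint. The root cell is always
split (whether a pair is dependent at all is decided downstream by the
null-calibrated MI threshold, not by the estimator); a deeper cell is split
while it holds at least 8 points (so each subcell would hold >= 2 in
expectation) and the chi-square statistic of its four prospective subcell
counts exceeds 7.815 (df=3, alpha=0.05). Each leaf cell contributes
(n_c/n) * ln((n_c/n) / (width * height)); the total is floored at 0. The
estimate is invariant under strictly monotone transforms of either argument
because only ranks enter.
"""

from __future__ import annotations

import numpy as np
from numba import njit

CHI2_SPLIT = 7.815  # chi-square df=3, alpha=0.05
MIN_CELL_POINTS = 8
_MAX_DEPTH = 64


@njit(cache=True)
def mi_from_ranks(xr, yr):
    """MI (nats) between two rank vectors scaled to (0, 1).

    Iterative quadrant partitioning with an explicit stack; points of the
    current cell are kept contiguous in a work buffer and partitioned in
    place, quicksort-style.
    """
    n = xr.size
    work = np.arange(n)
    buf = np.empty(n, np.int64)
    # stack frames: lo, hi (segment of work), x0, x1, y0, y1, depth
    cap = 4 * _MAX_DEPTH + 4
    st_lo = np.empty(cap, np.int64)
    st_hi = np.empty(cap, np.int64)
    st_x0 = np.empty(cap)
    st_x1 = np.empty(cap)
    st_y0 = np.empty(cap)
    st_y1 = np.empty(cap)
    st_d = np.empty(cap, np.int64)
    top = 0
    st_lo[0] = 0
    st_hi[0] = n
    st_x0[0] = 0.0
    st_x1[0] = 1.0
    st_y0[0] = 0.0
    st_y1[0] = 1.0
    st_d[0] = 0
    total = 0.0
    nf = float(n)
    while top >= 0:
        lo = st_lo[top]
        hi = st_hi[top]
        x0 = st_x0[top]
        x1 = st_x1[top]
        y0 = st_y0[top]
        y1 = st_y1[top]
        depth = st_d[top]
        top -= 1
        m = hi - lo
        if m == 0:
            continue
        xm = 0.5 * (x0 + x1)
        ym = 0.5 * (y0 + y1)
        split = False
        c0 = c1 = c2 = c3 = 0
        if m >= MIN_CELL_POINTS and depth < _MAX_DEPTH:
            for t in range(lo, hi):
                i = work[t]
                if yr[i] >= ym:
                    if xr[i] >= xm:
                        c3 += 1
                    else:
                        c2 += 1
                else:
                    if xr[i] >= xm:
                        c1 += 1
                    else:
                        c0 += 1
            e = m / 4.0
            chi2 = ((c0 - e) ** 2 + (c1 - e) ** 2
                    + (c2 - e) ** 2 + (c3 - e) ** 2) / e
            split = depth == 0 or chi2 > CHI2_SPLIT
        if not split:
            p = m / nf
            total += p * np.log(p / ((x1 - x0) * (y1 - y0)))
            continue
        # partition the segment into the 4 quadrants, stable
        o0 = lo
        o1 = o0 + c0
        o2 = o1 + c1
        o3 = o2 + c2
        p0, p1, p2, p3 = o0, o1, o2, o3
        for t in range(lo, hi):
            i = work[t]
            if yr[i] >= ym:
                if xr[i] >= xm:
                    buf[p3] = i
                    p3 += 1
                else:
                    buf[p2] = i
                    p2 += 1
            else:
                if xr[i] >= xm:
                    buf[p1] = i
                    p1 += 1
                else:
                    buf[p0] = i
                    p0 += 1
        for t in range(lo, hi):
            work[t] = buf[t]
        d1 = depth + 1
        # push the 4 subcells
        top += 1
        st_lo[top] = o0
        st_hi[top] = o1
        st_x0[top] = x0
        st_x1[top] = xm
        st_y0[top] = y0
        st_y1[top] = ym
        st_d[top] = d1
        top += 1
        st_lo[top] = o1
        st_hi[top] = o2
        st_x0[top] = xm
        st_x1[top] = x1
        st_y0[top] = y0
        st_y1[top] = ym
        st_d[top] = d1
        top += 1
        st_lo[top] = o2
        st_hi[top] = o3
        st_x0[top] = x0
        st_x1[top] = xm
        st_y0[top] = ym
        st_y1[top] = y1
        st_d[top] = d1
        top += 1
        st_lo[top] = o3
        st_hi[top] = hi
        st_x0[top] = xm
        st_x1[top] = x1
        st_y0[top] = ym
        st_y1[top] = y1
        st_d[top] = d1
    return total if total > 0.0 else 0.0


@njit(cache=True)
def pairwise_mi(R):
    """Symmetric MI matrix over the rows of a rank matrix (zero diagonal)."""
    n = R.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = mi_from_ranks(R[i], R[j])
            out[i, j] = v
            out[j, i] = v
    return out


@njit(cache=True)
def null_mi(R, pair_i, pair_j, seed):
    """Null MI draws: for each listed pair, permute one profile and score."""
    np.random.seed(seed)
    k = pair_i.size
    out = np.empty(k)
    for t in range(k):
        perm = np.random.permutation(R.shape[1])
        out[t] = mi_from_ranks(R[pair_i[t]], R[pair_j[t]][perm])
    return out


@njit(cache=True)
def dpi_flags(W, tolerance):
    """Data-processing-inequality removal flags on a dense weight matrix.

    An edge (i, j) is flagged iff some third node k closes a triangle in which
    (i, j) carries strictly the smallest weight:
    w_ij < (1 - tolerance) * min(w_ik, w_jk). Flags are computed on the input
    matrix only, so application is order-independent.
    """
    n = W.shape[0]
    removed = np.zeros((n, n), np.bool_)
    scale = 1.0 - tolerance
    for k in range(n):
        nbrs = np.where(W[k] > 0.0)[0]
        for a in range(nbrs.size):
            i = nbrs[a]
            wik = W[k, i]
            for b in range(a + 1, nbrs.size):
                j = nbrs[b]
                wij = W[i, j]
                if wij <= 0.0:
                    continue
                wjk = W[k, j]
                m = wik if wik < wjk else wjk
                if wij < scale * m:
                    removed[i, j] = True
                    removed[j, i] = True
    return removed


def rank01(x: np.ndarray) -> np.ndarray:
    """Stable ordinal ranks scaled to (0, 1): rank r -> (r + 0.5) / n."""
    x = np.asarray(x)
    n = x.shape[-1]
    order = np.argsort(x, axis=-1, kind="stable")
    r = np.empty_like(x, dtype=np.float64)
    np.put_along_axis(r, order, (np.arange(n, dtype=np.float64) + 0.5) / n, axis=-1)
    return r
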