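"""Vietoris-Rips H1 persistence kernel (numba).

Computes the H1 persistence pairs of the Rips filtration of a point
cloud given its distance matrix.  The reduction runs on the
anti-transposed (coboundary) matrix -- columns are edges in reverse
filtration order, pivots are triangles -- which pairs almost every
column immediately and is far faster than reducing triangle columns;
by the anti-transpose symmetry of persistence pairing it yields
exactly the same diagram as the standard boundary reduction for the
same simplexwise refinement (value-sorted, stable ties).

Two prunings keep the problem small without changing any
positive-persistence pair:

* the filtration is capped at the enclosing radius
  R = min_i max_j D[i, j]; at threshold R the complex is a cone and
  therefore simply connected, so every H1 death is <= R and no
  simplex with diameter > R can participate in a positive pair;
* only the 2-skeleton is built (H1 needs edges and triangles).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ZERO = np.uint64(0)
_ONE = np.uint64(1)


@njit(cache=True, inline="always")
def _top_bit(x):  # pragma: no cover - numba helper
    b = 0
    if x >> np.uint64(32):
        b += 32
        x >>= np.uint64(32)
    if x >> np.uint64(16):
        b += 16
        x >>= np.uint64(16)
    if x >> np.uint64(8):
        b += 8
        x >>= np.uint64(8)
    if x >> np.uint64(4):
        b += 4
        x >>= np.uint64(4)
    if x >> np.uint64(2):
        b += 2
        x >>= np.uint64(2)
    if x >> np.uint64(1):
        b += 1
    return b


@njit(cache=True)
def h1_pairs_from_distances(D):  # pragma: no cover - exercised via wrapper
    n = D.shape[0]
    empty = np.empty((0, 2), np.float64)
    if n < 3:
        return empty

    # enclosing radius
    R = np.inf
    for i in range(n):
        mx = 0.0
        for j in range(n):
            if j != i and D[i, j] > mx:
                mx = D[i, j]
        if mx < R:
            R = mx

    # edges with diameter <= R, sorted by length (stable)
    m_all = n * (n - 1) // 2
    ei = np.empty(m_all, np.int64)
    ej = np.empty(m_all, np.int64)
    ed = np.empty(m_all, np.float64)
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = D[i, j]
            if d <= R:
                ei[m] = i
                ej[m] = j
                ed[m] = d
                m += 1
    if m < 3:
        return empty
    order = np.argsort(ed[:m], kind="mergesort")
    rank = np.full((n, n), -1, np.int64)
    edge_val = np.empty(m, np.float64)
    for r in range(m):
        e = order[r]
        rank[ei[e], ej[e]] = r
        rank[ej[e], ei[e]] = r
        edge_val[r] = ed[e]

    # triangles with diameter <= R, in enumeration order
    nt_max = n * (n - 1) * (n - 2) // 6
    tv = np.empty(nt_max, np.float64)
    te = np.empty((nt_max, 3), np.int64)
    nt = 0
    for i in range(n):
        for j in range(i + 1, n):
            dij = D[i, j]
            if dij > R:
                continue
            for k in range(j + 1, n):
                dik = D[i, k]
                djk = D[j, k]
                if dik > R or djk > R:
                    continue
                v = dij
                if dik > v:
                    v = dik
                if djk > v:
                    v = djk
                tv[nt] = v
                te[nt, 0] = rank[i, j]
                te[nt, 1] = rank[i, k]
                te[nt, 2] = rank[j, k]
                nt += 1
    if nt == 0:
        return empty
    torder = np.argsort(tv[:nt], kind="mergesort")
    trank = np.empty(nt, np.int64)  # enumeration idx -> filtration rank
    tv_sorted = np.empty(nt, np.float64)
    for tt in range(nt):
        trank[torder[tt]] = tt
        tv_sorted[tt] = tv[torder[tt]]

    # cofacet lists (CSR): edge rank -> reverse triangle ranks
    deg = np.zeros(m + 1, np.int64)
    for t in range(nt):
        deg[te[t, 0] + 1] += 1
        deg[te[t, 1] + 1] += 1
        deg[te[t, 2] + 1] += 1
    off = np.cumsum(deg)
    fill = off[:m].copy()
    cof = np.empty(3 * nt, np.int64)
    for t in range(nt):
        rr = nt - 1 - trank[t]  # reverse rank: smallest triangle = top bit
        for c in range(3):
            e = te[t, c]
            cof[fill[e]] = rr
            fill[e] += 1

    # coboundary column reduction, edges in reverse filtration order
    words = (nt + 63) // 64
    cap = 64
    stored = np.empty((cap, words), np.uint64)
    stored_low = np.full(nt, -1, np.int64)  # pivot reverse-rank -> slot
    births = np.empty(m, np.float64)
    deaths = np.empty(m, np.float64)
    n_pairs = 0
    n_stored = 0
    col = np.zeros(words, np.uint64)

    for e in range(m - 1, -1, -1):
        lo = off[e]
        hi = off[e + 1]
        if lo == hi:
            continue
        low = -1
        for c in range(lo, hi):
            if cof[c] > low:
                low = cof[c]
        top_w = low >> 6
        for w in range(top_w + 1):
            col[w] = _ZERO
        for c in range(lo, hi):
            rr = cof[c]
            col[rr >> 6] ^= _ONE << np.uint64(rr & 63)
        while True:
            s = stored_low[low]
            if s < 0:
                if n_stored == cap:
                    new = np.empty((cap * 2, words), np.uint64)
                    new[:cap] = stored
                    stored = new
                    cap *= 2
                for w in range(top_w + 1):
                    stored[n_stored, w] = col[w]
                stored_low[low] = n_stored
                n_stored += 1
                births[n_pairs] = edge_val[e]
                deaths[n_pairs] = tv_sorted[nt - 1 - low]
                n_pairs += 1
                break
            for w in range(top_w + 1):
                col[w] ^= stored[s, w]
            low = -1
            for w in range(top_w, -1, -1):
                if col[w] != _ZERO:
                    low = (w << 6) + _top_bit(col[w])
                    break
            if low < 0:
                break  # column zeroed: edge creates no H1 class
            top_w = low >> 6

    out = np.empty((n_pairs, 2), np.float64)
    for p in range(n_pairs):
        out[p, 0] = births[p]
        out[p, 1] = deaths[p]
    return out
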