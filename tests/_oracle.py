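"""Independent brute-force oracles used by the test suite.

The persistence oracle enumerates every simplex of dimension <= 2,
sorts the whole filtration, and runs the textbook left-to-right
boundary-matrix reduction over Z/2 with python sets.  It shares no
code (and no algorithmic shortcuts) with the production kernel.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform


def rips_h1_pairs_oracle(points: np.ndarray) -> list[tuple[float, float]]:
    """All H1 (birth, death) pairs on the radius scale, brute force."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 3:
        return []
    D = squareform(pdist(points))

    simplices: list[tuple[float, int, tuple[int, ...]]] = []
    for i in range(n):
        simplices.append((0.0, 0, (i,)))
    for i in range(n):
        for j in range(i + 1, n):
            simplices.append((float(D[i, j]), 1, (i, j)))
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                val = max(D[i, j], D[i, k], D[j, k])
                simplices.append((float(val), 2, (i, j, k)))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index = {verts: idx for idx, (_, _, verts) in enumerate(simplices)}

    def boundary(verts: tuple[int, ...]) -> set[int]:
        if len(verts) == 1:
            return set()
        return {
            index[verts[:i] + verts[i + 1:]]
            for i in range(len(verts))
        }

    low_to_col: dict[int, set[int]] = {}
    pairs: list[tuple[float, float]] = []
    for j, (val_j, dim_j, verts_j) in enumerate(simplices):
        col = boundary(verts_j)
        while col:
            low = max(col)
            if low not in low_to_col:
                break
            col ^= low_to_col[low]
        if col:
            low = max(col)
            low_to_col[low] = col
            val_i, dim_i, _ = simplices[low]
            if dim_j == 2 and dim_i == 1:
                pairs.append((val_i / 2.0, val_j / 2.0))
    return pairs


def positive_pairs(pairs) -> list[tuple[float, float]]:
    """Sorted positive-persistence pairs (death > birth)."""
    out = [(float(b), float(d)) for b, d in pairs if d > b]
    return sorted(out)


def auc_u_statistic(scores, labels) -> float:
    """AUC via the Mann-Whitney U statistic with half-credit ties."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    ranks = rankdata(scores)
    n1 = labels.sum()
    n0 = (~labels).sum()
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def bh_oracle(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up by direct application of the rule."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        idx = order[pos]
        val = min(1.0, p[idx] * m / (pos + 1))
        running_min = min(running_min, val)
        adj[idx] = running_min
    return adj
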