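"""State-space reconstruction: time-delay embedding + Laplacian Eigenmaps.

Each gene's series is embedded in 3-D with coordinates
(x_t, x_{t-tau}, x_{t-2 tau}) over a sweep of lags tau, and each 3-D
cloud is reduced to 2-D with a spectral embedding of a k-nearest-
neighbour heat-kernel graph.  Non-periodic drift elongates the 3-D
cloud into a helix; the 2-D reduction preserves the circular
component, which the topology stage then scores.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from typing import Optional, Sequence, Union

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from timecycle.types import PointCloud, Series

logger = logging.getLogger(__name__)

DEFAULT_LAGS = (2, 3, 4, 5)
DEFAULT_K_NEIGHBORS = 6

_DEGENERATE_TOL = 1e-12


def min_length_for(dim: int, lag_samples: int) -> int:
    """Shortest series usable for a (dim, lag) embedding (>= 3 points)."""
    return (dim - 1) * lag_samples + 3


def delay_embed(s: Series, dim: int = 3, lag_samples: int = 2) -> PointCloud:
    """Time-delay embedding with ``dim`` coordinates and lag in samples.

    Point i (for i from (dim-1)*lag to N-1) has coordinates
    (x_i, x_{i-lag}, ..., x_{i-(dim-1)*lag}); the cloud has exactly
    N - (dim-1)*lag points.
    """
    if s.mask.any():
        raise ValueError("delay_embed requires a fully observed series")
    if dim < 2:
        raise ValueError("embedding dimension must be >= 2")
    if lag_samples < 1:
        raise ValueError("lag must be a positive number of samples")
    n = len(s)
    need = min_length_for(dim, lag_samples)
    if n < need:
        raise ValueError(
            f"series of length {n} too short for dim={dim}, lag={lag_samples}; "
            f"need at least {need} points"
        )
    x = s.values
    offset = (dim - 1) * lag_samples
    cols = [x[offset - j * lag_samples: n - j * lag_samples]
            for j in range(dim)]
    return PointCloud(np.column_stack(cols), source_lag=lag_samples)


def _largest_component(adj: np.ndarray) -> np.ndarray:
    """Indices of the largest connected component (first on ties)."""
    n = adj.shape[0]
    comp = np.full(n, -1, dtype=int)
    c = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = c
        while stack:
            u = stack.pop()
            for v in np.nonzero(adj[u])[0]:
                if comp[v] < 0:
                    comp[v] = c
                    stack.append(v)
        c += 1
    sizes = np.bincount(comp, minlength=c)
    return np.nonzero(comp == int(np.argmax(sizes)))[0]


def _spectral_coords(W: np.ndarray) -> np.ndarray:
    """2-D coordinates from the symmetric normalized graph Laplacian.

    Columns are the eigenvectors of the 2nd- and 3rd-smallest
    eigenvalues.
    """
    deg = W.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, _DEGENERATE_TOL))
    L = np.eye(W.shape[0]) - (inv_sqrt[:, None] * W) * inv_sqrt[None, :]
    L = 0.5 * (L + L.T)
    _, vecs = eigh(L, subset_by_index=[1, 2])
    return vecs


def laplacian_eigenmap(
    pc: PointCloud,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    heat_scale: Union[float, str] = "auto",
) -> Optional[PointCloud]:
    """Project a 3-D cloud to 2-D preserving local (circular) geometry.

    Builds a symmetric k-nearest-neighbour graph (edge if either
    endpoint selects the other) with heat-kernel weights
    exp(-dist^2 / scale^2); ``heat_scale="auto"`` uses the median
    pairwise distance.  If the graph is disconnected, the largest
    component is embedded and excluded points map to its centroid.

    Returns None (degenerate sentinel) when all points coincide or too
    few points remain; downstream scoring treats that as persistence 0.
    """
    P = pc.points
    n = P.shape[0]
    if n < 3:
        return None
    dists = pdist(P)
    if dists.size == 0 or dists.max() < _DEGENERATE_TOL:
        return None
    D = squareform(dists)
    if heat_scale == "auto":
        scale = float(np.median(dists))
    else:
        scale = float(heat_scale)
    if scale < _DEGENERATE_TOL:
        return None

    k = min(int(k_neighbors), n - 1)
    if k < 1:
        return None
    # directed kNN, then symmetrize by union
    order = np.argsort(D, axis=1, kind="stable")
    adj = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    adj[rows, order[:, 1:k + 1].ravel()] = True
    adj |= adj.T

    W = np.where(adj, np.exp(-(D / scale) ** 2), 0.0)

    comp = _largest_component(adj)
    if len(comp) < 3:
        return None
    coords = np.empty((n, 2))
    sub = _spectral_coords(W[np.ix_(comp, comp)])
    coords[comp] = sub
    if len(comp) < n:
        # frequent on noisy clouds; debug level to keep bulk runs quiet
        logger.debug(
            "kNN graph disconnected: embedding largest component "
            "(%d of %d points); others mapped to its centroid",
            len(comp), n,
        )
        rest = np.setdiff1d(np.arange(n), comp)
        coords[rest] = sub.mean(axis=0)
    return PointCloud(coords, source_lag=pc.source_lag)


@lru_cache(maxsize=256)
def _warn_skipped_once(skipped: tuple[int, ...], n: int) -> None:
    logger.warning("skipping infeasible lags %s for series of length %d",
                   list(skipped), n)


def feasible_lags(n: int, lag_set: Sequence[int], dim: int = 3) -> list[int]:
    """Lags from ``lag_set`` usable for a length-``n`` series."""
    return [int(t) for t in lag_set if n >= min_length_for(dim, int(t))]


def embed_over_lags(
    s: Series,
    lag_set: Sequence[int] = DEFAULT_LAGS,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    heat_scale: Union[float, str] = "auto",
) -> list[tuple[int, Optional[PointCloud]]]:
    """One 2-D cloud per feasible lag: delay_embed(dim=3) then NLDR.

    Infeasible lags are skipped with a warning; a cloud entry is None
    when the lag's embedding is degenerate.  Raises if no lag is
    feasible.
    """
    n = len(s)
    lags = feasible_lags(n, lag_set)
    skipped = [t for t in lag_set if int(t) not in lags]
    if skipped:
        _warn_skipped_once(tuple(skipped), n)
    if not lags:
        raise ValueError(
            f"no feasible lag in {tuple(lag_set)} for series of length {n}"
        )
    out: list[tuple[int, Optional[PointCloud]]] = []
    for tau in lags:
        pc3 = delay_embed(s, dim=3, lag_samples=tau)
        out.append((tau, laplacian_eigenmap(pc3, k_neighbors, heat_scale)))
    return out
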