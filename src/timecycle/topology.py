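"""Circularity scoring of 2-D clouds via Rips H1 persistent homology.

Birth/death values are reported on the radius scale (distance
threshold / 2), matching the convention that two points are connected
when their eps-balls intersect, i.e. at distance 2*eps.  The per-gene
score is the mean over the lag sweep of each cloud's maximum H1
persistence.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import pdist, squareform

from timecycle._rips import h1_pairs_from_distances
from timecycle.state_space import (
    DEFAULT_K_NEIGHBORS,
    DEFAULT_LAGS,
    embed_over_lags,
)
from timecycle.types import PersistenceScore, PointCloud, Series

__all__ = [
    "rips_h1_pairs",
    "rips_h1_max_persistence",
    "persistence_score",
    "NLDRSettings",
]


class NLDRSettings:
    """Settings for the Laplacian-Eigenmap reduction inside the sweep."""

    __slots__ = ("k_neighbors", "heat_scale")

    def __init__(self, k_neighbors: int = DEFAULT_K_NEIGHBORS,
                 heat_scale: Union[float, str] = "auto") -> None:
        self.k_neighbors = int(k_neighbors)
        self.heat_scale = heat_scale


def _as_points(pc: Union[PointCloud, np.ndarray]) -> np.ndarray:
    if isinstance(pc, PointCloud):
        return pc.points
    return np.asarray(pc, dtype=float)


def rips_h1_pairs(pc: Union[PointCloud, np.ndarray]) -> np.ndarray:
    """H1 (birth, death) pairs on the radius scale, shape (k, 2).

    Z/2 coefficients; filtration capped at the enclosing radius (which
    preserves every positive-persistence pair).
    """
    pts = _as_points(pc)
    if pts.shape[0] < 3:
        return np.empty((0, 2))
    D = squareform(pdist(pts))
    return h1_pairs_from_distances(D) / 2.0


def rips_h1_max_persistence(pc: Union[PointCloud, np.ndarray, None]) -> float:
    """Maximum H1 persistence (death - birth, radius scale); 0 if none."""
    if pc is None:
        return 0.0
    pairs = rips_h1_pairs(pc)
    if pairs.shape[0] == 0:
        return 0.0
    return float(np.max(pairs[:, 1] - pairs[:, 0]))


def persistence_score(
    s: Series,
    lag_set: Sequence[int] = DEFAULT_LAGS,
    nldr: Optional[NLDRSettings] = None,
) -> PersistenceScore:
    """Mean over feasible lags of per-cloud max H1 persistence.

    The input must be preprocessed (fully observed, standardized).
    Degenerate (constant) series score 0 at every lag.
    """
    nldr = nldr or NLDRSettings()
    if s.mask.any():
        raise ValueError("persistence_score requires a fully observed series")
    clouds = embed_over_lags(s, lag_set, nldr.k_neighbors, nldr.heat_scale)
    lags = tuple(t for t, _ in clouds)
    per_lag = np.array([rips_h1_max_persistence(pc) for _, pc in clouds])
    return PersistenceScore(score=float(per_lag.mean()), lags=lags,
                            per_lag_scores=per_lag)
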