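"""Shared permutation null and p-/q-value computation.

The null model permutes the finite differences of an observed series:
the resampled series has the same first value and the same multiset of
step-to-step changes, so it respects the transcription/degradation
rate constraints present in the data while destroying any cyclic
ordering.  Because every gene is standardized before scoring, one set
of permuted series drawn from the (standardized) dataset serves as the
null for all genes.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
from statsmodels.stats.multitest import multipletests

from timecycle.topology import NLDRSettings, persistence_score
from timecycle.types import (
    ExpressionSet,
    NullDistribution,
    Series,
    ZeroVarianceError,
)

__all__ = [
    "permute_differences",
    "build_shared_null",
    "empirical_p",
    "bh_fdr",
]


def permute_differences(s: Series, rng: np.random.Generator) -> Series:
    """Random series with the same first value and difference multiset.

    value_0 is preserved and value_i = value_0 + cumsum of a uniformly
    random permutation of the input's first differences; consequently
    the final value is preserved too.
    """
    if s.mask.any():
        raise ValueError("permute_differences requires a fully observed series")
    if len(s) < 3:
        raise ValueError("need at least 3 points")
    diffs = np.diff(s.values)
    permuted = rng.permutation(diffs)
    values = np.concatenate(([s.values[0]],
                             s.values[0] + np.cumsum(permuted)))
    return Series(s.times.copy(), values)


def _restandardize(values: np.ndarray) -> Optional[np.ndarray]:
    sd = float(np.std(values, ddof=1))
    if not np.isfinite(sd) or sd <= 0.0:
        return None
    return (values - values.mean()) / sd


def build_shared_null(
    es_standardized: ExpressionSet,
    n_resamples: int,
    lag_set: Sequence[int],
    nldr: Optional[NLDRSettings] = None,
    rng: Union[np.random.Generator, int, None] = None,
) -> NullDistribution:
    """Null persistence scores from permuted-difference resamples.

    Each resample draws a source gene uniformly with replacement from
    the standardized set, permutes its finite differences,
    re-standardizes, and scores it with the same lag sweep used for
    observed genes.  The candidate pool is sorted canonically
    (lexicographically by value vector) so the null does not depend on
    gene row order.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be positive")
    seed = -1
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = 0 if rng is None else int(rng)
        rng = np.random.default_rng(seed)
    nldr = nldr or NLDRSettings()

    vals = es_standardized.values
    sds = np.std(vals, axis=1, ddof=1)
    ok = np.isfinite(vals).all(axis=1) & (sds > 0)
    pool = vals[ok]
    if pool.shape[0] == 0:
        raise ValueError("no non-degenerate genes to build the null from")
    # canonical row order: null must not depend on gene ordering
    pool = pool[np.lexsort(pool.T[::-1])]

    times = es_standardized.sample_times
    scores = np.empty(n_resamples)
    for r in range(n_resamples):
        src = pool[rng.integers(pool.shape[0])]
        diffs = rng.permutation(np.diff(src))
        values = np.concatenate(([src[0]], src[0] + np.cumsum(diffs)))
        std = _restandardize(values)
        if std is None:
            scores[r] = 0.0
            continue
        scores[r] = persistence_score(Series(times, std), lag_set, nldr).score
    return NullDistribution(scores=scores, n_resamples=n_resamples, seed=seed)


def empirical_p(observed: float, null: NullDistribution) -> float:
    """Add-one empirical p-value: (1 + #{null >= observed}) / (1 + n)."""
    if null.n_resamples < 1:
        raise ValueError("null distribution is empty")
    count = int(np.count_nonzero(null.scores >= observed))
    return (1 + count) / (1 + null.n_resamples)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
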