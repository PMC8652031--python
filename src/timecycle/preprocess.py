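"""Replicate averaging, grid regularization, imputation, standardization.

Pipeline order is fixed: average replicates -> regularize grid ->
impute -> standardize.  The permutation null is always built from the
post-imputation series so that imputation assumptions are shared by
observed and null scores.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from timecycle.types import (
    ExpressionSet,
    PreprocessReport,
    Series,
    ZeroVarianceError,
)

_UNIFORM_TOL = 1e-9


def average_replicates(es: ExpressionSet) -> ExpressionSet:
    """Average replicate time-points, ignoring missing entries.

    Returns a single-replicate set with one column per unique time; a
    cell is missing only if it is missing in every replicate.
    """
    reps = np.unique(es.replicate_labels)
    if len(reps) == 1:
        return ExpressionSet(
            list(es.gene_ids), es.values.copy(), es.sample_times.copy(),
            np.ones(es.n_samples, dtype=int),
        )
    time_sets = {
        int(r): set(es.sample_times[es.replicate_labels == r].tolist())
        for r in reps
    }
    for i, ri in enumerate(reps):
        for rj in reps[i + 1:]:
            if not (time_sets[int(ri)] & time_sets[int(rj)]):
                raise ValueError(
                    f"replicates {ri} and {rj} have disjoint time grids"
                )
    unique_times = np.unique(es.sample_times)
    out = np.full((es.n_genes, len(unique_times)), np.nan)
    for k, t in enumerate(unique_times):
        vals = es.values[:, es.sample_times == t]
        cnt = (~np.isnan(vals)).sum(axis=1)
        tot = np.nansum(vals, axis=1)
        out[:, k] = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return ExpressionSet(
        list(es.gene_ids), out, unique_times,
        np.ones(len(unique_times), dtype=int),
    )


def impute_linear(s: Series) -> Series:
    """Fill missing values by linear interpolation in time.

    Interior gaps are interpolated between the nearest observed
    neighbours; leading/trailing gaps take the nearest observed value
    (constant extension, so the embedding sees no manufactured trend).
    """
    obs = ~s.mask
    if np.count_nonzero(obs) < 2:
        raise ValueError("need at least 2 observed values to impute")
    if obs.all():
        return Series(s.times.copy(), s.values.copy())
    filled = np.interp(s.times, s.times[obs], s.values[obs])
    return Series(s.times.copy(), filled)


def standardize(s: Series) -> Series:
    """Mean-center and scale to unit sample (n-1) standard deviation."""
    if s.mask.any():
        raise ValueError("standardize requires a fully observed series")
    if len(s) < 2:
        raise ValueError("standardize requires at least 2 points")
    sd = float(np.std(s.values, ddof=1))
    if not np.isfinite(sd) or sd <= 0.0:
        raise ZeroVarianceError("zero-variance series")
    return Series(s.times.copy(), (s.values - s.values.mean()) / sd)


def prepare_series(es: ExpressionSet) -> tuple[list[Optional[Series]],
                                               PreprocessReport]:
    """Average -> regularize -> impute every gene; report the bookkeeping.

    Genes with fewer than 3 observed time points after averaging come
    back as None (degenerate).  The report counts imputed points per
    gene and records the working grid interval and replicate count.
    """
    averaged = average_replicates(es)
    n_imputed = np.zeros(averaged.n_genes, dtype=int)
    out: list[Optional[Series]] = []
    for g in range(averaged.n_genes):
        s = averaged.gene_series(g)
        if s.n_observed < 3:
            out.append(None)
            continue
        n_imputed[g] = int(s.mask.sum())
        s = regularize_grid(s)
        out.append(impute_linear(s))
    steps = np.diff(averaged.sample_times)
    interval = float(steps.min()) if steps.size else 1.0
    report = PreprocessReport(
        n_imputed_per_gene=n_imputed,
        grid_interval_h=interval,
        replicate_count=len(np.unique(es.replicate_labels)),
    )
    return out, report


def regularize_grid(s: Series) -> Series:
    """Resample onto a uniform grid at the minimum observed interval.

    Already-uniform series pass through unchanged (missing values
    preserved).  Uneven series are linearly interpolated onto the
    uniform grid using the observed points only, so the output is
    fully observed.
    """
    if len(s) < 2:
        return Series(s.times.copy(), s.values.copy())
    steps = np.diff(s.times)
    if steps.max() - steps.min() < _UNIFORM_TOL:
        return Series(s.times.copy(), s.values.copy())
    dt = float(steps.min())
    n = int(round((s.times[-1] - s.times[0]) / dt)) + 1
    grid = s.times[0] + dt * np.arange(n)
    obs = ~s.mask
    if np.count_nonzero(obs) < 2:
        raise ValueError("need at least 2 observed values to regularize")
    vals = np.interp(grid, s.times[obs], s.values[obs])
    return Series(grid, vals)
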