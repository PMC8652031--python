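"""End-to-end per-gene analysis.

Pipeline order: average replicates -> regularize grid -> impute ->
standardize -> persistence score over the lag sweep -> shared-null
p-value -> BH q-value.  Period/phase/amplitude are estimated from the
replicate-averaged, imputed but unscaled series so amplitude stays in
input units.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from timecycle import preprocess, rhythm
from timecycle.inference import bh_fdr, build_shared_null, empirical_p
from timecycle.state_space import DEFAULT_K_NEIGHBORS, DEFAULT_LAGS
from timecycle.topology import NLDRSettings, persistence_score
from timecycle.types import (
    ExpressionSet,
    GeneResult,
    Series,
    ZeroVarianceError,
)

logger = logging.getLogger(__name__)

__all__ = ["TimeCycleConfig", "run_timecycle"]


@dataclass
class TimeCycleConfig:
    """Analysis settings for :func:`run_timecycle`."""

    lags: Sequence[int] = DEFAULT_LAGS
    n_resamples: int = 10_000
    seed: int = 0
    expected_period_h: float = 24.0
    k_neighbors: int = DEFAULT_K_NEIGHBORS
    heat_scale: object = "auto"

    def nldr(self) -> NLDRSettings:
        return NLDRSettings(self.k_neighbors, self.heat_scale)


def _degenerate_result(gene_id: str) -> dict:
    return {"gene_id": gene_id, "persistence": 0.0, "p_value": 1.0,
            "period_h": None, "phase_h": None, "amplitude": None}


def run_timecycle(
    es: ExpressionSet,
    config: Optional[TimeCycleConfig] = None,
) -> list[GeneResult]:
    """Score every gene in ``es``; one :class:`GeneResult` per row.

    Degenerate genes (constant, or fewer than 3 usable time points)
    get persistence 0, p = 1 and undefined rhythm parameters.  The
    shared null is generated once from a generator seeded with
    ``config.seed`` before per-gene scoring, so gene order cannot
    affect it.
    """
    config = config or TimeCycleConfig()
    nldr = config.nldr()
    t0 = time.perf_counter()

    imputed, report = preprocess.prepare_series(es)
    n_genes = len(imputed)
    logger.info("grid interval %.3gh, %d replicate(s), %d imputed values",
                report.grid_interval_h, report.replicate_count,
                int(report.n_imputed_per_gene.sum()))

    standardized: list[Optional[Series]] = [None] * n_genes
    for g, s in enumerate(imputed):
        if s is None:
            logger.warning("gene %s has <3 usable time points; "
                           "reporting undefined result", es.gene_ids[g])
            continue
        try:
            standardized[g] = preprocess.standardize(s)
        except ZeroVarianceError:
            logger.warning("gene %s is constant; reporting undefined result",
                           es.gene_ids[g])
    t1 = time.perf_counter()
    logger.info("preprocessing: %.2fs", t1 - t0)

    usable = [g for g in range(n_genes) if standardized[g] is not None]
    if usable:
        grid = standardized[usable[0]].times
        std_es = ExpressionSet(
            [es.gene_ids[g] for g in usable],
            np.vstack([standardized[g].values for g in usable]),
            grid, np.ones(len(grid), dtype=int),
        )
        null = build_shared_null(std_es, config.n_resamples, config.lags,
                                 nldr, rng=config.seed)
        null_sorted = np.sort(null.scores)
    else:
        null = None
    t2 = time.perf_counter()
    logger.info("shared null (%d resamples): %.2fs", config.n_resamples,
                t2 - t1)

    rows: list[dict] = []
    for g in range(n_genes):
        if standardized[g] is None:
            rows.append(_degenerate_result(es.gene_ids[g]))
            continue
        score = persistence_score(standardized[g], config.lags, nldr).score
        n_ge = len(null_sorted) - int(
            np.searchsorted(null_sorted, score, side="left"))
        p = (1 + n_ge) / (1 + null.n_resamples)
        row = {"gene_id": es.gene_ids[g], "persistence": score, "p_value": p}
        s_imp = imputed[g]
        if len(s_imp) >= 8:
            period, phase, amplitude = rhythm.estimate_rhythm(
                s_imp, config.expected_period_h)
        else:
            period = phase = amplitude = None
        row.update(period_h=period, phase_h=phase, amplitude=amplitude)
        rows.append(row)
    t3 = time.perf_counter()
    logger.info("per-gene scoring (%d genes): %.2fs", n_genes, t3 - t2)

    qvals = bh_fdr([r["p_value"] for r in rows])
    return [GeneResult(q_value=float(q), **row)
            for row, q in zip(rows, qvals)]
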