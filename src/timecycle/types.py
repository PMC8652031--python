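"""Domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


class TimeCycleError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TimeCycleError):
    """Malformed input file (bad header, duplicate ids, too few samples)."""


class ZeroVarianceError(TimeCycleError):
    """Sentinel for a degenerate (constant or all-missing) series.

    Callers map this to persistence 0, p = 1 and undefined rhythm
    parameters.
    """


@dataclass
class Series:
    """A single gene's ordered values on a time grid (hours).

    Missing entries are NaN; ``mask`` exposes them explicitly.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if self.times.shape != self.values.shape:
            raise ValueError(
                f"length mismatch: {len(self.times)} times vs "
                f"{len(self.values)} values"
            )
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask, True where the value is missing."""
        return np.isnan(self.values)

    @property
    def n_observed(self) -> int:
        return int(np.count_nonzero(~self.mask))

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ExpressionSet:
    """Gene x sample expression matrix with per-sample time/replicate labels."""

    gene_ids: list[str]
    values: np.ndarray
    sample_times: np.ndarray
    replicate_labels: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.replicate_labels = np.asarray(self.replicate_labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (genes x samples)")
        n_samples = self.values.shape[1]
        if len(self.sample_times) != n_samples:
            raise ValueError(
                f"{n_samples} columns but {len(self.sample_times)} sample times"
            )
        if len(self.replicate_labels) != n_samples:
            raise ValueError(
                f"{n_samples} columns but "
                f"{len(self.replicate_labels)} replicate labels"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dups = sorted({g for g in self.gene_ids if g in seen or seen.add(g)})
            raise ValueError(f"duplicate gene ids: {dups}")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length must match number of rows")
        for rep in np.unique(self.replicate_labels):
            t = self.sample_times[self.replicate_labels == rep]
            if len(t) >= 2 and not np.all(np.diff(t) > 0):
                raise ValueError(
                    f"sample times within replicate {rep} must be strictly "
                    "increasing"
                )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_series(self, index: int) -> Series:
        """Series of one gene; only valid for single-replicate sets."""
        if len(np.unique(self.replicate_labels)) != 1:
            raise ValueError("gene_series requires a single replicate; "
                             "average replicates first")
        return Series(self.sample_times.copy(), self.values[index].copy())


@dataclass
class GeneResult:
    """Per-gene output of the full pipeline."""

    gene_id: str
    persistence: float
    p_value: float
    q_value: float
    period_h: Optional[float] = None
    phase_h: Optional[float] = None
    amplitude: Optional[float] = None

    def __post_init__(self) -> None:
        if self.persistence < 0:
            raise ValueError("persistence must be >= 0")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must be in (0, 1]")
        if not (0 < self.q_value <= 1):
            raise ValueError("q_value must be in (0, 1]")


@dataclass
class PointCloud:
    """Finite point set in 2- or 3-D from delay embedding / NLDR."""

    points: np.ndarray
    source_lag: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2:
            raise ValueError("points must be an (n, d) array")
        if self.points.shape[1] not in (2, 3):
            raise ValueError("point dimension must be 2 or 3")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dimension(self) -> int:
        return self.points.shape[1]


@dataclass
class PersistenceScore:
    """Mean of per-lag H1 max-persistence scores for one series."""

    score: float
    lags: tuple[int, ...]
    per_lag_scores: np.ndarray

    def __post_init__(self) -> None:
        self.per_lag_scores = np.asarray(self.per_lag_scores, dtype=float)
        if len(self.lags) != len(self.per_lag_scores):
            raise ValueError("lags and per_lag_scores must align")


@dataclass
class NullDistribution:
    """Shared permutation-null persistence scores."""

    scores: np.ndarray
    n_resamples: int
    seed: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != self.n_resamples:
            raise ValueError("scores length must equal n_resamples")
        if np.any(self.scores < 0):
            raise ValueError("null scores must be non-negative")


@dataclass
class PreprocessReport:
    """Bookkeeping emitted by the preprocessing stage."""

    n_imputed_per_gene: np.ndarray
    grid_interval_h: float
    replicate_count: int

    def __post_init__(self) -> None:
        self.n_imputed_per_gene = np.asarray(self.n_imputed_per_gene, dtype=int)
        if np.any(self.n_imputed_per_gene < 0):
            raise ValueError("imputed counts must be >= 0")
        if self.grid_interval_h <= 0:
            raise ValueError("grid interval must be positive")
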