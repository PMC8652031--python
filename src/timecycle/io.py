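"""Expression-matrix and results I/O.

The default column-header convention is ``ZT_<hours>_<replicate>``
(e.g. ``ZT_0_1``); the replicate suffix may be omitted for
single-replicate data.  A custom regular expression with ``time`` and
(optionally) ``rep`` named groups can be supplied instead.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from timecycle.types import ExpressionSet, FormatError, GeneResult

DEFAULT_TIME_REGEX = r"^ZT_?(?P<time>\d+(?:\.\d+)?)(?:_(?P<rep>\d+))?$"

RESULT_COLUMNS = ("gene", "persistence", "pVal", "qVal", "period", "phase",
                  "amplitude")


def _parse_header(columns: Sequence[str], pattern: str) -> tuple[np.ndarray, np.ndarray]:
    rx = re.compile(pattern)
    times, reps = [], []
    for col in columns:
        m = rx.match(str(col).strip())
        if m is None:
            raise FormatError(
                f"column header {col!r} does not match time convention "
                f"{pattern!r}"
            )
        times.append(float(m.group("time")))
        try:
            rep = m.group("rep")
        except IndexError:
            rep = None
        reps.append(int(rep) if rep is not None else 1)
    return np.asarray(times, dtype=float), np.asarray(reps, dtype=int)


def read_expression_matrix(
    path: str | Path,
    time_regex: str = DEFAULT_TIME_REGEX,
    delimiter: Optional[str] = None,
    na_strings: Sequence[str] = ("NA", "NaN", "nan", ""),
) -> ExpressionSet:
    """Read a delimited gene x sample matrix into an :class:`ExpressionSet`.

    The first column holds gene ids; remaining column headers encode
    sampling time (hours) and replicate.  Cells that cannot be parsed as
    numbers become missing values.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                     keep_default_na=False)
    if df.shape[1] < 3:
        raise FormatError(
            f"need at least 3 sample columns, found {df.shape[1]}"
        )
    gene_ids = [str(g) for g in df.index]
    if len(set(gene_ids)) != len(gene_ids):
        seen: set[str] = set()
        dups = sorted({g for g in gene_ids if g in seen or seen.add(g)})
        raise FormatError(f"duplicate gene ids: {dups}")
    times, reps = _parse_header(df.columns, time_regex)

    cleaned = df.mask(df.isin(list(na_strings)))
    values = cleaned.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return ExpressionSet(gene_ids, values, times, reps)


def _fmt(x: Optional[float]) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return format(float(x), ".6g")


def write_results(results: Sequence[GeneResult], path: str | Path) -> None:
    """Write results as a TSV with one row per gene, in input order."""
    if not results:
        raise ValueError("results must be non-empty")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            row = (r.gene_id, _fmt(r.persistence), _fmt(r.p_value),
                   _fmt(r.q_value), _fmt(r.period_h), _fmt(r.phase_h),
                   _fmt(r.amplitude))
            fh.write("\t".join(row) + "\n")


def read_results(path: str | Path) -> list[GeneResult]:
    """Parse a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str},
                     na_values=["NA"], keep_default_na=False)
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"results file missing columns: {sorted(missing)}")

    def opt(x: float) -> Optional[float]:
        return None if pd.isna(x) else float(x)

    return [
        GeneResult(
            gene_id=row.gene,
            persistence=float(row.persistence),
            p_value=float(row.pVal),
            q_value=float(row.qVal),
            period_h=opt(row.period),
            phase_h=opt(row.phase),
            amplitude=opt(row.amplitude),
        )
        for row in df.itertuples(index=False)
    ]
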