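"""Readers and writers for the delimited text formats.

The canonical on-disk layout is samples-as-rows: a header row of gene
identifiers plus one label column, a leading sample-id column, and one row
per sample.  The common genes-as-rows dialect (the exact transpose of that
file) is read via ``orientation="genes"``.  Delimiter (comma vs tab) is
auto-detected from the header line and can be overridden.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .evaluation import ErrorReport
from .scores import ScoreTable
from .selection import SelectionResult

__all__ = [
    "load_dataset",
    "write_dataset",
    "write_score_table",
    "read_score_table",
    "write_selections",
    "write_error_report",
]

log = logging.getLogger("mdselect")

DEFAULT_LABEL_COLUMN = "class"


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def load_dataset(
    path,
    label_column: str = DEFAULT_LABEL_COLUMN,
    orientation: str = "samples",
    delimiter: str | None = None,
) -> ExpressionDataset:
    """Load and validate a delimited expression file.

    The two distinct label values are mapped to {0, 1} in sorted order and
    the mapping is logged.  Non-numeric, NaN or infinite cells, missing or
    degenerate label columns, and duplicate gene ids are rejected with
    messages naming the offending row/column.

    Parameters
    ----------
    orientation
        ``"samples"`` (samples as rows, the canonical layout) or
        ``"genes"`` (the transposed dialect).
    delimiter
        Explicit field separator; auto-detected from the header if None.
    """
    path = Path(path)
    if orientation not in ("samples", "genes"):
        raise ValueError(f"orientation must be 'samples' or 'genes', got {orientation!r}")
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if orientation == "samples":
        # pandas mangles duplicate header names, so check the raw header
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        dup = pd.Series(header)[pd.Series(header).duplicated()]
        if not dup.empty:
            raise ValueError(f"duplicate gene id {dup.iloc[0]!r} in header")
    else:
        dup = df.index[df.index.duplicated()]
        if not dup.empty:
            raise ValueError(f"duplicate gene id {dup[0]!r} in first column")
        df = df.T
    if label_column not in df.columns:
        raise ValueError(
            f"label column {label_column!r} not found in {path.name}; "
            f"columns start with {list(df.columns[:5])}"
        )
    raw_labels = df[label_column]
    levels = sorted(raw_labels.astype(str).unique())
    if len(levels) != 2:
        raise ValueError(
            f"label column {label_column!r} must have exactly 2 distinct values, "
            f"found {len(levels)}: {levels[:6]}"
        )
    mapping = {levels[0]: 0, levels[1]: 1}
    log.info("label mapping: %r -> 0, %r -> 1", levels[0], levels[1])
    labels = raw_labels.astype(str).map(mapping).to_numpy()

    expr = df.drop(columns=[label_column])
    values = expr.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if len(bad):
        i, j = bad[0]
        raise ValueError(
            f"non-numeric or non-finite value {expr.iat[i, j]!r} at "
            f"sample {expr.index[i]!r}, gene {expr.columns[j]!r}"
        )
    return ExpressionDataset(
        values=values,
        labels=labels,
        gene_ids=expr.columns.astype(str).to_numpy(),
        sample_ids=expr.index.astype(str).to_numpy(),
    )


def write_dataset(
    data: ExpressionDataset,
    path,
    label_column: str = DEFAULT_LABEL_COLUMN,
    delimiter: str = ",",
) -> None:
    """Write the canonical samples-as-rows layout (full float precision)."""
    df = pd.DataFrame(data.values, index=data.sample_ids, columns=data.gene_ids)
    df.insert(len(df.columns), label_column, data.labels)
    df.index.name = "sample_id"
    # %.17g guarantees float64 round-trips through text exactly
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def write_score_table(table: ScoreTable, path, delimiter: str = ",") -> None:
    table.table.to_csv(path, sep=delimiter, index=False)


def read_score_table(path, delimiter: str | None = None) -> ScoreTable:
    sep = delimiter or _sniff_delimiter(Path(path))
    return ScoreTable(table=pd.read_csv(path, sep=sep))


def write_selections(
    selections: list[SelectionResult], path, genelist_dir=None, delimiter: str = ","
) -> None:
    """Write the long selections table and, optionally, per-(method, k)
    gene-list files (one id per line) under ``genelist_dir``."""
    rows = [
        {"method": s.method, "k": s.k, "rank": r + 1, "gene_id": g, "score": sc}
        for s in selections
        for r, (g, sc) in enumerate(zip(s.gene_ids, s.scores))
    ]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)
    if genelist_dir is not None:
        genelist_dir = Path(genelist_dir)
        genelist_dir.mkdir(parents=True, exist_ok=True)
        for s in selections:
            out = genelist_dir / f"{s.method}_top{s.k}.txt"
            out.write_text("\n".join(s.gene_ids) + "\n")


def write_error_report(report: ErrorReport, path, delimiter: str = ",") -> None:
    report.to_csv(path, sep=delimiter)
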