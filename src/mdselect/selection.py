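"""Top-k gene selection from a score table.

The selection protocol keeps, for each scoring method, the k best-ranked
genes (k = 5, 10, 15 and 20 by default), producing the method x k grid
whose subsets are then handed to the classification-error harness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .scores import METHODS, ScoreTable

__all__ = ["SelectionResult", "select_top_k", "selection_grid", "DEFAULT_KS"]

DEFAULT_KS = (5, 10, 15, 20)


@dataclass(frozen=True)
class SelectionResult:
    """An ordered top-k gene subset for one method.

    ``gene_ids`` are in rank order (best first); ``scores`` carry the
    method's ranking statistic for those genes — non-increasing for
    score-ranked methods, non-decreasing P-values for wilcoxon.
    """

    method: str
    k: int
    gene_ids: tuple[str, ...]
    scores: tuple[float, ...]


def select_top_k(table: ScoreTable, method: str, k: int) -> SelectionResult:
    """The k best-ranked genes for ``method``, stable under ties.

    Ties were already broken deterministically (by gene column order) when
    the ranks were assigned, so two runs on the same table are identical.
    If k exceeds the number of genes, all genes are returned with a warning.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid methods: {list(METHODS)}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    g = table.n_genes
    if k > g:
        warnings.warn(
            f"k={k} exceeds the {g} available genes; returning all genes", stacklevel=2
        )
        k = g
    ranks = table.ranks(method)
    order = np.argsort(ranks, kind="stable")[:k]
    scores = table.scores(method)
    return SelectionResult(
        method=method,
        k=k,
        gene_ids=tuple(table.gene_ids[order]),
        scores=tuple(float(s) for s in scores[order]),
    )


def selection_grid(
    table: ScoreTable,
    methods: Sequence[str] = METHODS,
    ks: Iterable[int] = DEFAULT_KS,
) -> list[SelectionResult]:
    """One :class:`SelectionResult` per (method, k) pair, methods-major."""
    methods = list(methods)
    ks = list(ks)
    if not methods or not ks:
        raise ValueError("methods and ks must be non-empty")
    return [select_top_k(table, m, k) for m in methods for k in ks]
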