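"""Two-class expression dataset container.

The universal input of the package: a real-valued samples x genes matrix
with a binary class label per sample.  Everything downstream (scoring,
selection, cross-validated evaluation) consumes this type, so validation
happens once, here, at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExpressionDataset"]


@dataclass(frozen=True)
class ExpressionDataset:
    """Samples x genes expression matrix with binary labels.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_genes)
        Real expression values; must be finite.
    labels : ndarray of shape (n_samples,)
        Class membership per sample, coded 0/1.  Both classes must be
        present with at least two samples each (class standard deviations
        use the n-1 denominator and are undefined otherwise).
    gene_ids : sequence of str
        Unique gene identifiers, one per column.
    sample_ids : sequence of str
        Unique sample identifiers, one per row.
    """

    values: np.ndarray
    labels: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        gene_ids = np.asarray(self.gene_ids, dtype=str)
        if self.sample_ids is None:
            sample_ids = np.array([f"s{i + 1}" for i in range(values.shape[0])])
        else:
            sample_ids = np.asarray(self.sample_ids, dtype=str)

        if values.ndim != 2:
            raise ValueError(f"values must be 2-D (samples x genes), got ndim={values.ndim}")
        n, g = values.shape
        if labels.shape != (n,):
            raise ValueError(f"labels length {labels.shape} does not match {n} samples")
        if sample_ids.shape != (n,):
            raise ValueError(f"sample_ids length {len(sample_ids)} does not match {n} samples")
        if gene_ids.shape != (g,):
            raise ValueError(f"gene_ids length {len(gene_ids)} does not match {g} genes")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at sample {sample_ids[bad[0]]!r}, gene {gene_ids[bad[1]]!r}"
            )
        extra = set(np.unique(labels)) - {0, 1}
        if extra:
            raise ValueError(f"labels must be coded 0/1, found extra values {sorted(extra)}")
        for k in (0, 1):
            nk = int(np.sum(labels == k))
            if nk < 2:
                raise ValueError(
                    f"class {k} has {nk} sample(s); at least 2 per class are required "
                    "(class SD uses the n-1 denominator)"
                )
        if len(np.unique(gene_ids)) != g:
            dup = _first_duplicate(gene_ids)
            raise ValueError(f"duplicate gene id {dup!r}")
        if len(np.unique(sample_ids)) != n:
            dup = _first_duplicate(sample_ids)
            raise ValueError(f"duplicate sample id {dup!r}")

        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def class_sizes(self) -> tuple[int, int]:
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def class_values(self, k: int) -> np.ndarray:
        """Rows of the matrix belonging to class ``k`` (0 or 1)."""
        return self.values[self.labels == k]

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        """Restrict to the given genes, preserving the requested order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"unknown gene id(s): {missing[:5]}")
        cols = np.array([index[g] for g in gene_ids], dtype=int)
        return ExpressionDataset(
            values=self.values[:, cols],
            labels=self.labels,
            gene_ids=np.asarray(list(gene_ids), dtype=str),
            sample_ids=self.sample_ids,
        )

    def subset_samples(self, rows: np.ndarray) -> "ExpressionDataset":
        """Restrict to the given sample rows (index array or boolean mask)."""
        return ExpressionDataset(
            values=self.values[rows],
            labels=self.labels[rows],
            gene_ids=self.gene_ids,
            sample_ids=self.sample_ids[rows],
        )


def _first_duplicate(ids) -> str:
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return ""
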