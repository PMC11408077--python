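"""Seeded two-class expression simulators and hand-computable fixtures.

The simulator emulates the regime the filter scores are designed for:
many more genes than samples, a small planted set of informative genes
carrying a between-class mean shift, and a large majority of pure-noise
genes.  Optional log-normal noise produces right-skewed marginals and
optional cell-wise contamination injects extreme outliers — the data
features that motivate a median-based test over a mean-based score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .dataset import ExpressionDataset

__all__ = ["SimSpec", "simulate", "fixture_suite", "Fixture"]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated dataset.

    n0, n1
        Samples per class (>= 2 each).
    n_genes
        Total genes; the first ``n_informative`` are planted.
    n_informative
        Genes given a true between-class shift.
    effect
        Mean shift in noise-SD units (class 1 shifted up); 0 = null.
    noise
        ``"normal"`` or ``"lognormal"`` (the normal draws, shift included,
        are exponentiated, giving right skew).
    outlier_fraction
        Fraction of matrix cells replaced by outliers, in [0, 1).
    outlier_magnitude
        Outlier offset added to the contaminated cell, in noise-SD units
        (default 20 — far outside the bulk of the distribution).
    seed
        Seed for the generator; same spec + seed = bit-identical matrix.
    """

    n0: int = 20
    n1: int = 20
    n_genes: int = 100
    n_informative: int = 5
    effect: float = 1.0
    noise: str = "normal"
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n0 < 2 or self.n1 < 2:
            raise ValueError("need at least 2 samples per class")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError("n_informative must be in [0, n_genes]")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.noise not in ("normal", "lognormal"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")


def simulate(spec: SimSpec) -> tuple[ExpressionDataset, frozenset[str]]:
    """Generate a dataset from ``spec`` plus the set of truly informative genes.

    Genes are iid standard normal noise; the first ``n_informative``
    columns get ``effect`` added in class 1.  Log-normal mode exponentiates
    the (shifted) draws.  Contamination then adds ``outlier_magnitude`` to a
    uniformly chosen fraction of cells.  Labels are sorted, class 0 first.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n0 + spec.n1
    x = rng.standard_normal((n, spec.n_genes))
    labels = np.concatenate([np.zeros(spec.n0, dtype=int), np.ones(spec.n1, dtype=int)])
    x[labels == 1, : spec.n_informative] += spec.effect
    if spec.noise == "lognormal":
        x = np.exp(x)
    n_out = int(round(spec.outlier_fraction * x.size))
    if n_out:
        cells = rng.choice(x.size, size=n_out, replace=False)
        x.flat[cells] += spec.outlier_magnitude
    width = len(str(spec.n_genes))
    gene_ids = np.array([f"g{j + 1:0{width}d}" for j in range(spec.n_genes)])
    data = ExpressionDataset(values=x, labels=labels, gene_ids=gene_ids)
    truth = frozenset(gene_ids[: spec.n_informative])
    return data, truth


class Fixture(NamedTuple):
    """A tiny canned dataset with its hand-computed expected statistics."""

    name: str
    data: ExpressionDataset
    expected: dict


def fixture_suite() -> dict[str, Fixture]:
    """Hand-computable toy datasets with their expected statistics.

    * ``sep_gene``: one gene, class 0 = [0, 2], class 1 = [4, 6].  Means
      1 and 5, both SDs sqrt(2), so SNR = 4 / (2 sqrt 2) ~ 1.41421 and the
      Fisher score is 16/8 = 2.  The pooled median is 3; the 2x2 median
      table is (a,b,c,d) = (0,2,2,0), chi-square 4.
    * ``sym_mood``: both classes are [1, 2, 3, 4]; every statistic is at
      its null value (SNR 0, Mood and Wilcoxon P = 1).
    * ``sep_toy``: 4 samples x 3 genes where only g2 separates the
      classes; g2 ranks first under all four methods.
    * ``wilcoxon_123``: class 0 = [1, 2, 3] vs class 1 = [4, 5, 6]; the
      exact two-sided rank-sum P is 0.1 (2 of the 20 label assignments are
      as extreme, i.e. 2 * 1/20).
    * ``mood_sep``: class 0 = [1..5] vs class 1 = [11..15]; grand median 8,
      table (0,5,5,0), chi-square 10.
    """
    chi2_4_p = 0.04550026389635842  # chi-square(1) upper tail at 4
    suite = {}

    data = ExpressionDataset(
        values=np.array([[0.0], [2.0], [4.0], [6.0]]),
        labels=[0, 0, 1, 1],
        gene_ids=["g1"],
    )
    suite["sep_gene"] = Fixture(
        "sep_gene",
        data,
        {
            "mu0": 1.0,
            "mu1": 5.0,
            "sigma": np.sqrt(2.0),
            "snr": 4.0 / (2.0 * np.sqrt(2.0)),
            "fisher": 2.0,
            "mood_chi2": 4.0,
            "mood_p": chi2_4_p,
            "md": (4.0 / (2.0 * np.sqrt(2.0))) / chi2_4_p,
        },
    )

    vals = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0])[:, np.newaxis]
    suite["sym_mood"] = Fixture(
        "sym_mood",
        ExpressionDataset(values=vals, labels=[0] * 4 + [1] * 4, gene_ids=["g1"]),
        {"snr": 0.0, "mood_p": 1.0, "wilcoxon_p": 1.0, "mood_table": (2, 2, 2, 2)},
    )

    toy = np.array(
        [
            # g1: identical class multisets; g2: separable; g3: constant
            [5.0, 0.0, 7.0],
            [1.0, 2.0, 7.0],
            [1.0, 4.0, 7.0],
            [5.0, 6.0, 7.0],
        ]
    )
    suite["sep_toy"] = Fixture(
        "sep_toy",
        ExpressionDataset(values=toy, labels=[0, 0, 1, 1], gene_ids=["g1", "g2", "g3"]),
        {"best_gene": "g2"},
    )

    suite["wilcoxon_123"] = Fixture(
        "wilcoxon_123",
        ExpressionDataset(
            values=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])[:, np.newaxis],
            labels=[0, 0, 0, 1, 1, 1],
            gene_ids=["g1"],
        ),
        {"wilcoxon_p": 0.1},
    )

    suite["mood_sep"] = Fixture(
        "mood_sep",
        ExpressionDataset(
            values=np.array([1.0, 2, 3, 4, 5, 11, 12, 13, 14, 15])[:, np.newaxis],
            labels=[0] * 5 + [1] * 5,
            gene_ids=["g1"],
        ),
        {"mood_chi2": 10.0, "mood_table": (0, 5, 5, 0)},
    )
    return suite
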