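"""Per-gene ranking statistics for two-class expression data.

Implements the four filter scores and the hybrid statistic that combines
two of them:

* **SNR** (signal-to-noise, a.k.a. S2N): ``|mu0 - mu1| / (sigma0 + sigma1)``
  — the gap between class means relative to within-class variability.
* **Fisher score**: sample-size-weighted between-class scatter over
  within-class scatter, ``sum_k n_k (mu_k - mu)^2 / sum_k n_k sigma_k^2``.
* **Wilcoxon rank-sum** (Mann-Whitney U) two-sided P-value; exact
  enumeration for small pooled sample sizes, tie-corrected normal
  approximation otherwise.
* **Mood's median test** P-value: dichotomize every sample at the pooled
  grand median and apply a 1-df Pearson chi-square test to the resulting
  2x2 table.  Being median-based, it is insensitive to single extreme
  outliers — the robustness that motivates the hybrid score.
* **Md**: the SNR score divided by the Mood's-test P-value.  A gene ranks
  highly only if it has both a large standardized mean gap *and* a
  median-level group difference that survives outliers.

All scorers are vectorized over genes.  Class standard deviations use the
n-1 denominator throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset

__all__ = [
    "GeneClassStats",
    "MedianTestTable",
    "ScoreTable",
    "ScoreConfig",
    "class_stats",
    "snr_score",
    "fisher_score",
    "wilcoxon_score",
    "mood_median_pvalue",
    "md_score",
    "score_all",
    "METHODS",
]

#: Canonical method names, in reporting order.
METHODS = ("md", "snr", "fisher", "wilcoxon")

#: Guard added to every variance/SD denominator so zero-variance genes
#: produce large-but-finite scores instead of infinities.
DEFAULT_EPS_SD = 1e-12

#: Floor applied to the Mood P-value before dividing: keeps Md finite when
#: the chi-square tail underflows, while leaving ultra-significant genes on top.
DEFAULT_P_FLOOR = 1e-300

#: Pooled sample size at or below which the Wilcoxon P-value is computed by
#: exhaustive enumeration of label assignments.
DEFAULT_EXACT_THRESHOLD = 12

_TINY = 5e-324  # smallest positive float; keeps P-values in (0, 1]


@dataclass(frozen=True)
class ScoreConfig:
    """Numerical knobs shared by the scorers.

    eps_sd
        Denominator guard for SNR and Fisher (default 1e-12).
    p_floor
        Lower bound on the Mood P-value inside the Md ratio (default 1e-300).
    exact_threshold
        Largest pooled n for which the Wilcoxon P is exact (default 12).
    mood_continuity
        Apply the Yates continuity correction to the median-test chi-square
        (default off: plain Pearson statistic).
    """

    eps_sd: float = DEFAULT_EPS_SD
    p_floor: float = DEFAULT_P_FLOOR
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD
    mood_continuity: bool = False


@dataclass(frozen=True)
class GeneClassStats:
    """Per-gene, per-class sample counts, means and SDs (n-1 denominator)."""

    n0: int
    n1: int
    mu0: np.ndarray
    mu1: np.ndarray
    sigma0: np.ndarray
    sigma1: np.ndarray
    mu: np.ndarray  # overall per-gene mean


@dataclass(frozen=True)
class MedianTestTable:
    """Per-gene 2x2 contingency tables behind Mood's median test.

    For each gene: ``grand_median`` is the pooled median over all samples;
    ``a``/``b`` count class-0/class-1 samples strictly above it and
    ``c``/``d`` those at or below it.  Stored as parallel arrays over genes.
    """

    grand_median: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray


@dataclass(frozen=True)
class ScoreTable:
    """All per-gene scores, P-values and per-method ranks (1 = best)."""

    table: pd.DataFrame = field(repr=False)

    COLUMNS = (
        "gene_id",
        "snr",
        "fisher",
        "wilcoxon_p",
        "mood_p",
        "md",
        "rank_snr",
        "rank_fisher",
        "rank_wilcoxon",
        "rank_md",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"ScoreTable missing columns {missing}")

    @property
    def gene_ids(self) -> np.ndarray:
        return self.table["gene_id"].to_numpy(dtype=str)

    @property
    def n_genes(self) -> int:
        return len(self.table)

    def scores(self, method: str) -> np.ndarray:
        """Ranking statistic for ``method`` (P-values for wilcoxon)."""
        col = {"md": "md", "snr": "snr", "fisher": "fisher", "wilcoxon": "wilcoxon_p"}
        if method not in col:
            raise ValueError(f"unknown method {method!r}; valid: {list(col)}")
        return self.table[col[method]].to_numpy()

    def ranks(self, method: str) -> np.ndarray:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; valid: {list(METHODS)}")
        return self.table[f"rank_{method}"].to_numpy(dtype=int)


def class_stats(data: ExpressionDataset) -> GeneClassStats:
    """Per-gene, per-class n, mean and SD, plus the overall mean.

    The overall mean equals the sample-size-weighted mean of the class
    means by construction.  Requires >= 2 samples per class (enforced at
    dataset construction; rechecked here for safety).
    """
    for k in (0, 1):
        nk = int(np.sum(data.labels == k))
        if nk < 2:
            raise ValueError(f"class {k} has {nk} sample(s); need >= 2 for the n-1 SD")
    x0 = data.class_values(0)
    x1 = data.class_values(1)
    return GeneClassStats(
        n0=x0.shape[0],
        n1=x1.shape[0],
        mu0=x0.mean(axis=0),
        mu1=x1.mean(axis=0),
        sigma0=x0.std(axis=0, ddof=1),
        sigma1=x1.std(axis=0, ddof=1),
        mu=data.values.mean(axis=0),
    )


def snr_score(stats_: GeneClassStats, eps_sd: float = DEFAULT_EPS_SD) -> np.ndarray:
    """Signal-to-noise score ``|mu0 - mu1| / (sigma0 + sigma1 + eps_sd)``."""
    return np.abs(stats_.mu0 - stats_.mu1) / (stats_.sigma0 + stats_.sigma1 + eps_sd)


def fisher_score(stats_: GeneClassStats, eps_sd: float = DEFAULT_EPS_SD) -> np.ndarray:
    """Fisher score: weighted between-class over within-class scatter."""
    between = stats_.n0 * (stats_.mu0 - stats_.mu) ** 2 + stats_.n1 * (stats_.mu1 - stats_.mu) ** 2
    within = stats_.n0 * stats_.sigma0**2 + stats_.n1 * stats_.sigma1**2
    return between / (within + eps_sd)


def _wilcoxon_exact(data: ExpressionDataset) -> np.ndarray:
    """Two-sided exact rank-sum P per gene by enumerating label assignments.

    Uses midranks, so ties are handled exactly.  The two-sided P is
    ``min(1, 2 * min(P(T <= t), P(T >= t)))`` for the class-0 rank sum T,
    whose null distribution is generated by all C(N, n0) assignments.
    """
    n0, _ = data.class_sizes
    n = data.n_samples
    combos = np.array(list(itertools.combinations(range(n), n0)), dtype=int)
    obs_rows = np.flatnonzero(data.labels == 0)
    p = np.empty(data.n_genes)
    for j in range(data.n_genes):
        ranks = stats.rankdata(data.values[:, j])
        t_all = ranks[combos].sum(axis=1)
        t_obs = ranks[obs_rows].sum()
        # tolerance absorbs float midrank round-off in the comparison
        lo = np.mean(t_all <= t_obs + 1e-9)
        hi = np.mean(t_all >= t_obs - 1e-9)
        p[j] = min(1.0, 2.0 * min(lo, hi))
    return p


def wilcoxon_score(
    data: ExpressionDataset, exact_threshold: int = DEFAULT_EXACT_THRESHOLD
) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) P-value per gene.

    Exact enumeration when the pooled sample size is at most
    ``exact_threshold``; otherwise the normal approximation with
    tie-corrected variance and continuity correction.
    """
    if data.n_samples <= exact_threshold:
        p = _wilcoxon_exact(data)
    else:
        res = stats.mannwhitneyu(
            data.class_values(0),
            data.class_values(1),
            alternative="two-sided",
            method="asymptotic",
            axis=0,
        )
        p = np.asarray(res.pvalue, dtype=float)
    return np.clip(p, _TINY, 1.0)


def mood_median_pvalue(
    data: ExpressionDataset, continuity: bool = False
) -> tuple[np.ndarray, MedianTestTable]:
    """Mood's median test P-value per gene, with the 2x2 tables for audit.

    Each sample is classified as strictly above vs at-or-below the pooled
    grand median of its gene; the 1-df Pearson chi-square statistic on the
    resulting class x side table gives the P-value (upper tail).  Degenerate
    tables — e.g. a constant gene, where nobody is above the median —
    return P = 1 (the gene carries no median-level signal).

    Parameters
    ----------
    continuity
        Apply the Yates continuity correction (default off).
    """
    n0, n1 = data.class_sizes
    n = data.n_samples
    med = np.median(data.values, axis=0)
    above = data.values > med[np.newaxis, :]
    a = above[data.labels == 0].sum(axis=0)
    b = above[data.labels == 1].sum(axis=0)
    c = n0 - a
    d = n1 - b
    row_above = a + b
    row_below = c + d
    degenerate = (row_above == 0) | (row_below == 0)

    diff = np.abs(a * d - b * c).astype(float)
    if continuity:
        diff = np.maximum(diff - n / 2.0, 0.0)
    denom = n0 * n1 * row_above * row_below
    chi2 = np.zeros(data.n_genes)
    ok = ~degenerate
    chi2[ok] = n * diff[ok] ** 2 / denom[ok]

    p = stats.chi2.sf(chi2, df=1)
    p[degenerate] = 1.0
    p = np.clip(p, _TINY, 1.0)
    table = MedianTestTable(grand_median=med, a=a, b=b, c=c, d=d)
    return p, table


def md_score(
    snr: np.ndarray, mood_p: np.ndarray, p_floor: float = DEFAULT_P_FLOOR
) -> np.ndarray:
    """Hybrid Md score: ``snr / max(mood_p, p_floor)`` per gene."""
    snr = np.asarray(snr, dtype=float)
    mood_p = np.asarray(mood_p, dtype=float)
    if snr.shape != mood_p.shape:
        raise ValueError(f"shape mismatch: snr {snr.shape} vs mood_p {mood_p.shape}")
    if p_floor <= 0:
        raise ValueError("p_floor must be positive")
    if np.any(snr < 0):
        raise ValueError("negative SNR input — upstream scoring bug")
    return snr / np.maximum(mood_p, p_floor)


def _rank(keys: np.ndarray, ascending: bool) -> np.ndarray:
    """Ranks 1..G, best first; ties broken by gene column order (stable)."""
    order = np.argsort(keys if ascending else -keys, kind="stable")
    ranks = np.empty(len(keys), dtype=int)
    ranks[order] = np.arange(1, len(keys) + 1)
    return ranks


def score_all(data: ExpressionDataset, config: ScoreConfig | None = None) -> ScoreTable:
    """Run all four scorers and assemble the full score/rank table.

    Ranking direction: descending for snr, fisher and md; ascending for
    the wilcoxon P-value.  Ties break by gene column order.
    """
    cfg = config or ScoreConfig()
    st = class_stats(data)
    snr = snr_score(st, eps_sd=cfg.eps_sd)
    fisher = fisher_score(st, eps_sd=cfg.eps_sd)
    wilcoxon_p = wilcoxon_score(data, exact_threshold=cfg.exact_threshold)
    mood_p, _ = mood_median_pvalue(data, continuity=cfg.mood_continuity)
    md = md_score(snr, mood_p, p_floor=cfg.p_floor)
    table = pd.DataFrame(
        {
            "gene_id": data.gene_ids,
            "snr": snr,
            "fisher": fisher,
            "wilcoxon_p": wilcoxon_p,
            "mood_p": mood_p,
            "md": md,
            "rank_snr": _rank(snr, ascending=False),
            "rank_fisher": _rank(fisher, ascending=False),
            "rank_wilcoxon": _rank(wilcoxon_p, ascending=True),
            "rank_md": _rank(md, ascending=False),
        }
    )
    return ScoreTable(table=table)
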