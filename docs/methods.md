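# Methods

## Statistics

All scores operate on a samples × genes matrix with binary labels; class
standard deviations use the n−1 denominator, and every gene is scored
independently of the others.

**SNR (S2N).** `snr_j = |μ₀ⱼ − μ₁ⱼ| / (σ₀ⱼ + σ₁ⱼ + ε)` with
ε = 1e-12. The absolute difference is used because ranking needs a
magnitude, not a direction. The ε guard keeps zero-variance genes (both
classes constant but at different levels) at large finite scores instead
of infinity, preserving a total order.

**Fisher score.** `S_j = Σₖ nₖ(μₖⱼ − μⱼ)² / (Σₖ nₖ σₖⱼ² + ε)`, the
canonical weighted between-/within-class scatter ratio, with the same ε
guard. Both SNR and Fisher are invariant to shifting a gene by a constant
and to positive rescaling.

**Wilcoxon rank-sum.** Two-sided Mann–Whitney P-value per gene. For
pooled n ≤ 12 (configurable) the null distribution of the class-0 midrank
sum is enumerated over all C(n, n₀) label assignments, which is exact
under ties; the two-sided P is `min(1, 2·min(P(T≤t), P(T≥t)))`. Above
the threshold the normal approximation with tie-corrected variance and
continuity correction is used (scipy's asymptotic Mann–Whitney path).

**Mood's median test.** Per gene, the pooled grand median is computed
over both classes; each sample is classified *strictly above* vs
*at-or-below* it (ties with the median count as below — one documented
convention rather than a dropped-ties variant, so every sample is used
and margins are fixed at n₀, n₁). The 1-df Pearson chi-square on the 2×2
class × side table gives the P-value from the chi-square upper tail.
Yates continuity correction is off by default and available as a flag.
Degenerate tables (a side with zero total, e.g. a constant gene) return
P = 1: such a gene carries no median-level signal and must not rank.

**Md.** `Md_j = snr_j / max(P_mood,j, p_floor)` with p_floor = 1e-300.
The floor only matters when the chi-square tail underflows; it keeps the
score finite while leaving ultra-significant genes at the top. Md is
strictly increasing in SNR at fixed P and strictly decreasing in P at
fixed positive SNR. The intended behaviour under contamination: a single
extreme outlier inflates a noise gene's SNR (it moves one class mean and
SD), but shifts at most one sample across the pooled median, so the Mood
P stays unremarkable and Md holds the gene down.

**Ranks.** Descending for snr/fisher/md, ascending for the Wilcoxon P;
ties break by gene column order (stable sort), making every run
deterministic.

## Selection and evaluation

Top-k subsets are taken per method for k ∈ {5, 10, 15, 20} by default;
selections at smaller k are prefixes of larger k. If k exceeds the gene
count the full ranking is returned with a warning, so small fixtures work
under the default grid.

Errors are estimated with repeated stratified k-fold CV (default 5 folds
× 10 repeats, seeded) as the mean ± SD of per-fold misclassification
fractions, for Random Forest (default 500 trees, library split defaults)
and K-NN (default 3 neighbours, Euclidean metric, majority vote). Fold,
repeat and neighbour counts are pragmatic conventions: 5×10 gives a
low-variance average at modest cost, and k=3 is the smallest
noise-tolerant odd neighbourhood. Tests and the acceptance script run
reduced grids (100-tree forests, 2 repeats) since the threshold
properties they check do not depend on ensemble size.

Two selection timings are provided. `pre_cv` (default) selects genes once
on the full dataset, then cross-validates the classifier on that fixed
subset — the common filter-then-evaluate protocol, which is optimistically
biased because test folds influenced the selection. `nested` re-selects
genes inside every training fold and is unbiased; on pure-noise data its
error is demonstrably no lower than `pre_cv`'s (checked by a sign test in
the suite). K-NN results are exactly reproducible from the seed across
platforms; Random Forest reproducibility is per-environment (threading
and library version dependent), which the manifest records.

## Synthetic data

`simulate` draws iid standard-normal noise for n₀+n₁ samples × G genes,
adds `effect` (in noise-SD units) to the first `n_informative` genes in
class 1, optionally exponentiates all draws (log-normal mode, giving
right-skewed marginals), and finally adds `outlier_magnitude` (default
20 SD) to a uniformly chosen fraction of cells. Defaults
(n₀ = n₁ = 20, G = 100, 5 informative genes) give the p ≫ n shape at a
size where a full scoring run takes milliseconds. Contamination targets
random cells rather than whole samples because per-gene robustness is
what distinguishes Md from SNR. Labels are sorted (class 0 first);
stratified CV makes the order irrelevant.

What the generator does *not* emulate: gene–gene correlation, batch
effects, intensity-dependent variance, or realistic microarray
normalization. Passing tests therefore demonstrate correctness of the
statistics and the machinery, and the qualitative robustness/recovery
behaviour — not performance claims on real expression data.

## Calibrated thresholds

Two simulation thresholds were fixed once against large-replicate runs
and then frozen:

- **Recovery:** with effect = 10 SD, all 5 planted genes appear in the Md
  top-5 in ≥ 95 % of 50 seeds (the observed rate is 100 %); mean recovery
  is monotone in effect over {0, 0.5, 1, 2, 4} up to one inversion within
  ±0.05 simulation noise.
- **Outlier ordering:** a single +20 SD outlier in a noise gene leaves
  that gene's Md rank worse than its SNR rank in ≥ 60 % of 50 replicates.
  The long-run rate at the default condition is ≈ 0.70 (1000 replicates):
  the comparison is inherently noisy because the Mood P-value is discrete
  at n = 40 and the inflated SNR also enters Md's numerator, so the
  threshold sits ~3 binomial SDs below the long-run rate.

## Degenerate inputs and numerical conventions

- Datasets must be finite, two-class, ≥ 2 samples per class (n−1 SDs),
  with unique gene and sample identifiers; loaders reject violations with
  the offending row/column named.
- Label values are mapped to {0, 1} in sorted order and the mapping is
  logged.
- All P-values are clipped into (0, 1]; Md's division is additionally
  floored at p_floor.
- Dataset CSV round-trips are exact: floats are written with `%.17g` and
  parsed with round-trip precision.

## Known limitations

Strictly binary classes (no multi-class extension); raw P-values are used
inside Md (no multiple-testing correction — the ranking only needs
relative order); no missing-value handling; no embedded/wrapper selection
methods. The `fetch-uci` CLI command documents candidate sources for the
public benchmark microarray datasets rather than downloading them, since
no stable canonical URLs exist.
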