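# mdselect

Robust filter-based gene selection for two-class, high-dimensional
expression data (bulk microarray/RNA-seq style matrices where genes far
outnumber samples), plus a cross-validated harness to measure how well the
selected genes classify.

## The problem and the statistic

With *p* ≫ *n*, most genes are noise and classifiers degrade unless a
small informative subset is found first. Filter methods score each gene
independently and keep the top *k*. `mdselect` implements four classic
filters and one hybrid:

- **SNR (signal-to-noise, S2N)** — `|μ₀ − μ₁| / (σ₀ + σ₁)`: the gap
  between class means relative to within-class variability. Sensitive to
  outliers, because both means and SDs are.
- **Fisher score** — `Σₖ nₖ(μₖ − μ)² / Σₖ nₖσₖ²`: between-class over
  within-class scatter.
- **Wilcoxon rank-sum** — two-sided Mann–Whitney P-value per gene (exact
  by enumeration for pooled n ≤ 12, tie-corrected normal approximation
  above).
- **Mood's median test** — dichotomize all samples of a gene at the
  pooled grand median, then a 1-df Pearson chi-square on the resulting
  2×2 class-by-side table. Median-based, hence robust to outliers and
  skew.
- **Md (hybrid)** — `Md = SNR / P_mood`: a gene ranks highly only when it
  shows both a large standardized mean gap *and* a median-level group
  difference that a single extreme value cannot fake.

Selected subsets (top 5/10/15/20 by default) are evaluated by average
misclassification rate under Random Forest and K-NN (Euclidean) with
repeated stratified k-fold cross-validation.

## Worked example

```python
from mdselect import SimSpec, simulate, score_all, select_top_k, EvalConfig, cv_error

data, truth = simulate(SimSpec(n0=20, n1=20, n_genes=100,
                               n_informative=5, effect=2.0, seed=42))
table = score_all(data)
top = select_top_k(table, "md", 5)
print("top-5 by Md:", [str(g) for g in top.gene_ids])
print("truly informative:", sorted(str(g) for g in truth))
sub = table.table.loc[table.table.rank_md <= 5, ["gene_id", "snr", "mood_p", "md"]]
print(sub.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
err, sd = cv_error(data, top.gene_ids,
                   EvalConfig(classifier="knn", cv_folds=5, cv_repeats=10, seed=0))
print(f"K-NN CV error on the Md top-5: {err:.3f} +/- {sd:.3f}")
```

prints

```
top-5 by Md: ['g001', 'g004', 'g005', 'g002', 'g003']
truly informative: ['g001', 'g002', 'g003', 'g004', 'g005']
gene_id   snr   mood_p       md
   g001  1.25 1.25e-08 9.99e+07
   g002  1.08 9.55e-06 1.13e+05
   g003 0.969 9.55e-06 1.02e+05
   g004  1.21  4.2e-07 2.88e+06
   g005  1.17 9.55e-06 1.23e+05
K-NN CV error on the Md top-5: 0.000 +/- 0.000
```

All five planted genes (a 2-SD mean shift) are recovered at rank 1–5: each
combines a large SNR with a tiny Mood P-value, so Md separates them from
the 95 noise genes by several orders of magnitude, and the resulting
5-gene K-NN classifier makes no CV errors.

The same pipeline from the shell:

```bash
mdselect simulate --effect 2 --seed 42 --out sim.csv --truth-out truth.txt
mdselect run sim.csv --out-dir results/
```

which writes `scores.csv` (all statistics and ranks), `selections.csv`
plus per-(method, k) gene lists, `errors.csv` (method × k × classifier
mean CV errors), and a `manifest.json` recording the exact configuration.
Real datasets load from delimited text with a header of gene identifiers
and a binary label column (`mdselect run data.csv --label-column class`);
the transposed genes-as-rows dialect is read with
`--orientation genes`.

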