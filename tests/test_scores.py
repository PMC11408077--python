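"""Unit and property tests for the per-gene ranking statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mdselect import (
    ExpressionDataset,
    ScoreConfig,
    class_stats,
    fisher_score,
    md_score,
    mood_median_pvalue,
    score_all,
    snr_score,
    wilcoxon_score,
)

from ._oracles import naive_fisher, naive_mood, naive_snr, naive_wilcoxon_exact
from .conftest import random_dataset


def two_class(vals0, vals1, gene_ids=("g1",)):
    v0 = np.atleast_2d(np.asarray(vals0, dtype=float).T).reshape(len(vals0), -1)
    v1 = np.atleast_2d(np.asarray(vals1, dtype=float).T).reshape(len(vals1), -1)
    values = np.vstack([v0, v1])
    labels = [0] * len(v0) + [1] * len(v1)
    return ExpressionDataset(values=values, labels=labels, gene_ids=list(gene_ids))


class TestClassStats:
    def test_hand_example(self):
        st_ = class_stats(two_class([0, 2], [4, 6]))
        assert st_.mu0[0] == 1 and st_.mu1[0] == 5 and st_.mu[0] == 3
        assert st_.sigma0[0] == pytest.approx(np.sqrt(2), abs=1e-12)
        assert st_.sigma1[0] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_constant_gene(self):
        st_ = class_stats(two_class([7, 7], [7, 7, 7]))
        assert st_.mu0[0] == st_.mu1[0] == st_.mu[0] == 7
        assert st_.sigma0[0] == st_.sigma1[0] == 0

    def test_single_sample_class_rejected(self):
        with pytest.raises(ValueError, match="class 0"):
            two_class([5], [5, 5])

    def test_overall_mean_is_weighted_class_mean(self, rng):
        data = random_dataset(rng)
        st_ = class_stats(data)
        weighted = (st_.n0 * st_.mu0 + st_.n1 * st_.mu1) / (st_.n0 + st_.n1)
        np.testing.assert_allclose(st_.mu, weighted, rtol=1e-9)


class TestSnrFisher:
    def test_snr_hand_example(self):
        st_ = class_stats(two_class([0, 2], [4, 6]))
        assert snr_score(st_)[0] == pytest.approx(4 / (2 * np.sqrt(2)), abs=1e-9)

    def test_snr_zero_for_identical_distributions(self):
        st_ = class_stats(two_class([1, 2, 3], [3, 2, 1]))
        assert snr_score(st_)[0] == 0

    def test_snr_zero_variance_guard(self):
        st_ = class_stats(two_class([3, 3], [9, 9]))
        s = snr_score(st_)[0]
        assert np.isfinite(s) and s == pytest.approx(6 / 1e-12, rel=1e-6)

    def test_fisher_hand_example(self):
        st_ = class_stats(two_class([0, 2], [4, 6]))
        assert fisher_score(st_)[0] == pytest.approx(2.0, abs=1e-9)

    def test_fisher_zero_for_equal_means(self):
        st_ = class_stats(two_class([1, 3], [0, 4]))
        assert fisher_score(st_)[0] == pytest.approx(0.0, abs=1e-12)

    def test_fisher_scale_invariant(self, rng):
        data = random_dataset(rng)
        doubled = ExpressionDataset(
            2 * data.values, data.labels, data.gene_ids, data.sample_ids
        )
        np.testing.assert_allclose(
            fisher_score(class_stats(data)),
            fisher_score(class_stats(doubled)),
            rtol=1e-9,
        )


class TestWilcoxon:
    def test_exact_hand_example(self):
        p = wilcoxon_score(two_class([1, 2, 3], [4, 5, 6]))
        assert p[0] == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        p = wilcoxon_score(two_class([1, 2, 3], [2, 1, 3]))
        assert p[0] == 1.0

    def test_exact_path_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n0 = int(rng.integers(2, 7))
            n1 = int(rng.integers(2, 7))
            x0 = rng.integers(0, 5, size=n0).astype(float)  # integers force ties
            x1 = rng.integers(0, 5, size=n1).astype(float)
            got = wilcoxon_score(two_class(x0, x1))[0]
            assert got == pytest.approx(naive_wilcoxon_exact(x0, x1), abs=1e-9)

    def test_exact_path_matches_scipy_when_tie_free(self, rng):
        for _ in range(20):
            x0 = rng.standard_normal(int(rng.integers(2, 7)))
            x1 = rng.standard_normal(int(rng.integers(2, 7)))
            got = wilcoxon_score(two_class(x0, x1))[0]
            ref = sps.mannwhitneyu(x0, x1, alternative="two-sided", method="exact")
            assert got == pytest.approx(ref.pvalue, abs=1e-9)

    def test_asymptotic_path_in_unit_interval(self, rng):
        values = np.round(rng.standard_normal((30, 10)), 1)
        data = ExpressionDataset(values, [0] * 15 + [1] * 15, [f"g{j}" for j in range(10)])
        p = wilcoxon_score(data)
        assert np.all((p > 0) & (p <= 1))


class TestMood:
    def test_symmetric_classes(self, suite):
        p, t = mood_median_pvalue(suite["sym_mood"].data)
        assert p[0] == 1.0
        assert (t.a[0], t.b[0], t.c[0], t.d[0]) == (2, 2, 2, 2)

    def test_separated_classes_chi_square_ten(self, suite):
        data = suite["mood_sep"].data
        p, t = mood_median_pvalue(data)
        assert (t.a[0], t.b[0], t.c[0], t.d[0]) == (0, 5, 5, 0)
        assert t.grand_median[0] == 8
        assert p[0] == pytest.approx(sps.chi2.sf(10, 1), abs=1e-12)

    def test_constant_gene_degenerate(self):
        p, _ = mood_median_pvalue(two_class([5, 5], [5, 5]))
        assert p[0] == 1.0

    def test_table_margins(self, rng):
        data = random_dataset(rng)
        _, t = mood_median_pvalue(data)
        n0, n1 = data.class_sizes
        assert np.all(t.a + t.c == n0) and np.all(t.b + t.d == n1)

    def test_matches_scipy_median_test(self, rng):
        for _ in range(20):
            data = random_dataset(rng)
            p, _ = mood_median_pvalue(data)
            for j in range(data.n_genes):
                x0 = data.class_values(0)[:, j]
                x1 = data.class_values(1)[:, j]
                try:
                    ref = sps.median_test(x0, x1, ties="below", correction=False)
                except ValueError:  # degenerate pooled table
                    continue
                assert p[j] == pytest.approx(ref.pvalue, abs=1e-9)

    def test_continuity_correction_flag(self):
        data = two_class([1, 2, 3, 4, 5], [11, 12, 13, 14, 15])
        p_plain, _ = mood_median_pvalue(data, continuity=False)
        p_yates, _ = mood_median_pvalue(data, continuity=True)
        assert p_yates[0] > p_plain[0]
        np.testing.assert_allclose(
            p_yates[0], naive_mood(data.values, data.labels, continuity=True)[0]
        )


class TestMd:
    def test_direct_ratio(self):
        assert md_score(np.array([2.0]), np.array([0.05]))[0] == pytest.approx(40.0)

    def test_zero_snr(self):
        assert md_score(np.array([0.0]), np.array([0.3]))[0] == 0.0

    def test_chained_hand_example(self):
        data = two_class([0, 2], [4, 6])
        snr = snr_score(class_stats(data))
        mood_p, _ = mood_median_pvalue(data)
        md = md_score(snr, mood_p)
        assert md[0] == pytest.approx(1.4142135 / 0.04550026, rel=1e-6)

    def test_negative_snr_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            md_score(np.array([-1.0]), np.array([0.5]))

    def test_p_floor(self):
        md = md_score(np.array([1.0]), np.array([1e-320]), p_floor=1e-300)
        assert md[0] == pytest.approx(1e300)

    @settings(max_examples=50, derandomize=True)
    @given(
        snr=st.floats(1e-6, 1e3),
        p1=st.floats(1e-200, 1.0),
        p2=st.floats(1e-200, 1.0),
        bump=st.floats(1e-6, 10.0),
    )
    def test_monotonicity(self, snr, p1, p2, bump):
        """Md increases with snr at fixed P and decreases with P at fixed snr."""
        lo, hi = sorted([p1, p2])
        a = md_score(np.array([snr]), np.array([lo]))[0]
        b = md_score(np.array([snr]), np.array([hi]))[0]
        assert a >= b and (a > b or lo == hi)
        c = md_score(np.array([snr + bump]), np.array([lo]))[0]
        assert c > a


class TestInvariances:
    """Location-shift and positive-scaling invariance of all four statistics."""

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.01, 100),
        seed=st.integers(0, 10_000),
    )
    def test_shift_and_scale(self, shift, scale, seed):
        data = random_dataset(np.random.default_rng(seed))
        transformed = ExpressionDataset(
            data.values * scale + shift, data.labels, data.gene_ids, data.sample_ids
        )
        st_a, st_b = class_stats(data), class_stats(transformed)
        np.testing.assert_allclose(
            snr_score(st_a), snr_score(st_b), rtol=1e-7, atol=1e-9
        )
        np.testing.assert_allclose(
            fisher_score(st_a), fisher_score(st_b), rtol=1e-7, atol=1e-9
        )
        np.testing.assert_allclose(
            wilcoxon_score(data), wilcoxon_score(transformed), atol=1e-9
        )
        np.testing.assert_allclose(
            mood_median_pvalue(data)[0], mood_median_pvalue(transformed)[0], atol=1e-9
        )


class TestScoreAll:
    def test_separable_toy_ranks_first_everywhere(self, suite):
        table = score_all(suite["sep_toy"].data)
        for method in ("md", "snr", "fisher", "wilcoxon"):
            assert table.gene_ids[table.ranks(method) == 1][0] == "g2"

    def test_ranks_are_permutations(self, rng):
        table = score_all(random_dataset(rng))
        g = table.n_genes
        for method in ("md", "snr", "fisher", "wilcoxon"):
            assert sorted(table.ranks(method)) == list(range(1, g + 1))

    def test_column_permutation_equivariance(self, rng):
        data = random_dataset(rng, n_max=16, g_max=10)
        perm = rng.permutation(data.n_genes)
        permuted = ExpressionDataset(
            data.values[:, perm], data.labels, data.gene_ids[perm], data.sample_ids
        )
        t1 = score_all(data).table.set_index("gene_id")
        t2 = score_all(permuted).table.set_index("gene_id")
        for col in ("snr", "fisher", "wilcoxon_p", "mood_p", "md"):
            np.testing.assert_allclose(
                t1[col].loc[t2.index], t2[col], rtol=1e-12, atol=0
            )

    def test_md_column_consistent_with_ratio(self, rng):
        table = score_all(random_dataset(rng)).table
        np.testing.assert_array_equal(
            table["md"], table["snr"] / np.maximum(table["mood_p"], 1e-300)
        )

    def test_shuffled_labels_make_planted_rank_uniform(self):
        """Under label permutation the planted gene's rank is ~uniform on 1..G."""
        rng = np.random.default_rng(77)
        n, g = 20, 10
        values = rng.standard_normal((n, g))
        values[n // 2 :, 0] += 3.0  # planted gene
        ranks = []
        for _ in range(200):
            labels = rng.permutation([0] * (n // 2) + [1] * (n // 2))
            data = ExpressionDataset(values, labels, [f"g{j}" for j in range(g)])
            ranks.append(score_all(data).ranks("md")[0])
        # KS sanity check against the discrete uniform on 1..G
        res = sps.kstest(ranks, sps.randint(1, g + 1).cdf)
        assert res.pvalue > 1e-3

    def test_oracle_equivalence_random_matrices(self):
        """snr/fisher/mood agree with naive reimplementations to 1e-9."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            data = random_dataset(rng)
            st_ = class_stats(data)
            np.testing.assert_allclose(
                snr_score(st_), naive_snr(data.values, data.labels), atol=1e-9
            )
            np.testing.assert_allclose(
                fisher_score(st_), naive_fisher(data.values, data.labels), atol=1e-9
            )
            np.testing.assert_allclose(
                mood_median_pvalue(data)[0],
                naive_mood(data.values, data.labels),
                atol=1e-9,
            )
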