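import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ferroscore import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    InputError,
    bh_adjust,
    gsea_two_group,
    gsva_scores,
    ssgsea_scores,
)


# --- independent brute-force oracles (literal summations, no vectorization) ---

def ssgsea_walk_oracle(values, gene_ids, members, alpha):
    """Literal step-by-step ssGSEA running sum for one sample."""
    n = len(values)
    order = sorted(range(n), key=lambda i: (-values[i], gene_ids[i]))
    rank = {i: n - pos for pos, i in enumerate(order)}
    sum_in = sum(rank[i] ** alpha for i in order if gene_ids[i] in members)
    n_out = sum(1 for i in order if gene_ids[i] not in members)
    es, cin, cout = 0.0, 0.0, 0.0
    for i in order:
        if gene_ids[i] in members:
            cin += rank[i] ** alpha / sum_in
        else:
            cout += 1.0 / n_out
        es += cin - cout
    return es


def gsva_walk_oracle(values, gene_ids, members, tau, max_diff):
    """Literal GSVA walk with the empirical CDF (kcdf='none'), one sample at
    a time, given the full matrix for the cross-sample CDF."""
    n_genes, n_samples = values.shape
    # empirical CDF per gene with average ties
    z = np.empty_like(values, dtype=float)
    for i in range(n_genes):
        for j in range(n_samples):
            less = sum(1 for k in range(n_samples) if values[i, k] < values[i, j])
            ties = sum(1 for k in range(n_samples) if values[i, k] == values[i, j])
            z[i, j] = (less + (ties + 1) / 2.0) / n_samples
    out = np.empty(n_samples)
    for j in range(n_samples):
        order = sorted(range(n_genes), key=lambda i: (-z[i, j], gene_ids[i]))
        rank = {i: pos + 1 for pos, i in enumerate(order)}
        r = {i: abs(n_genes / 2.0 - rank[i]) for i in range(n_genes)}
        sum_in = sum(abs(r[i]) ** tau for i in order if gene_ids[i] in members)
        n_out = sum(1 for i in order if gene_ids[i] not in members)
        walk, cin, cout = [], 0.0, 0.0
        for i in order:
            if gene_ids[i] in members:
                cin += abs(r[i]) ** tau / (sum_in if sum_in > 0 else 1.0)
            else:
                cout += 1.0 / n_out
            walk.append(cin - cout)
        if max_diff:
            out[j] = max(max(walk), 0.0) + min(min(walk), 0.0)
        else:
            out[j] = walk[int(np.argmax(np.abs(walk)))]
    return out


class TestSsgsea:
    def test_five_gene_walk_matches_literal_summation(self, five_gene_expr):
        sets = GeneSetCollection([GeneSet("S", "", frozenset({"g1", "g2"}))])
        sm = ssgsea_scores(five_gene_expr, sets, alpha=0.25, normalize=False)
        expected = ssgsea_walk_oracle(
            [5, 4, 3, 2, 1], ["g1", "g2", "g3", "g4", "g5"], {"g1", "g2"}, 0.25
        )
        assert expected == pytest.approx(2.513942856221443, abs=1e-12)
        assert sm.scores[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_random_fixtures_match_oracle(self):
        rng = np.random.default_rng(7)
        gene_ids = [f"g{i}" for i in range(6)]
        for trial in range(10):
            values = rng.normal(size=(6, 3)).round(2)  # rounding forces ties
            expr = ExpressionMatrix(gene_ids, ["a", "b", "c"], values)
            members = set(rng.choice(gene_ids, size=2, replace=False))
            sets = GeneSetCollection([GeneSet("S", "", frozenset(members))])
            sm = ssgsea_scores(expr, sets, alpha=0.25, normalize=False)
            for j in range(3):
                exp = ssgsea_walk_oracle(values[:, j], gene_ids, members, 0.25)
                assert sm.scores[0, j] == pytest.approx(exp, abs=1e-12)

    def test_rank_identical_samples_score_identically(self, toy_sets):
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(1, 6)],
            ["s1", "s2"],
            np.array([[10.0, 3.0], [8.0, 2.5], [6.0, 2.0], [4.0, 1.5], [2.0, 1.0]]),
        )
        sm = ssgsea_scores(expr, toy_sets, normalize=False)
        np.testing.assert_allclose(sm.scores[:, 0], sm.scores[:, 1], atol=1e-12)

    def test_monotone_transform_invariance(self, toy_sets):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(5, 4))
        gene_ids = [f"g{i}" for i in range(1, 6)]
        expr = ExpressionMatrix(gene_ids, list("abcd"), values)
        warped = ExpressionMatrix(gene_ids, list("abcd"), np.exp(values) * 3 + 1)
        a = ssgsea_scores(expr, toy_sets, normalize=False)
        b = ssgsea_scores(warped, toy_sets, normalize=False)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)

    def test_set_covering_all_genes_rejected(self, tiny_expr):
        sets = GeneSetCollection([GeneSet("all", "", frozenset({"g1", "g2", "g3"}))])
        with pytest.raises(InputError, match="every gene"):
            ssgsea_scores(tiny_expr, sets)

    def test_absent_set_error_names_it(self, tiny_expr):
        sets = GeneSetCollection([GeneSet("ghost", "", frozenset({"zz"}))])
        with pytest.raises(InputError, match="ghost"):
            ssgsea_scores(tiny_expr, sets)

    def test_normalization_divides_by_global_range(self, five_gene_expr, toy_sets):
        raw = ssgsea_scores(five_gene_expr, toy_sets, normalize=False)
        norm = ssgsea_scores(five_gene_expr, toy_sets, normalize=True)
        rng_ = raw.scores.max() - raw.scores.min()
        np.testing.assert_allclose(norm.scores, raw.scores / rng_, atol=1e-12)


class TestGsva:
    def test_six_gene_fixture_matches_bruteforce_walk(self):
        rng = np.random.default_rng(11)
        gene_ids = [f"g{i}" for i in range(6)]
        values = rng.normal(size=(6, 4)).round(2)
        expr = ExpressionMatrix(gene_ids, list("abcd"), values)
        members = {"g0", "g3"}
        sets = GeneSetCollection([GeneSet("S", "", frozenset(members))])
        for max_diff in (True, False):
            sm = gsva_scores(expr, sets, tau=1.0, max_diff=max_diff, kcdf="none")
            exp = gsva_walk_oracle(values, gene_ids, members, 1.0, max_diff)
            np.testing.assert_allclose(sm.scores[0], exp, atol=1e-12)

    def test_upranked_samples_score_positive(self):
        # GSVA scores are relative across samples: a set scores positive in
        # exactly the samples where its genes sit high in their cross-sample
        # CDFs.  Plant a shared increasing trend in the set genes and check
        # the scores track it, positive at the top and negative at the bottom.
        rng = np.random.default_rng(5)
        n_genes, n_samples = 12, 8
        gene_ids = [f"g{i}" for i in range(n_genes)]
        values = rng.normal(size=(n_genes, n_samples))
        trend = np.linspace(-4.0, 4.0, n_samples)
        values[:3] += trend  # g0..g2 rise monotonically across samples
        expr = ExpressionMatrix(gene_ids, [f"s{j}" for j in range(n_samples)], values)
        sets = GeneSetCollection([GeneSet("trend", "", frozenset({"g0", "g1", "g2"}))])
        sm = gsva_scores(expr, sets, kcdf="gaussian")
        assert sm.scores[0, -1] > 0 > sm.scores[0, 0]
        assert stats.spearmanr(sm.scores[0], trend).statistic > 0.8

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        gene_ids = [f"g{i}" for i in range(8)]
        values = rng.normal(size=(8, 5))
        samples = [f"s{j}" for j in range(5)]
        sets = GeneSetCollection([GeneSet("S", "", frozenset({"g1", "g4", "g6"}))])
        perm = [3, 0, 4, 1, 2]
        a = gsva_scores(ExpressionMatrix(gene_ids, samples, values), sets, kcdf="none")
        b = gsva_scores(
            ExpressionMatrix(gene_ids, [samples[p] for p in perm], values[:, perm]),
            sets,
            kcdf="none",
        )
        np.testing.assert_allclose(a.scores[:, perm], b.scores, atol=1e-12)

    def test_too_few_samples_rejected(self, tiny_expr, toy_sets):
        sets = GeneSetCollection([GeneSet("S", "", frozenset({"g1"}))])
        with pytest.raises(InputError, match="4 samples"):
            gsva_scores(tiny_expr, sets)

    def test_poisson_kernel_runs_on_counts(self):
        rng = np.random.default_rng(13)
        values = rng.poisson(5.0, size=(6, 5)).astype(float)
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(6)], [f"s{j}" for j in range(5)], values, "counts"
        )
        sets = GeneSetCollection([GeneSet("S", "", frozenset({"g0", "g1"}))])
        sm = gsva_scores(expr, sets, kcdf="poisson")
        assert np.all(np.isfinite(sm.scores))


class TestGseaTwoGroup:
    @staticmethod
    def _dataset(seed, n=40, n_genes=60, shift_genes=(), shift=0.0):
        rng = np.random.default_rng(seed)
        gene_ids = [f"g{i}" for i in range(n_genes)]
        values = rng.normal(size=(n_genes, n))
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        for g in shift_genes:
            values[gene_ids.index(g), labels == 1] += shift
        expr = ExpressionMatrix(gene_ids, [f"s{j}" for j in range(n)], values)
        return expr, labels, gene_ids

    def test_size_filter_excludes_and_reports(self):
        expr, labels, gene_ids = self._dataset(1)
        sets = GeneSetCollection(
            [
                GeneSet("small9", "", frozenset(gene_ids[:9])),
                GeneSet("ok", "", frozenset(gene_ids[10:25])),
            ]
        )
        results, excluded = gsea_two_group(expr, labels, sets, n_perm=50, seed=0)
        assert [r.set_name for r in results] == ["ok"]
        assert ("small9", 9) in excluded

    def test_no_surviving_set_is_error(self):
        expr, labels, gene_ids = self._dataset(2)
        sets = GeneSetCollection([GeneSet("tiny", "", frozenset(gene_ids[:3]))])
        with pytest.raises(InputError, match="size filter"):
            gsea_two_group(expr, labels, sets, n_perm=10, seed=0)

    def test_planted_upshift_detected(self):
        up = [f"g{i}" for i in range(12)]
        expr, labels, gene_ids = self._dataset(3, n=40, shift_genes=up, shift=2.0)
        sets = GeneSetCollection(
            [
                GeneSet("planted", "", frozenset(up)),
                GeneSet("null1", "", frozenset(gene_ids[20:35])),
                GeneSet("null2", "", frozenset(gene_ids[35:50])),
            ]
        )
        results, _ = gsea_two_group(expr, labels, sets, n_perm=1000, seed=0)
        planted = next(r for r in results if r.set_name == "planted")
        assert planted.es > 0
        assert planted.padj < 0.05

    def test_each_class_needs_three_samples(self):
        expr, _, _ = self._dataset(4, n=40)
        labels = np.array([0] * 2 + [1] * 38)
        sets = GeneSetCollection([GeneSet("S", "", frozenset(expr.gene_ids[:15]))])
        with pytest.raises(InputError, match="3 samples"):
            gsea_two_group(expr, labels, sets, n_perm=10, seed=0)


class TestBHAdjust:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-15
        )

    def test_classic_mixed_example(self):
        # step-up by hand: p*(m/rank), cumulative min from the largest rank
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.04, 0.03, 0.005]),
            [0.02, 0.04, 0.04, 0.02],
            atol=1e-15,
        )

    def test_equal_inputs_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.7]), [0.7])

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_monotone(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)
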