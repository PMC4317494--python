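"""TE computation, moderated t machinery, BH, overlaps, enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from riboseed import (
    ExpressionTruth,
    ShrinkageEstimate,
    adjust_bh,
    call_regulated,
    compute_te,
    enrichment_score,
    fit_shrinkage,
    moderated_t,
    normalize,
    overlap_sets,
    preranked_enrichment,
    simulate_expression_experiment,
    te_test,
)


def paired_matrix(values_tx, values_tl, condition="c"):
    n = len(values_tx[0])
    genes = [f"g{i}" for i in range(n)]
    data = {}
    for r, (tx, tl) in enumerate(zip(values_tx, values_tl), 1):
        data[f"{condition}|transcriptome|r{r}"] = tx
        data[f"{condition}|translatome|r{r}"] = tl
    return pd.DataFrame(data, index=genes)


class TestNormalize:
    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        pd.testing.assert_frame_equal(normalize(m), m)

    def test_shift_removed(self):
        m = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 3, 4]})
        out = normalize(m)
        assert np.allclose(out["a"], out["b"])
        assert np.allclose(out.mean(), out.mean().iloc[0])

    def test_columns_share_sorted_multiset(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(50, 4)))
        out = normalize(m).to_numpy()
        ref_sorted = np.sort(out[:, 0])
        for j in range(1, 4):
            assert np.allclose(np.sort(out[:, j]), ref_sorted)

    def test_non_finite_rejected(self):
        m = pd.DataFrame({"a": [1.0, np.nan]})
        with pytest.raises(ValueError):
            normalize(m)


class TestComputeTE:
    def test_identical_channels_zero(self):
        m = paired_matrix([[5.0, 6]], [[5.0, 6]])
        assert (compute_te(m) == 0).all().all()

    def test_fourfold_is_two(self):
        m = paired_matrix([[5.0, 5]], [[7.0, 7]])
        assert np.allclose(compute_te(m), 2.0)

    def test_unpaired_sample_rejected(self):
        m = pd.DataFrame(
            {"c|transcriptome|r1": [1.0], "c|translatome|r2": [1.0]},
            index=["g0"],
        )
        with pytest.raises(ValueError, match="r1|r2"):
            compute_te(m)

    def test_bad_label_rejected(self):
        m = pd.DataFrame({"weird": [1.0]}, index=["g0"])
        with pytest.raises(ValueError, match="weird"):
            compute_te(m)

    def test_generator_truth_recovered(self):
        effects = {f"gene_{i:05d}": 2.0 for i in range(10)}
        truth = ExpressionTruth(te_effects=effects, n_replicates=4, s0=0.1, d0=20)
        mat, truth_tab = simulate_expression_experiment(truth, 100, 5)
        ti = compute_te(mat)
        err = ti.mean(axis=1) - truth_tab["true_log2_te"]
        assert np.abs(err).max() < 0.6  # ~5 sigma of mean with sd<=0.2-ish


class TestShrinkage:
    def test_equal_variances_give_infinite_d0(self):
        est = fit_shrinkage(np.full(100, 0.3), d=2)
        assert np.isinf(est.d0)
        assert est.s0_sq == pytest.approx(0.3, rel=1e-6)

    def test_recovery_from_generated_variances(self):
        rng = np.random.default_rng(4)
        sg2 = 0.0625 * 4 / rng.chisquare(4, 5000)
        s2 = sg2 * rng.chisquare(1, 5000)
        est = fit_shrinkage(s2, d=1)
        assert est.d0 == pytest.approx(4.0, abs=1.5)
        assert est.s0_sq == pytest.approx(0.0625, rel=0.2)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            fit_shrinkage(np.ones(10), d=1)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_shrinkage(np.zeros(100), d=1)

    def test_posterior_between_prior_and_sample(self):
        est = ShrinkageEstimate(d0=4.0, s0_sq=0.25)
        s2 = np.array([0.01, 0.25, 4.0])
        post = est.moderate(s2, d=1)
        lo = np.minimum(s2, 0.25)
        hi = np.maximum(s2, 0.25)
        assert np.all(post >= lo) and np.all(post <= hi)


class TestModeratedT:
    def test_zero_mean(self):
        t, p = moderated_t([0.0], [0.5], 2, ShrinkageEstimate(4.0, 0.25))
        assert t[0] == 0
        assert p[0] == pytest.approx(1.0)

    def test_infinite_d0_limit(self):
        est = ShrinkageEstimate(d0=np.inf, s0_sq=0.25)
        t, p = moderated_t([1.0], [99.0], 4, est)
        assert t[0] == pytest.approx(1.0 / np.sqrt(0.25 / 4))
        assert p[0] == pytest.approx(2 * stats.norm.sf(t[0]))

    def test_d0_zero_equals_ordinary_t(self):
        """The d0 -> 0 limit reproduces scipy's one-sample t-test."""
        rng = np.random.default_rng(2)
        x = rng.normal(0.3, 1.0, size=(200, 4))
        means = x.mean(axis=1)
        variances = x.var(axis=1, ddof=1)
        t, p = moderated_t(means, variances, 4, ShrinkageEstimate(0.0, 1.0))
        t_ref, p_ref = stats.ttest_1samp(x, 0.0, axis=1)
        assert np.allclose(t, t_ref)
        assert np.allclose(p, p_ref)

    def test_null_p_uniform(self):
        truth = ExpressionTruth(d0=4.0, s0=0.25, n_replicates=2)
        mat, _ = simulate_expression_experiment(truth, 2000, 13)
        ti = compute_te(mat)
        x = ti.to_numpy()
        sh = fit_shrinkage(x.var(axis=1, ddof=1), d=1)
        _, p = moderated_t(x.mean(axis=1), x.var(axis=1, ddof=1), 2, sh)
        assert stats.kstest(p, "uniform").statistic < 0.05


class TestAdjustBH:
    def test_hand_example(self):
        adj = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_all_ones(self):
        assert np.allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_single_unchanged(self):
        assert adjust_bh([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_matches_hand_step_up(self, p):
        """Step-up with running minimum from the largest rank, capped at 1."""
        p = np.asarray(p)
        n = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            adj[i] = running
        assert np.allclose(adjust_bh(p), adj)
        assert np.all(adjust_bh(p) >= p - 1e-12)


class TestCallRegulated:
    def test_up_call(self):
        assert call_regulated([1.2], [0.01])[0] == "up"

    def test_not_significant(self):
        assert call_regulated([1.2], [0.2])[0] == "unchanged"

    def test_down_symmetric(self):
        assert call_regulated([-1.2], [0.01])[0] == "down"

    def test_log2_threshold_variant(self):
        fc = 2**1.5
        assert call_regulated([2.0], [0.01], fc_threshold=fc)[0] == "up"
        assert call_regulated([1.2], [0.01], fc_threshold=fc)[0] == "unchanged"

    def test_boundary_strict(self):
        assert call_regulated([1.0], [0.01])[0] == "unchanged"  # not > 1


class TestOverlap:
    def test_pairwise_example(self):
        out = overlap_sets({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}})
        both = out[(out["A"]) & (out["B"])]["count"].sum()
        assert both == 2
        assert out["count"].sum() == 4

    def test_disjoint(self):
        out = overlap_sets({"A": {"a"}, "B": {"b"}})
        assert out[(out["A"]) & (out["B"])]["count"].sum() == 0

    def test_three_way_inclusion_exclusion(self):
        rng = np.random.default_rng(6)
        universe = [f"g{i}" for i in range(60)]
        sets = {
            name: set(rng.choice(universe, size=rng.integers(5, 30), replace=False))
            for name in "ABC"
        }
        out = overlap_sets(sets)
        assert out["count"].sum() == len(set().union(*sets.values()))
        for name in "ABC":
            assert out[out[name]]["count"].sum() == len(sets[name])

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            overlap_sets({"A": {"a"}})


def brute_force_es(ranked, metric, members):
    """Loop-based running sum; returns (signed max deviation, peak, dip)."""
    n_hit = sum(g in members for g in ranked)
    n_miss = len(ranked) - n_hit
    total_w = sum(abs(m) for g, m in zip(ranked, metric) if g in members)
    running, peak, dip = 0.0, 0.0, 0.0
    for g, m in zip(ranked, metric):
        if g in members:
            running += abs(m) / total_w if total_w else 1.0 / n_hit
        else:
            running -= 1.0 / n_miss
        peak = max(peak, running)
        dip = min(dip, running)
    best = peak if peak >= -dip else dip
    return best, peak, dip


class TestEnrichment:
    def test_top_ranked_single_gene_set(self):
        ranked = [f"g{i}" for i in range(10)]
        metric = np.linspace(5, 0.5, 10)
        assert enrichment_score(ranked, metric, {"g0"}) == pytest.approx(1.0)

    def test_set_covering_all_genes_scores_zero(self):
        ranked = ["a", "b", "c"]
        assert enrichment_score(ranked, np.ones(3), {"a", "b", "c"}) == 0.0

    def test_es_bounded(self):
        rng = np.random.default_rng(1)
        ranked = [f"g{i}" for i in range(30)]
        metric = rng.normal(size=30)
        for _ in range(20):
            members = set(rng.choice(ranked, size=5, replace=False))
            es = enrichment_score(ranked, metric, members)
            assert -1 <= es <= 1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = int(rng.integers(5, 26))
            ranked = [f"g{i}" for i in range(n)]
            metric = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, max(2, n // 2)))
            members = set(rng.choice(ranked, size=k, replace=False))
            got = enrichment_score(ranked, metric, members)
            best, peak, dip = brute_force_es(ranked, metric, members)
            assert abs(got) == pytest.approx(abs(best), abs=1e-9)
            if abs(peak + dip) > 1e-9:  # sign well-defined (no magnitude tie)
                assert got == pytest.approx(best, abs=1e-9)

    def test_preranked_pipeline(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i:03d}" for i in range(200)]
        metric = pd.Series(rng.normal(size=200), index=genes)
        top = set(metric.sort_values(ascending=False).index[:15])
        sets = {
            "top_set": top,
            "random_set": set(rng.choice(genes, size=15, replace=False)),
            "tiny": {"g000"},                      # below min size
            "huge": set(genes) | {"x"},            # above max size (after cap)
        }
        res = preranked_enrichment(
            metric, sets, n_perm=200, min_size=5, max_size=100, seed=0
        )
        assert set(res.table.index) == {"top_set", "random_set"}
        assert res.table.loc["top_set", "es"] > res.table.loc["random_set", "es"]
        assert res.table.loc["top_set", "p"] < 0.05
        assert res.table.loc["top_set", "fdr_q"] < 0.25

    def test_duplicate_gene_rejected(self):
        s = pd.Series([1.0, 2.0], index=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            preranked_enrichment(s, {"x": {"a"}})

    def test_empty_after_size_filter_warns(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.warns(UserWarning):
            res = preranked_enrichment(s, {"x": {"a"}}, min_size=5)
        assert res.table.empty

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(50)]
        metric = pd.Series(rng.normal(size=50), index=genes)
        sets = {"s1": set(genes[:10]), "s2": set(genes[20:30])}
        r1 = preranked_enrichment(metric, sets, n_perm=50, seed=5)
        r2 = preranked_enrichment(metric, sets, n_perm=50, seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)


class TestTeTest:
    def test_spiked_genes_called(self):
        genes = [f"gene_{i:05d}" for i in range(500)]
        effects = {g: 2.0 for g in genes[:25]}
        truth = ExpressionTruth(te_effects=effects, d0=4.0, s0=0.25)
        mat, _ = simulate_expression_experiment(truth, 500, 8)
        res = te_test(compute_te(mat))
        called_up = set(res.index[res["call"] == "up"])
        assert len(called_up & set(genes[:25])) >= 15
        assert res["p_adj"].min() >= res["p"].min()
        assert (res["p_adj"] >= res["p"] - 1e-12).all()

    def test_requires_two_pairs(self):
        ti = pd.DataFrame({"c|r1": [0.1] * 100})
        with pytest.raises(ValueError):
            te_test(ti)
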