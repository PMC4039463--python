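"""Dual-cutoff expression calls, SAM, arm enrichment, clustering, Fisher."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import cnadose as cd
from cnadose.expression import (
    ControlBaseline, call_expression_status, call_matrix, sam_two_class,
    per_arm_deregulation_test, hierarchical_profile_clustering, to_linear,
    _pooled_se,
)
from cnadose.stats import fisher_exact_rxc


class TestCallExpressionStatus:
    @pytest.mark.parametrize("expr,mean,sd,expected", [
        (210, 100, 10, 1),     # both up clauses hold
        (210, 100, 150, 0),    # the SD clause binds
        (100, 100, 10, 0),     # at the control mean
        (40, 100, 10, -1),     # both down clauses hold
        (40, 100, 80, 0),      # SD clause binds on the way down
        (200, 100, 10, 1),     # 2x boundary is inclusive
        (50, 100, 10, -1),     # 0.5x boundary is inclusive
    ])
    def test_dual_cutoff_rule(self, expr, mean, sd, expected):
        assert call_expression_status(expr, mean, sd) == expected

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            call_expression_status(-1.0, 100, 10)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0, 1e6), st.floats(1e-3, 1e6), st.floats(0, 1e6))
    def test_statuses_exclusive_and_exhaustive(self, expr, mean, sd):
        assert call_expression_status(expr, mean, sd) in (-1, 0, 1)

    def test_matrix_call_agrees_with_scalar_rule(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        controls = pd.DataFrame(rng.lognormal(4, 1, (50, 6)), index=genes)
        tumors = pd.DataFrame(rng.lognormal(4, 1.5, (50, 4)), index=genes)
        baseline = ControlBaseline.from_controls(controls)
        calls = call_matrix(tumors, baseline)
        for g in genes[:20]:
            for t in tumors.columns:
                assert calls.loc[g, t] == call_expression_status(
                    tumors.loc[g, t], baseline.mean[g], baseline.sd[g])

    def test_null_cohort_specificity_below_one_percent(self):
        # pure-null synthetic cohort at default noise: false-call rate < 1%
        cfg = cd.CohortConfig(direct_dosage_fraction=0.0,
                              trans_gene_fraction=0.0,
                              marker_spacing=500_000)
        cohort = cd.generate_cohort(cfg, seed=3)
        baseline = ControlBaseline.from_controls(cohort.control_expr)
        calls = call_matrix(cohort.tumor_expr, baseline)
        assert (calls != 0).to_numpy().mean() < 0.01


def planted_matrices(seed, n_genes=300, n_shift=0, shift=2.0, n1=8, n2=8,
                     sd=0.5):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    base = rng.normal(6, 1.5, n_genes)
    ctrl = pd.DataFrame(2.0 ** (base[:, None] + rng.normal(0, sd, (n_genes, n2))),
                        index=genes)
    tum_log = base[:, None] + rng.normal(0, sd, (n_genes, n1))
    tum_log[:n_shift] += shift
    tum = pd.DataFrame(2.0 ** tum_log, index=genes)
    return tum, ctrl, genes


class TestSam:
    def test_null_self_comparison_calls_nothing(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(100)]
        m = pd.DataFrame(rng.lognormal(4, 1, (100, 5)), index=genes)
        res = sam_two_class(m, m.copy(), fdr_target=0.5, n_permutations=50,
                            seed=0)
        assert res.stats["called"].sum() == 0

    def test_exhaustive_enumeration_at_six_per_class(self):
        tum, ctrl, _ = planted_matrices(2, n_genes=60, n_shift=5, n1=6, n2=6)
        res = sam_two_class(tum, ctrl, n_permutations=10, seed=0)
        assert res.exhaustive
        assert res.n_permutations == math.comb(12, 6) == 924
        # independent oracle: enumerate every label assignment directly
        x = np.log2(np.hstack([tum.to_numpy(), ctrl.to_numpy()]))
        oracle = []
        for combo in itertools.combinations(range(12), 6):
            idx1 = np.array(combo)
            idx2 = np.array([i for i in range(12) if i not in combo])
            x1, x2 = x[:, idx1], x[:, idx2]
            diff = x1.mean(axis=1) - x2.mean(axis=1)
            oracle.append(diff / (_pooled_se(x1, x2) + res.s0))
        oracle = np.array(oracle)
        assert np.allclose(np.sort(res.null_d, axis=0),
                           np.sort(oracle, axis=0))

    def test_planted_fourfold_signal_recall_and_fdr(self):
        recalls, fdps, ests = [], [], []
        for seed in range(5):
            tum, ctrl, genes = planted_matrices(100 + seed, n_genes=500,
                                                n_shift=50, n1=10, n2=10)
            res = sam_two_class(tum, ctrl, n_permutations=200, seed=seed)
            called = set(res.called_genes)
            recalls.append(len(called & set(genes[:50])) / 50)
            fdps.append(len(called - set(genes[:50])) / max(1, len(called)))
            ests.append(res.fdr)
        assert np.mean(recalls) >= 0.9
        se = np.std(fdps) / np.sqrt(len(fdps))
        assert np.mean(fdps) <= np.mean(ests) + 2 * se + 1e-12

    def test_zero_variance_equal_means_gene_is_safe(self):
        genes = ["flat", "g1", "g2"]
        rng = np.random.default_rng(3)
        tum = pd.DataFrame(rng.lognormal(4, 1, (3, 4)), index=genes)
        ctrl = pd.DataFrame(rng.lognormal(4, 1, (3, 4)), index=genes)
        tum.loc["flat"] = 16.0
        ctrl.loc["flat"] = 16.0
        res = sam_two_class(tum, ctrl, n_permutations=20, seed=0)
        assert res.stats.loc["flat", "d"] == 0.0
        assert np.isfinite(res.stats["d"]).all()

    def test_d_invariant_under_gene_reordering(self):
        tum, ctrl, genes = planted_matrices(4, n_genes=80, n_shift=10)
        res = sam_two_class(tum, ctrl, n_permutations=30, seed=0)
        perm = np.random.default_rng(0).permutation(genes)
        res2 = sam_two_class(tum.loc[perm], ctrl.loc[perm],
                             n_permutations=30, seed=0)
        pd.testing.assert_series_equal(res.stats["d"].sort_index(),
                                       res2.stats["d"].sort_index())

    def test_fold_change_filter_blocks_small_shifts(self):
        # a strong but sub-1.5-fold shift must not be called
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(200)]
        base = np.full(200, 8.0)
        ctrl = pd.DataFrame(
            2.0 ** (base[:, None] + rng.normal(0, 0.05, (200, 10))),
            index=genes)
        tum_log = base[:, None] + rng.normal(0, 0.05, (200, 10))
        tum_log[:20] += 0.3   # 1.23-fold, strongly significant
        tum = pd.DataFrame(2.0 ** tum_log, index=genes)
        res = sam_two_class(tum, ctrl, fc_min=1.5, n_permutations=100, seed=0)
        assert res.stats["called"].sum() == 0


class TestPerArmEnrichment:
    def test_uniform_rates_flag_nothing(self):
        genes = [f"g{i}" for i in range(400)]
        arm = pd.Series(np.repeat(list("abcd"), 100), index=genes)
        dereg = pd.Series([i % 10 == 0 for i in range(400)], index=genes)
        table = per_arm_deregulation_test(dereg, arm)
        assert not table["enriched"].any()

    def test_strong_arm_enrichment_flagged(self):
        genes = [f"g{i}" for i in range(2000)]
        arm = pd.Series(["hot"] * 1000 + ["rest"] * 1000, index=genes)
        dereg = pd.Series([True] * 160 + [False] * 840
                          + [True] * 95 + [False] * 905, index=genes)
        table = per_arm_deregulation_test(dereg, arm).set_index("arm")
        assert table.loc["hot", "enriched"]
        assert table.loc["hot", "p"] < 0.001

    def test_chi_square_matches_hand_formula(self):
        a, b, c, d = 30, 70, 10, 90
        n = a + b + c + d
        expected_chi2 = n * (a * d - b * c) ** 2 / \
            ((a + b) * (c + d) * (a + c) * (b + d))
        chi2, _, _, _ = sps.chi2_contingency([[a, b], [c, d]],
                                             correction=False)
        assert chi2 == pytest.approx(expected_chi2)


class TestClustering:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(30)]
        blob1 = rng.normal(0, 0.3, (30, 6))
        blob2 = rng.normal(5, 0.3, (30, 5))
        expr = pd.DataFrame(np.hstack([blob1, blob2]), index=genes,
                            columns=[f"s{i}" for i in range(11)])
        res = hierarchical_profile_clustering(expr, k=2)
        labels = res.groups
        assert labels.iloc[:6].nunique() == 1
        assert labels.iloc[6:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_duplicate_sample_merges_first_at_zero_height(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(0, 1, (10, 4)),
                            columns=list("abcd"))
        expr["dup"] = expr["a"]
        res = hierarchical_profile_clustering(expr, k=2)
        assert res.linkage[0, 2] == 0.0
        assert {int(res.linkage[0, 0]), int(res.linkage[0, 1])} == \
            {0, 4}  # columns a and dup

    def test_constant_matrix_degenerates_to_single_cluster(self):
        expr = pd.DataFrame(np.ones((5, 4)), columns=list("abcd"))
        res = hierarchical_profile_clustering(expr, k=3)
        assert res.degenerate
        assert res.groups.nunique() == 1
        assert res.association_p is None

    def test_newick_contains_all_samples(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.normal(0, 1, (6, 5)),
                            columns=[f"s{i}" for i in range(5)])
        res = hierarchical_profile_clustering(expr)
        assert res.newick.endswith(";")
        for s in expr.columns:
            assert s in res.newick


class TestFisherExact:
    def test_matches_hypergeometric_two_sided(self):
        table = [[8, 2], [3, 7]]
        _, p_scipy = sps.fisher_exact(table)
        assert fisher_exact_rxc(table) == pytest.approx(p_scipy, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_2x2_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 12, (2, 2))
        _, p_scipy = sps.fisher_exact(table)
        assert fisher_exact_rxc(table.tolist()) == pytest.approx(
            p_scipy, abs=1e-9)

    def test_2x3_probabilities_sum_to_one_over_enumeration(self):
        # internal consistency: enumerated table probabilities are a pmf
        from cnadose.stats import _enumerate_tables, _log_table_prob
        rows, cols = np.array([5, 7]), np.array([4, 4, 4])
        total = sum(math.exp(_log_table_prob(np.asarray(t)))
                    for t in _enumerate_tables(rows, cols))
        assert total == pytest.approx(1.0)


def test_scale_conversion_round_trip():
    rng = np.random.default_rng(9)
    m = pd.DataFrame(rng.normal(6, 2, (5, 3)))
    linear = to_linear(m, "log2")
    assert np.allclose(np.log2(linear), m)
    assert to_linear(linear, "linear") is linear
    with pytest.raises(ValueError):
        to_linear(m, "ln")
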