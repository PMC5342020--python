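"""Association statistics, instability scores, clustering, and the
exact-test primitives, each against an independent oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cnabreak import (
    RegionSet,
    chi2_2x2,
    cluster_samples,
    compare_groups,
    fisher_exact,
    instability_scores,
    mann_whitney_scores,
    permutation_fdr,
    detect_breakpoints,
)
from cnabreak.cohort_stats import linkage_to_newick, sample_dissimilarity
from conftest import make_panel


def region_set_from_calls(calls: np.ndarray, posteriors: np.ndarray | None = None) -> RegionSet:
    """Wrap a bare region x sample call matrix as a RegionSet (one probe
    per region)."""
    calls = np.asarray(calls, dtype=np.int8)
    R, S = calls.shape
    panel = make_panel(R)
    regions = pd.DataFrame(
        {
            "chrom": "chr1",
            "start_row": np.arange(R),
            "end_row": np.arange(R),
            "start_pos": (np.arange(R) + 1) * 1000,
            "end_pos": (np.arange(R) + 1) * 1000,
            "n_probes": 1,
        }
    )
    if posteriors is None:
        posteriors = np.zeros((R, S, 4))
        idx = (calls.astype(int) + 1).clip(0, 3)
        for c in range(4):
            posteriors[:, :, c] = idx == c
    return RegionSet(panel, [f"s{i}" for i in range(S)], regions, calls, posteriors)


class TestChi2:
    def test_matches_scipy_without_correction(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.integers(0, 30, (2, 2)) + 1
            expected = sps.chi2_contingency(t, correction=False)[0]
            assert chi2_2x2(t) == pytest.approx(expected, abs=1e-10)

    def test_reported_relapse_loss_table(self):
        """The 2x2 table rebuilt from reported carrier frequencies (48/49
        relapsed vs 48/65 relapse-free) gives chi-square ~ 12.2 with
        asymptotic p < 0.001."""
        table = np.array([[48, 48], [1, 17]])
        stat = chi2_2x2(table)
        assert stat == pytest.approx(sps.chi2_contingency(table, correction=False)[0])
        assert 11.5 < stat < 13.0
        assert sps.chi2.sf(stat, 1) < 0.001

    def test_degenerate_margin_zero_statistic(self):
        assert chi2_2x2(np.array([[0, 0], [5, 7]])) == 0.0


class TestCompareGroups:
    def test_identical_groups_null(self):
        calls = np.tile(np.array([[-1] * 5 + [0] * 5]), (3, 1)).astype(np.int8)
        labels = np.array([0, 1] * 5)
        res = compare_groups(region_set_from_calls(calls), labels, n_perm=200, seed=0)
        assert (res["p"] > 0.5).all()
        assert (res["fdr"] > 0.5).all()

    def test_seeded_permutations_reproducible(self):
        rng = np.random.default_rng(5)
        calls = (rng.random((20, 40)) < 0.3).astype(np.int8) * -1
        labels = rng.integers(0, 2, 40)
        rs = region_set_from_calls(calls)
        a = compare_groups(rs, labels, n_perm=500, seed=9)
        b = compare_groups(rs, labels, n_perm=500, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_label_flip_and_region_order_invariance(self):
        rng = np.random.default_rng(6)
        calls = (rng.random((15, 30)) < 0.4).astype(np.int8) * -1
        labels = rng.integers(0, 2, 30)
        rs = region_set_from_calls(calls)
        a = compare_groups(rs, labels, n_perm=300, seed=4)
        b = compare_groups(rs, 1 - labels, n_perm=300, seed=4)
        assert np.allclose(a["stat"], b["stat"])
        perm = rng.permutation(15)
        c = compare_groups(region_set_from_calls(calls[perm]), labels, n_perm=300, seed=4)
        merged = a.set_index("region").loc[perm]["stat"].to_numpy()
        assert np.allclose(merged, c.sort_values("region")["stat"].to_numpy())

    def test_min_freq_filter_excludes_rare_regions(self):
        calls = np.zeros((2, 40), dtype=np.int8)
        calls[0, :2] = -1  # 5% carriers: below the 10% filter
        calls[1, :20] = -1
        res = compare_groups(
            region_set_from_calls(calls), np.array([0, 1] * 20), n_perm=100, seed=0
        )
        assert set(res["region"]) == {1}

    def test_single_group_rejected(self):
        calls = np.zeros((2, 10), dtype=np.int8)
        with pytest.raises(ValueError):
            compare_groups(region_set_from_calls(calls), np.zeros(10), n_perm=10)


class TestPermutationFdr:
    def test_strong_signal_gets_low_fdr(self):
        obs = np.array([50.0, 1.0, 0.5])
        null = np.random.default_rng(0).chisquare(1, (3, 1000))
        fdr = permutation_fdr(obs, null)
        assert fdr[0] < 0.01
        assert fdr[1] > 0.2

    def test_capped_at_one(self):
        obs = np.zeros(5)
        null = np.ones((5, 100))
        assert (permutation_fdr(obs, null) == 1.0).all()


class TestInstabilityScores:
    def test_all_neutral_sample_scores_zero(self, small_callset):
        import copy

        cs = copy.deepcopy(small_callset)
        cs.states[:, 0] = 0
        scores = instability_scores(cs)
        assert scores.iloc[0]["cna_score"] == 0

    def test_constructed_loss_segment_counts(self):
        """A single interior 100-probe loss contributes cna_score 100 and
        bp_score 2 (both ends)."""
        from cnabreak import CallSet, Segment, SegmentedCohort

        panel = make_panel(300)
        states = np.zeros((300, 1), dtype=np.int8)
        states[100:200, 0] = -1
        posts = np.zeros((300, 1, 4))
        cs = CallSet(panel, ["s0"], states, posts)
        segs = [
            [
                Segment("chr1", 0, 99, 0.0),
                Segment("chr1", 100, 199, -0.6),
                Segment("chr1", 200, 299, 0.0),
            ]
        ]
        seg = SegmentedCohort(panel, ["s0"], segs, np.array([0.1]))
        bpset = detect_breakpoints(seg)
        scores = instability_scores(cs, bpset)
        assert scores.iloc[0]["cna_score"] == 100
        assert scores.iloc[0]["bp_score"] == 2

    def test_mutation_coupled_instability_recovered(self):
        """Samples mutated in a gene that adds extra CNA segments show
        higher CNA-scores (Mann-Whitney) with good power at n = 60."""
        import sys

        sys.path.insert(0, "tests")
        from conftest import small_config
        from cnabreak import (
            MutationModel,
            call_states,
            fit_call_mixture,
            segment_cohort,
            simulate_cohort,
        )

        hits = 0
        n_rep = 5
        for seed in range(n_rep):
            cfg = small_config(
                seed=200 + seed,
                n_samples=60,
                mutation_models={"APC": MutationModel(0.5, extra_segments=3)},
            )
            cohort, _, mut, truth = simulate_cohort(cfg)
            cs = call_states(
                seg := segment_cohort(cohort, seed=seed), fit_call_mixture(seg)
            )
            scores = instability_scores(cs)["cna_score"].to_numpy()
            labels = mut["APC"].to_numpy()
            _, p = mann_whitney_scores(scores, labels)
            med_mut = np.median(scores[labels == 1])
            med_wt = np.median(scores[labels == 0])
            hits += (p < 0.05) and (med_mut > med_wt)
        assert hits >= 0.8 * n_rep


class TestMannWhitney:
    def test_enumeration_oracle_separated_groups(self):
        """{1,2,3} vs {4,5,6}: U = 0 and exact two-sided p = 2/20."""
        scores = np.array([1, 2, 3, 4, 5, 6], float)
        labels = np.array([0, 0, 0, 1, 1, 1])
        u, p = mann_whitney_scores(scores, labels)
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_all_tied_p_one(self):
        u, p = mann_whitney_scores(np.ones(10), np.array([0] * 5 + [1] * 5))
        assert p == 1.0

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(0, 1, 30)
        labels = rng.integers(0, 2, 30)
        _, p1 = mann_whitney_scores(scores, labels)
        _, p2 = mann_whitney_scores(scores, 1 - labels)
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestClusterSamples:
    def test_duplicated_sample_merged_first(self):
        rng = np.random.default_rng(1)
        posts = rng.dirichlet(np.ones(4), size=(30, 5))
        posts[:, 1, :] = posts[:, 0, :]  # sample 1 duplicates sample 0
        rs = region_set_from_calls(np.zeros((30, 5), dtype=np.int8), posts)
        Z, labels, D = cluster_samples(rs)
        assert D[0, 1] == 0.0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == 0.0

    def test_two_archetypes_recovered(self):
        """Samples drawn from two distinct call archetypes separate into
        the correct 2-cluster cut (Rand index > 0.9)."""
        rng = np.random.default_rng(3)
        R, S = 60, 20
        base_a = rng.integers(-1, 2, R)
        base_b = rng.integers(-1, 2, R)
        truth = np.array([0] * 10 + [1] * 10)
        posts = np.zeros((R, S, 4))
        for s in range(S):
            calls = np.where(rng.random(R) < 0.9, base_a if truth[s] == 0 else base_b,
                             rng.integers(-1, 2, R))
            idx = (calls + 1).clip(0, 3)
            for c in range(4):
                posts[:, s, c] = 0.9 * (idx == c) + 0.025
        rs = region_set_from_calls(np.zeros((R, S), dtype=np.int8), posts)
        _, labels, _ = cluster_samples(rs, n_clusters=2)
        same_truth = truth[:, None] == truth[None, :]
        same_pred = labels[:, None] == labels[None, :]
        iu = np.triu_indices(S, 1)
        rand = (same_truth[iu] == same_pred[iu]).mean()
        assert rand > 0.9

    def test_dissimilarity_is_a_metric(self):
        rng = np.random.default_rng(4)
        posts = rng.dirichlet(np.ones(4), size=(25, 6))
        D = sample_dissimilarity(posts)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12

    def test_single_sample_rejected(self):
        rs = region_set_from_calls(np.zeros((5, 1), dtype=np.int8))
        with pytest.raises(ValueError):
            cluster_samples(rs)

    def test_newick_export_contains_all_samples(self):
        rng = np.random.default_rng(5)
        posts = rng.dirichlet(np.ones(4), size=(20, 6))
        rs = region_set_from_calls(np.zeros((20, 6), dtype=np.int8), posts)
        Z, _, _ = cluster_samples(rs)
        nwk = linkage_to_newick(Z, rs.samples)
        assert nwk.endswith(";")
        for name in rs.samples:
            assert name in nwk


class TestFisherExact:
    def test_perfect_association_matches_enumeration(self):
        """[[10,0],[0,10]]: two-sided p = 2 / C(20,10)."""
        _, p, flag = fisher_exact(np.array([[10, 0], [0, 10]]))
        assert not flag
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_independence_p_one(self):
        odds, p, _ = fisher_exact(np.array([[5, 5], [5, 5]]))
        assert p == 1.0 and odds == 1.0

    def test_transpose_invariance(self):
        t = np.array([[12, 3], [5, 9]])
        assert fisher_exact(t)[1] == pytest.approx(fisher_exact(t.T)[1], rel=1e-12)

    def test_zero_margin_flagged(self):
        odds, p, flag = fisher_exact(np.array([[0, 0], [3, 4]]))
        assert flag and p == 1.0

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(np.array([[0.5, 1], [1, 1]]))
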