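"""Breakpoint detection, the binomial recurrence null, gene mapping with
pooling, and the discrete FDR correction."""

import math

import numpy as np
import pandas as pd
import pytest

from cnabreak import (
    BreakpointSet,
    GeneModel,
    Segment,
    SegmentedCohort,
    detect_breakpoints,
    filter_enrichment,
    map_genes,
)
from cnabreak import test_breakpoint_locations as probe_recurrence_test
from cnabreak import test_recurrent_genes as gene_recurrence_test
from statsmodels.stats.multitest import multipletests
from conftest import make_panel, make_multi_panel


def _segmented(panel, per_sample_segments):
    n = len(per_sample_segments)
    return SegmentedCohort(
        panel, [f"s{i}" for i in range(n)], per_sample_segments, np.full(n, 0.1)
    )


def _bpset_from_flags(panel, flags):
    flags = np.asarray(flags, bool)
    counts = flags.sum(axis=1)
    rate = flags.sum() / flags.size
    return BreakpointSet(panel, [f"s{i}" for i in range(flags.shape[1])], flags, counts, rate)


def binom_tail_oracle(k: int, n: int, p: float) -> float:
    """Brute-force P(X >= k) by direct summation."""
    return sum(math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


class TestDetectBreakpoints:
    def test_single_genomewide_segment_no_breakpoints(self):
        panel = make_multi_panel(50, 2)
        segs = [[Segment("chr1", 0, 49, 0.0), Segment("chr2", 50, 99, 0.0)]]
        bpset = detect_breakpoints(_segmented(panel, segs))
        assert bpset.flags.sum() == 0 and bpset.rate == 0.0

    def test_boundary_flagged_at_first_probe_of_new_segment(self):
        panel = make_panel(100)
        segs = [[Segment("chr1", 0, 49, 0.0), Segment("chr1", 50, 99, 1.0)]]
        bpset = detect_breakpoints(_segmented(panel, segs))
        assert np.flatnonzero(bpset.flags[:, 0]).tolist() == [50]

    def test_chromosome_start_never_flagged(self, small_segmented):
        bpset = detect_breakpoints(small_segmented)
        for _, lo, _ in small_segmented.panel.chrom_bounds():
            assert bpset.counts[lo] == 0

    def test_flags_match_generator_truth_for_true_segments(self, small_bundle):
        """Detection applied to the true segments recovers exactly the
        true breakpoints."""
        cohort, _, _, truth = small_bundle
        seg = _segmented(cohort.panel, truth.segments)
        seg.samples = list(cohort.samples)
        bpset = detect_breakpoints(seg)
        for s in range(cohort.n_samples):
            assert np.array_equal(np.flatnonzero(bpset.flags[:, s]), truth.breakpoints[s])

    def test_per_sample_score_identity(self, small_segmented):
        """Sum of per-probe counts equals sum of per-sample BP-scores
        equals sum over samples of (segments per chromosome - 1)."""
        bpset = detect_breakpoints(small_segmented)
        assert bpset.counts.sum() == bpset.sample_bp_scores().sum()
        expected = 0
        for segs in small_segmented.segments:
            per_chrom = {}
            for seg in segs:
                per_chrom[seg.chrom] = per_chrom.get(seg.chrom, 0) + 1
            expected += sum(v - 1 for v in per_chrom.values())
        assert bpset.flags.sum() == expected

    def test_enrichment_probes_must_be_filtered(self):
        panel = make_panel(10)
        panel.probes.loc[3, "is_enrichment"] = True
        segs = [[Segment("chr1", 0, 9, 0.0)]]
        with pytest.raises(ValueError, match="enrichment"):
            detect_breakpoints(_segmented(panel, segs))

    def test_filter_enrichment_drops_probes(self, small_cohort):
        panel = small_cohort.panel.probes.copy()
        panel.loc[[5, 10], "is_enrichment"] = True
        from cnabreak.core import CopyNumberCohort, ProbePanel

        cohort = CopyNumberCohort(ProbePanel(panel), small_cohort.samples, small_cohort.ratios)
        filtered = filter_enrichment(cohort)
        assert filtered.panel.n_probes == small_cohort.panel.n_probes - 2
        assert not filtered.panel.probes["is_enrichment"].any()


class TestBreakpointLocationTest:
    def test_zero_count_probe_has_p_one(self):
        panel = make_panel(50)
        flags = np.zeros((50, 10), bool)
        flags[7, :3] = True
        table = probe_recurrence_test(_bpset_from_flags(panel, flags))
        assert table.loc[0, "p"] == 1.0

    def test_binomial_tail_matches_brute_force(self):
        panel = make_panel(1000)
        flags = np.zeros((1000, 100), bool)
        flags[5, :5] = True  # 5 of 100 samples at one probe
        # scatter singletons so the rate is r = 0.001
        extra = 100 * 1000 // 1000 - 5
        rows = np.arange(10, 10 + extra)
        flags[rows, 0] = True
        bpset = _bpset_from_flags(panel, flags)
        assert bpset.rate == pytest.approx(0.001)
        table = probe_recurrence_test(bpset)
        expected = binom_tail_oracle(5, 100, 0.001)
        assert table.loc[5, "p"] == pytest.approx(expected, abs=1e-12)

    def test_no_breakpoints_all_p_one(self):
        panel = make_panel(20)
        table = probe_recurrence_test(_bpset_from_flags(panel, np.zeros((20, 5), bool)))
        assert (table["p"] == 1.0).all() and not table["significant"].any()

    def test_uniform_null_yields_no_recurrent_probes(self):
        """Uniformly random breakpoints produce ~no probes at FDR < 0.1."""
        rng = np.random.default_rng(8)
        panel = make_panel(500)
        sig_fraction = []
        for _ in range(50):
            flags = rng.random((500, 60)) < 0.005
            table = probe_recurrence_test(_bpset_from_flags(panel, flags))
            sig_fraction.append(table["significant"].mean())
        assert np.mean(sig_fraction) < 0.005


class TestMapGenes:
    def _bpset(self):
        panel = make_panel(100)
        flags = np.zeros((100, 10), bool)
        flags[51, :3] = True
        return _bpset_from_flags(panel, flags)

    def test_frequency_counting(self):
        genes = [GeneModel("G1", "chr1", 51_500, 52_500)]  # covers probe row 51
        table = map_genes(self._bpset(), genes)
        assert table.loc[0, "n_probes"] == 1
        assert table.loc[0, "frequency"] == pytest.approx(0.3)

    def test_identical_probe_sets_pooled(self):
        genes = [
            GeneModel("B", "chr1", 51_900, 52_100),
            GeneModel("A", "chr1", 51_800, 52_200),
        ]
        table = map_genes(self._bpset(), genes)
        assert len(table) == 1
        assert table.loc[0, "pool_name"] == "A*"
        assert table.loc[0, "member_genes"] == "A,B"

    def test_gene_without_probes_excluded(self):
        genes = [GeneModel("EMPTY", "chr1", 51_100, 51_200)]
        assert len(map_genes(self._bpset(), genes)) == 0

    def test_gene_on_silent_chromosome_has_zero_frequency(self):
        panel = make_multi_panel(50, 2)
        flags = np.zeros((100, 10), bool)
        flags[20, :4] = True  # chr1 only
        genes = [GeneModel("QUIET", "chr2", 10_000, 20_000)]
        table = map_genes(_bpset_from_flags(panel, flags), genes)
        assert table.loc[0, "frequency"] == 0.0

    def test_pooling_is_a_partition(self, small_segmented):
        bpset = detect_breakpoints(small_segmented)
        pos = bpset.panel.positions()
        genes = [
            GeneModel(f"G{i}", chrom, int(pos[lo] + i * 997 % 50_000), int(pos[lo] + i * 997 % 50_000) + 30_000)
            for i, (chrom, lo, hi) in enumerate(bpset.panel.chrom_bounds() * 10)
        ]
        # make names unique
        genes = [GeneModel(f"G{i}", g.chrom, g.start, g.end) for i, g in enumerate(genes)]
        table = map_genes(bpset, genes)
        members = [m for row in table["member_genes"] for m in row.split(",")]
        assert len(members) == len(set(members))


class TestRecurrentGenes:
    def _table_and_bpset(self, m_g=5, k_g=4, n=100, rate=0.002):
        panel = make_panel(2000)
        flags = np.zeros((2000, n), bool)
        # background to fix the rate
        total = int(rate * 2000 * n)
        rng = np.random.default_rng(0)
        idx = rng.choice(2000 * n, size=total, replace=False)
        flags[np.unravel_index(idx, flags.shape)] = True
        bpset = _bpset_from_flags(panel, flags)
        table = pd.DataFrame(
            [
                {
                    "pool_name": "G",
                    "member_genes": "G",
                    "chrom": "chr1",
                    "n_probes": m_g,
                    "probe_rows": list(range(m_g)),
                    "n_affected": k_g,
                    "frequency": k_g / n,
                    "affected": np.zeros(n, bool),
                }
            ]
        )
        return table, bpset

    def test_unaffected_gene_never_significant(self):
        table, bpset = self._table_and_bpset(k_g=0)
        out = gene_recurrence_test(table, bpset)
        assert out.loc[0, "p"] == 1.0 and not out.loc[0, "significant"]

    def test_gene_p_matches_brute_force_binomial(self):
        table, bpset = self._table_and_bpset(m_g=5, k_g=4, n=100)
        out = gene_recurrence_test(table, bpset)
        q = 1 - (1 - bpset.rate) ** 5
        assert out.loc[0, "null_prob"] == pytest.approx(q, abs=1e-15)
        assert out.loc[0, "p"] == pytest.approx(binom_tail_oracle(4, 100, q), abs=1e-12)

    def test_discrete_correction_dominates_plain_bh(self):
        """The min-attainable-p exclusion never flags fewer genes than
        plain BH on the same discrete p-values."""
        rng = np.random.default_rng(3)
        for rep in range(25):
            n = 40
            G = 60
            panel = make_panel(500)
            flags = rng.random((500, n)) < rng.uniform(0.001, 0.01)
            bpset = _bpset_from_flags(panel, flags)
            m = rng.integers(1, 8, G)
            k = rng.binomial(n, 0.08, G)
            table = pd.DataFrame(
                {
                    "pool_name": [f"G{i}" for i in range(G)],
                    "member_genes": [f"G{i}" for i in range(G)],
                    "chrom": "chr1",
                    "n_probes": m,
                    "probe_rows": [[0]] * G,
                    "n_affected": k,
                    "frequency": k / n,
                    "affected": [np.zeros(n, bool)] * G,
                }
            )
            out = gene_recurrence_test(table, bpset, fdr_cut=0.1)
            plain = multipletests(out["p"].to_numpy(), method="fdr_bh")[1] < 0.1
            assert out["significant"].to_numpy()[plain].all()
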