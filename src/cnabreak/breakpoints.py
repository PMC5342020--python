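"""CNA-associated breakpoint detection and recurrent breakpoint genes.

A breakpoint is the genomic address where a sample's copy-number state
changes: here, the first probe of every segment except each chromosome's
first segment. Probes added to the array to enrich cancer-gene loci are
excluded beforehand so the genome-wide probe spacing — and hence the
random-breakage null — is even.

Cohort-level non-randomness is tested per probe against a binomial null
with the genome-wide per-probe breakpoint rate, with Benjamini-Hochberg
FDR control. Breakpoints are then mapped to gene footprints; genes whose
associated probe sets are identical are pooled (their frequency is the
cumulative frequency over pooled members), and recurrent breakpoint
genes are identified with a discrete Benjamini-Hochberg-type correction
that first excludes genes whose minimum attainable p-value (every sample
affected) already exceeds the significance threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import BreakpointSet, GeneModel, ProbePanel, SegmentedCohort

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.1


def filter_enrichment(panel_or_cohort):
    """Drop enrichment probes (returns same type restricted to even-spaced
    backbone probes)."""
    if isinstance(panel_or_cohort, ProbePanel):
        return panel_or_cohort.subset(~panel_or_cohort.probes["is_enrichment"].to_numpy())
    return panel_or_cohort.subset_probes(
        ~panel_or_cohort.panel.probes["is_enrichment"].to_numpy()
    )


def detect_breakpoints(segmented: SegmentedCohort) -> BreakpointSet:
    """Flag, per sample, the first probe of every segment except each
    chromosome's first; compute per-probe cohort counts and the
    genome-wide rate r = total breakpoints / (probes x samples).

    The segmented cohort must already be on the enrichment-filtered
    panel (re-segmenting after the filter, not just masking probes).
    """
    panel = segmented.panel
    if panel.probes["is_enrichment"].any():
        raise ValueError(
            "panel still contains enrichment probes; apply filter_enrichment "
            "and re-segment before breakpoint detection"
        )
    P, S = panel.n_probes, len(segmented.samples)
    chrom_first = {lo for _, lo, _ in panel.chrom_bounds()}
    flags = np.zeros((P, S), dtype=bool)
    for s, segs in enumerate(segmented.segments):
        for seg in segs:
            if seg.start not in chrom_first:
                flags[seg.start, s] = True
    counts = flags.sum(axis=1)
    rate = float(flags.sum()) / (P * S)
    return BreakpointSet(panel, list(segmented.samples), flags, counts, rate)


def breakpoint_set_from_indices(
    panel: ProbePanel, samples: list[str], indices_per_sample: list[np.ndarray]
) -> BreakpointSet:
    """Assemble a BreakpointSet from known per-sample breakpoint probe
    rows (e.g. a generator's ground truth), bypassing segmentation."""
    P = panel.n_probes
    flags = np.zeros((P, len(samples)), dtype=bool)
    for s, rows in enumerate(indices_per_sample):
        flags[np.asarray(rows, dtype=int), s] = True
    counts = flags.sum(axis=1)
    rate = float(flags.sum()) / (P * len(samples)) if flags.size else 0.0
    return BreakpointSet(panel, list(samples), flags, counts, rate)


def test_breakpoint_locations(bpset: BreakpointSet, fdr_cut: float = DEFAULT_FDR) -> pd.DataFrame:
    """Per-probe binomial tail p-values and BH-FDR for breakpoint
    recurrence; significant at FDR < ``fdr_cut``."""
    S = len(bpset.samples)
    if bpset.rate == 0:
        p = np.ones(bpset.panel.n_probes)
    else:
        p = stats.binom.sf(bpset.counts - 1, S, bpset.rate)
    fdr = multipletests(p, method="fdr_bh")[1]
    out = bpset.panel.probes[["probe_id", "chrom", "pos"]].copy()
    out["count"] = bpset.counts
    out["p"] = p
    out["fdr"] = fdr
    out["significant"] = fdr < fdr_cut
    return out


def map_genes(
    bpset: BreakpointSet, genes: list[GeneModel]
) -> pd.DataFrame:
    """Map breakpoints to gene footprints.

    A gene's associated probes are the panel probes lying inside
    [start, end] on its chromosome; a gene is affected in a sample iff at
    least one associated probe carries a breakpoint flag. Genes with
    identical probe sets are pooled into one entry (affected samples =
    union over members, which for identical probe sets is each member's
    own set). Genes covering no probe are excluded and logged.

    Returns one row per (pooled) gene: pool_name, member_genes, n_probes,
    probe_rows, n_affected, frequency, affected (bool vector).
    """
    probes = bpset.panel.probes
    S = len(bpset.samples)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, lo, hi in bpset.panel.chrom_bounds():
        by_chrom[chrom] = (probes["pos"].to_numpy()[lo:hi], np.arange(lo, hi))
    pools: dict[tuple[int, ...], list[str]] = {}
    for gene in genes:
        if gene.chrom not in by_chrom:
            logger.info("gene %s on chromosome without probes; excluded", gene.gene_name)
            continue
        pos, rows = by_chrom[gene.chrom]
        i = np.searchsorted(pos, gene.start, side="left")
        j = np.searchsorted(pos, gene.end, side="right")
        if i == j:
            logger.info("gene %s covers no probes; excluded", gene.gene_name)
            continue
        pools.setdefault(tuple(rows[i:j]), []).append(gene.gene_name)
    rows_out = []
    for probe_rows, members in pools.items():
        members = sorted(members)
        affected = bpset.flags[list(probe_rows)].any(axis=0)
        name = members[0] + ("*" if len(members) > 1 else "")
        rows_out.append(
            {
                "pool_name": name,
                "member_genes": ",".join(members),
                "chrom": probes["chrom"].iloc[probe_rows[0]],
                "n_probes": len(probe_rows),
                "probe_rows": list(probe_rows),
                "n_affected": int(affected.sum()),
                "frequency": affected.sum() / S,
                "affected": affected,
            }
        )
    table = pd.DataFrame(rows_out)
    if len(table):
        table = table.sort_values(
            ["n_affected", "pool_name"], ascending=[False, True]
        ).reset_index(drop=True)
    return table


def test_recurrent_genes(
    gene_table: pd.DataFrame,
    bpset: BreakpointSet,
    fdr_cut: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Discrete-FDR test for recurrent breakpoint genes.

    Null model: with genome-wide per-probe breakpoint rate r, a gene
    covered by m probes is affected in one sample with probability
    q = 1 - (1-r)^m; the number of affected samples is Binomial(S, q),
    giving a right-tail p-value. Because these p-values are discrete,
    plain BH over all genes wastes power on genes that could never be
    significant; genes whose minimum attainable p (all S samples
    affected, q^S) exceeds the threshold are excluded before BH is
    applied to the remainder.
    """
    out = gene_table.copy()
    S = len(bpset.samples)
    r = bpset.rate
    m = out["n_probes"].to_numpy(float)
    k = out["n_affected"].to_numpy(int)
    q = 1.0 - (1.0 - r) ** m
    p = stats.binom.sf(k - 1, S, q)
    p_min = np.power(q, S)  # attained when every sample is affected
    eligible = p_min <= fdr_cut
    fdr = np.ones(len(out))
    if eligible.any():
        fdr[eligible] = multipletests(p[eligible], method="fdr_bh")[1]
    out["null_prob"] = q
    out["p"] = p
    out["p_min"] = p_min
    out["eligible"] = eligible
    out["fdr"] = fdr
    out["significant"] = eligible & (fdr < fdr_cut)
    return out
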