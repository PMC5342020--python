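"""Gene mutation matrix construction and mutation-driven analyses.

Variant records become a binary sample x gene mutation matrix under the
panel-sequencing calling rule: a gene is mutated in a sample iff at
least one record has variant allele fraction >= 0.20, is not synonymous,
and is not a known polymorphism. Pathway columns (e.g. the MAPK pathway
KRAS/NRAS/BRAF, which carry near-mutually-exclusive activating
mutations in colorectal cancer) are logical ORs over member genes and
are always recomputed, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_stats import fisher_exact

VAF_THRESHOLD = 0.20  # strict >= ("at least 20% of the reads")

DEFAULT_PATHWAYS: dict[str, tuple[str, ...]] = {
    "MAPK": ("KRAS", "NRAS", "BRAF"),
    "APC_or_MAPK": ("APC", "KRAS", "NRAS", "BRAF"),
}


@dataclass(frozen=True)
class VariantRecord:
    sample_id: str
    gene: str
    vaf: float
    consequence: str  # 'synonymous' | 'non_synonymous'
    known_polymorphism: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        if self.consequence not in ("synonymous", "non_synonymous"):
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def passes(self) -> bool:
        return (
            self.vaf >= VAF_THRESHOLD
            and self.consequence == "non_synonymous"
            and not self.known_polymorphism
        )


def call_mutations(
    records: Iterable[VariantRecord],
    samples: Sequence[str],
    genes: Sequence[str],
) -> pd.DataFrame:
    """Binary mutation matrix; samples with no (passing) records get
    all-zero rows. Idempotent and order-independent over records."""
    known = set(samples)
    matrix = pd.DataFrame(
        0, index=pd.Index(list(samples), name="sample_id"), columns=list(genes), dtype=np.int8
    )
    for rec in records:
        if rec.sample_id not in known:
            raise ValueError(f"unknown sample id {rec.sample_id!r}")
        if rec.gene in matrix.columns and rec.passes:
            matrix.loc[rec.sample_id, rec.gene] = 1
    return matrix


def pathway_combine(
    matrix: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Add logical-OR pathway columns; idempotent (recomputes existing
    derived columns from their members)."""
    gene_sets = dict(DEFAULT_PATHWAYS if gene_sets is None else gene_sets)
    out = matrix.copy()
    for name, members in gene_sets.items():
        if len(members) == 0:
            raise ValueError(f"empty gene set {name!r}")
        missing = [g for g in members if g not in matrix.columns]
        if missing:
            raise ValueError(f"gene set {name!r} references unknown genes {missing}")
        out[name] = matrix[list(members)].any(axis=1).astype(np.int8)
    return out


def cooccurrence_tests(
    matrix: pd.DataFrame, gene_pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Fisher exact co-occurrence / mutual-exclusivity tests per gene pair.

    direction is 'co-occurring' for OR > 1, 'exclusive' for OR < 1.
    ``odds_ratio_display`` applies a 0.5 continuity adjustment when a
    cell is zero so exclusive pairs remain plottable on a log scale.
    """
    rows = []
    for g1, g2 in gene_pairs:
        for g in (g1, g2):
            if g not in matrix.columns:
                raise ValueError(f"gene {g!r} not in matrix")
        a = matrix[g1].astype(bool)
        b = matrix[g2].astype(bool)
        table = np.array(
            [[(a & b).sum(), (a & ~b).sum()], [(~a & b).sum(), (~a & ~b).sum()]]
        )
        odds, p, degenerate = fisher_exact(table)
        tc = table + 0.5
        odds_disp = float(tc[0, 0] * tc[1, 1] / (tc[0, 1] * tc[1, 0])) if (table == 0).any() else odds
        if degenerate or odds == 1.0:
            direction = "none"
        else:
            direction = "co-occurring" if odds > 1 else "exclusive"
        rows.append(
            {
                "gene1": g1,
                "gene2": g2,
                "n11": int(table[0, 0]),
                "n10": int(table[0, 1]),
                "n01": int(table[1, 0]),
                "n00": int(table[1, 1]),
                "odds_ratio": odds,
                "odds_ratio_display": odds_disp,
                "p": p,
                "direction": direction,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def oncoprint_export(matrix: pd.DataFrame) -> pd.DataFrame:
    """Canonical gene x sample 0/1 matrix for oncoprint-style display:
    genes ordered by mutation frequency (desc, then name), samples by
    mutation burden (desc, then id). Input sample order is irrelevant."""
    if matrix.size == 0:
        raise ValueError("empty mutation matrix")
    m = matrix.astype(int)
    gene_order = sorted(m.columns, key=lambda g: (-int(m[g].sum()), g))
    sample_order = sorted(m.index, key=lambda s: (-int(m.loc[s].sum()), s))
    return m.loc[sample_order, gene_order].T
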