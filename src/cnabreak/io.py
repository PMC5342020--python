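"""On-disk formats for every pipeline artifact.

All tabular artifacts are TSV with headers; genomic intervals exchanged
as BED are converted between BED's 0-based half-open convention and the
internal 1-based inclusive convention at this boundary. Segments are
written in the standard SEG dialect (sample, chrom, loc.start, loc.end,
num.mark, seg.mean). Readers validate rather than silently coerce;
every writer produces files its paired reader accepts unchanged.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    ClinicalTable,
    CopyNumberCohort,
    GeneModel,
    ProbePanel,
    Segment,
    SegmentedCohort,
)
from .mutations import VariantRecord

SEG_COLUMNS = ["sample", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


# ---------------------------------------------------------------- probe panel

def write_probe_panel(panel: ProbePanel, path: str | Path) -> None:
    df = panel.probes.copy()
    df["is_enrichment"] = df["is_enrichment"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_probe_panel(path: str | Path) -> ProbePanel:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    required = {"probe_id", "chrom", "pos", "is_enrichment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"probe panel {path}: missing columns {sorted(missing)}")
    df["is_enrichment"] = df["is_enrichment"].astype(bool)
    return ProbePanel(df)  # sortedness/uniqueness enforced by the container


# --------------------------------------------------------------- ratio matrix

def write_ratio_matrix(cohort: CopyNumberCohort, path: str | Path) -> None:
    df = pd.DataFrame(cohort.ratios, columns=cohort.samples)
    df.insert(0, "probe_id", cohort.panel.probes["probe_id"].to_numpy())
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_ratio_matrix(path: str | Path, panel: ProbePanel) -> CopyNumberCohort:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if "probe_id" not in df.columns:
        raise ValueError(f"ratio matrix {path}: missing probe_id column")
    if not (df["probe_id"].to_numpy() == panel.probes["probe_id"].to_numpy()).all():
        raise ValueError(f"ratio matrix {path}: probe order does not match panel")
    samples = [c for c in df.columns if c != "probe_id"]
    ratios = df[samples].to_numpy(float)
    return CopyNumberCohort(panel, samples, ratios)


# ------------------------------------------------------------------ gene BED

def read_gene_bed(path: str | Path) -> list[GeneModel]:
    """BED4 (chrom, start, end, name), 0-based half-open -> 1-based
    inclusive gene models."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: BED line needs 4 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if end <= start:
                raise ValueError(f"{path}:{ln}: empty interval for {name}")
            genes.append(GeneModel(name, chrom, start + 1, end))
    names = [g.gene_name for g in genes]
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise ValueError(f"{path}: duplicate gene name {dup!r}")
    return genes


def write_gene_bed(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_name}\n")


# ------------------------------------------------------------------ clinical

def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.data.to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stage": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"clinical table {path}: missing sample_id column")
    df = df.set_index("sample_id")
    for col in ("relapse", "event", "adjuvant"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return ClinicalTable(df)


# ------------------------------------------------------------------ variants

def read_variants(path: str | Path) -> list[VariantRecord]:
    """Variant records from TSV (sample, gene, vaf, consequence,
    known_polymorphism)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str, "consequence": str})
    required = {"sample", "gene", "vaf", "consequence", "known_polymorphism"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table {path}: missing columns {sorted(missing)}")
    return [
        VariantRecord(
            sample_id=row["sample"],
            gene=row["gene"],
            vaf=float(row["vaf"]),
            consequence=row["consequence"],
            known_polymorphism=bool(int(row["known_polymorphism"])),
        )
        for _, row in df.iterrows()
    ]


def write_variants(records: list[VariantRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.sample_id, r.gene, r.vaf, r.consequence, int(r.known_polymorphism))
            for r in records
        ],
        columns=["sample", "gene", "vaf", "consequence", "known_polymorphism"],
    ).to_csv(path, sep="\t", index=False)


def read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    """Minimal single-sample-per-record VCF: INFO carries SAMPLE, GENE,
    VAF, CSQCLASS and the KNOWN_SNP flag."""
    records: list[VariantRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{ln}: truncated VCF record")
            info = {}
            for item in fields[7].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    info[k] = v
                elif item:
                    info[item] = True
            try:
                records.append(
                    VariantRecord(
                        sample_id=str(info["SAMPLE"]),
                        gene=str(info["GENE"]),
                        vaf=float(info["VAF"]),
                        consequence=str(info["CSQCLASS"]),
                        known_polymorphism=bool(info.get("KNOWN_SNP", False)),
                    )
                )
            except KeyError as exc:
                raise ValueError(f"{path}:{ln}: missing INFO key {exc}") from exc
    return records


# ---------------------------------------------------------- mutation matrix

def write_mutation_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="sample_id")


def read_mutation_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    return df.astype(np.int8)


# ----------------------------------------------------------------------- SEG

def write_seg(segmented: SegmentedCohort, path: str | Path) -> None:
    """Standard SEG: one row per segment, 1-based inclusive coordinates."""
    df = segmented.to_frame()
    df.columns = SEG_COLUMNS
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_seg(path: str | Path, panel: ProbePanel) -> SegmentedCohort:
    """Rebuild a SegmentedCohort from SEG rows against a known panel."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SEG {path}: missing columns {sorted(missing)}")
    pos = panel.positions()
    chroms = panel.probes["chrom"].to_numpy()
    samples = list(dict.fromkeys(df["sample"]))
    by_chrom = {c: (pos[lo:hi], lo) for c, lo, hi in panel.chrom_bounds()}
    segments: list[list[Segment]] = []
    for sample in samples:
        rows = df[df["sample"] == sample]
        segs = []
        for _, row in rows.iterrows():
            if row["chrom"] not in by_chrom:
                raise ValueError(f"SEG {path}: unknown chromosome {row['chrom']}")
            cpos, lo = by_chrom[row["chrom"]]
            i = int(np.searchsorted(cpos, row["loc.start"], side="left"))
            j = int(np.searchsorted(cpos, row["loc.end"], side="right")) - 1
            if i > j or cpos[i] != row["loc.start"] or cpos[j] != row["loc.end"]:
                raise ValueError(
                    f"SEG {path}: segment bounds {row['chrom']}:{row['loc.start']}-"
                    f"{row['loc.end']} do not match panel probe positions"
                )
            segs.append(Segment(row["chrom"], lo + i, lo + j, float(row["seg.mean"])))
        segments.append(segs)
    sc = SegmentedCohort(panel, samples, segments, np.full(len(samples), np.nan))
    sc.validate_partition()
    return sc


# ----------------------------------------------------------- cohort bundles

def write_cohort(
    cohort: CopyNumberCohort,
    outdir: str | Path,
    clinical: ClinicalTable | None = None,
    mutations: pd.DataFrame | None = None,
    truth=None,
) -> None:
    """Write a simulated or real cohort as a directory of TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_probe_panel(cohort.panel, outdir / "panel.tsv")
    write_ratio_matrix(cohort, outdir / "ratios.tsv")
    if clinical is not None:
        write_clinical(clinical, outdir / "clinical.tsv")
    if mutations is not None:
        write_mutation_matrix(mutations, outdir / "mutations.tsv")
    if truth is not None:
        pd.DataFrame(truth.states, columns=cohort.samples).assign(
            probe_id=cohort.panel.probes["probe_id"].to_numpy()
        ).to_csv(outdir / "truth_states.tsv", sep="\t", index=False)
        rows = []
        for sample, bps in zip(cohort.samples, truth.breakpoints):
            for b in bps:
                rows.append((sample, cohort.panel.probes["probe_id"].iloc[b], int(b)))
        pd.DataFrame(rows, columns=["sample", "probe_id", "probe_row"]).to_csv(
            outdir / "truth_breakpoints.tsv", sep="\t", index=False
        )


def read_cohort(outdir: str | Path) -> tuple[CopyNumberCohort, ClinicalTable | None, pd.DataFrame | None]:
    outdir = Path(outdir)
    panel = read_probe_panel(outdir / "panel.tsv")
    cohort = read_ratio_matrix(outdir / "ratios.tsv", panel)
    clinical = None
    if (outdir / "clinical.tsv").exists():
        clinical = read_clinical(outdir / "clinical.tsv")
        clinical.aligned_to(cohort.samples)
    mutations = None
    if (outdir / "mutations.tsv").exists():
        mutations = read_mutation_matrix(outdir / "mutations.tsv")
    return cohort, clinical, mutations
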