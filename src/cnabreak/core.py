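"""Shared in-memory containers for the array-CGH cohort pipeline.

The pipeline's central objects mirror the stages of a copy-number study:
a :class:`ProbePanel` describes the array design, a
:class:`CopyNumberCohort` holds the probe x sample log2-ratio matrix, a
:class:`SegmentedCohort` the per-sample piecewise-constant profiles, a
:class:`CallSet` the discrete copy-number states with class posteriors,
and a :class:`RegionSet` the reduced co-aberrant regions used for
cohort-level association testing.

Coordinates are 1-based inclusive basepairs throughout; probe indices are
0-based row offsets into the panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: copy-number state codes used everywhere downstream
LOSS, NEUTRAL, GAIN, AMP = -1, 0, 1, 2
STATE_NAMES = {LOSS: "loss", NEUTRAL: "neutral", GAIN: "gain", AMP: "amplification"}
STATE_CODES = {v: k for k, v in STATE_NAMES.items()}
#: order of the four mixture classes in posterior arrays
CLASS_ORDER = (LOSS, NEUTRAL, GAIN, AMP)


def chrom_sort_key(label: str) -> tuple:
    """Natural chromosome ordering: 1..22, then X (23), Y, then others."""
    s = str(label)
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.isdigit():
        return (0, int(s), "")
    if s.upper() == "X":
        return (0, 23, "")
    if s.upper() == "Y":
        return (0, 24, "")
    return (1, 0, s)


@dataclass
class ProbePanel:
    """Array design: one row per probe, sorted by (chromosome, position).

    Columns of :attr:`probes`: ``probe_id`` (unique str), ``chrom`` (str),
    ``pos`` (int, 1-based), ``is_enrichment`` (bool; probes added at cancer
    gene loci that are excluded from breakpoint analysis to keep probe
    spacing even).
    """

    probes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.probes.reset_index(drop=True)
        required = ["probe_id", "chrom", "pos", "is_enrichment"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"probe panel missing columns: {missing}")
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        df["is_enrichment"] = df["is_enrichment"].astype(bool)
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicate probe_id: {dup!r}")
        keys = [(chrom_sort_key(c), p) for c, p in zip(df["chrom"], df["pos"])]
        for i in range(1, len(keys)):
            if keys[i] <= keys[i - 1]:
                raise ValueError(
                    "panel not sorted: probe "
                    f"{df['probe_id'].iloc[i]!r} at {df['chrom'].iloc[i]}:"
                    f"{df['pos'].iloc[i]} out of order"
                )
        self.probes = df

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def chroms(self) -> list[str]:
        seen: list[str] = []
        for c in self.probes["chrom"]:
            if not seen or seen[-1] != c:
                seen.append(c)
        return seen

    def chrom_bounds(self) -> list[tuple[str, int, int]]:
        """(chrom, start_row, stop_row) half-open row ranges, in panel order."""
        out = []
        chroms = self.probes["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out.append((chroms[start], start, i))
                start = i
        return out

    def subset(self, mask: np.ndarray) -> "ProbePanel":
        return ProbePanel(self.probes.loc[np.asarray(mask, bool)].reset_index(drop=True))

    def positions(self) -> np.ndarray:
        return self.probes["pos"].to_numpy()


@dataclass
class CopyNumberCohort:
    """Probe panel plus probe x sample matrix of log2 tumor/normal ratios."""

    panel: ProbePanel
    samples: list[str]
    ratios: np.ndarray  # (n_probes, n_samples), float

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.shape != (self.panel.n_probes, len(self.samples)):
            raise ValueError(
                f"ratio matrix shape {self.ratios.shape} inconsistent with "
                f"{self.panel.n_probes} probes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.ratios)):
            raise ValueError("ratio matrix contains non-finite values")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample names")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "CopyNumberCohort":
        return CopyNumberCohort(self.panel, list(self.samples), self.ratios.copy())

    def subset_probes(self, mask: np.ndarray) -> "CopyNumberCohort":
        mask = np.asarray(mask, bool)
        return CopyNumberCohort(self.panel.subset(mask), list(self.samples), self.ratios[mask])


@dataclass(frozen=True)
class Segment:
    """One constant-copy-number segment: global probe rows [start, end]."""

    chrom: str
    start: int  # first probe row (inclusive, global panel index)
    end: int  # last probe row (inclusive)
    mean: float

    @property
    def n_probes(self) -> int:
        return self.end - self.start + 1


@dataclass
class SegmentedCohort:
    """Per-sample ordered segment lists over a shared panel, plus QC."""

    panel: ProbePanel
    samples: list[str]
    segments: list[list[Segment]]  # per sample, panel order
    mad: np.ndarray  # per-sample MAD of lag-1 differences (noise estimate)

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.samples):
            raise ValueError("one segment list per sample required")
        self.mad = np.asarray(self.mad, dtype=float)

    def validate_partition(self) -> None:
        """Check segments tile every chromosome without gaps or overlap."""
        bounds = self.panel.chrom_bounds()
        for sample, segs in zip(self.samples, self.segments):
            it = iter(segs)
            for chrom, lo, hi in bounds:
                expect = lo
                while expect < hi:
                    seg = next(it, None)
                    if seg is None or seg.chrom != chrom or seg.start != expect:
                        raise ValueError(f"segments of {sample} do not tile {chrom}")
                    expect = seg.end + 1
                if expect != hi:
                    raise ValueError(f"segments of {sample} overrun {chrom}")
            if next(it, None) is not None:
                raise ValueError(f"extra segments in {sample}")

    def sample_values(self, s: int) -> np.ndarray:
        """Segment means expanded back to a per-probe vector for sample s."""
        out = np.empty(self.panel.n_probes)
        for seg in self.segments[s]:
            out[seg.start : seg.end + 1] = seg.mean
        return out

    def to_frame(self) -> pd.DataFrame:
        pos = self.panel.positions()
        rows = []
        for sample, segs in zip(self.samples, self.segments):
            for seg in segs:
                rows.append(
                    (sample, seg.chrom, int(pos[seg.start]), int(pos[seg.end]),
                     seg.n_probes, seg.mean)
                )
        return pd.DataFrame(
            rows, columns=["sample", "chrom", "start", "end", "num_probes", "seg_mean"]
        )


@dataclass
class CallSet:
    """Discrete copy-number states with per-probe class posteriors.

    ``states`` is probe x sample with codes {-1 loss, 0 neutral, +1 gain,
    +2 amplification}; ``posteriors`` is probe x sample x 4 in
    :data:`CLASS_ORDER`, each probe inheriting its segment's posterior.
    """

    panel: ProbePanel
    samples: list[str]
    states: np.ndarray  # (P, S) int8
    posteriors: np.ndarray  # (P, S, 4) float
    segmented: SegmentedCohort | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        P, S = self.panel.n_probes, len(self.samples)
        if self.states.shape != (P, S) or self.posteriors.shape != (P, S, 4):
            raise ValueError("call matrices inconsistent with panel/samples")


@dataclass
class RegionSet:
    """Co-aberrant regions: a partition of the probe space with region-level
    calls (per-sample modal state) and averaged posteriors."""

    panel: ProbePanel
    samples: list[str]
    regions: pd.DataFrame  # chrom, start_row, end_row, start_pos, end_pos, n_probes
    calls: np.ndarray  # (R, S) int8
    posteriors: np.ndarray  # (R, S, 4)

    @property
    def n_regions(self) -> int:
        return len(self.regions)


@dataclass
class BreakpointSet:
    """CNA-associated breakpoint indicators on the (enrichment-filtered) panel."""

    panel: ProbePanel
    samples: list[str]
    flags: np.ndarray  # (P, S) bool; True = copy-number state changes at this probe
    counts: np.ndarray  # (P,) per-probe cohort counts
    rate: float  # genome-wide per-probe per-sample breakpoint rate

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        self.counts = np.asarray(self.counts, dtype=int)

    def sample_bp_scores(self) -> np.ndarray:
        return self.flags.sum(axis=0)


@dataclass(frozen=True)
class GeneModel:
    """A gene footprint, 1-based inclusive."""

    gene_name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_name}: start > end")


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation: stage, relapse, DFS follow-up."""

    data: pd.DataFrame  # index sample_id; stage, relapse, dfs_time, event, adjuvant

    def __post_init__(self) -> None:
        df = self.data
        required = ["stage", "relapse", "dfs_time", "event", "adjuvant"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        if (df["dfs_time"] <= 0).any():
            bad = df.index[df["dfs_time"] <= 0][0]
            raise ValueError(f"non-positive DFS time for sample {bad!r}")
        bad_stage = set(df["stage"].unique()) - {"II", "III"}
        if bad_stage:
            raise ValueError(f"unknown stage labels: {sorted(bad_stage)}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def aligned_to(self, samples: Sequence[str]) -> "ClinicalTable":
        missing = sorted(set(samples) - set(self.data.index))
        extra = sorted(set(self.data.index) - set(samples))
        if missing or extra:
            raise ValueError(
                f"sample mismatch between cohort and clinical table; "
                f"missing from clinical: {missing}; only in clinical: {extra}"
            )
        return ClinicalTable(self.data.loc[list(samples)])
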