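"""Synthetic array-CGH cohort generator with full ground truth.

Emulates a two-stage (II/III) microsatellite-stable colon cancer cohort
profiled on an evenly spaced oligonucleotide array: segmental gains and
losses at CRC-typical population frequencies, Gaussian probe noise,
optional low-frequency "genomic wave" artifacts, a relapse-enriched loss
region, mutation-coupled chromosomal instability, and exponential
disease-free-survival times with group-specific hazards.

The default genome is deliberately scaled down (5 synthetic chromosomes x
400 probes at 17 kb spacing) so the full pipeline runs in seconds; the
~180K-probe scale of a real 180K array is a configuration choice.
Every stochastic choice flows from a single seed, so regeneration with
the same configuration is bit-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AMP,
    GAIN,
    LOSS,
    NEUTRAL,
    STATE_CODES,
    ClinicalTable,
    CopyNumberCohort,
    ProbePanel,
    Segment,
)

#: log2-ratio offsets of the four states in a ~70% tumor-cell-content sample
DEFAULT_OFFSETS = {LOSS: -0.6, NEUTRAL: 0.0, GAIN: 0.45, AMP: 1.2}

MAPK_GENES = ("KRAS", "NRAS", "BRAF")


@dataclass(frozen=True)
class ArchetypeRegion:
    """A recurrent CNA present in a given fraction of the cohort.

    ``start_probe``/``end_probe`` are 0-based inclusive probe offsets
    within the chromosome.
    """

    chrom: str
    start_probe: int
    end_probe: int
    state: str  # 'loss' | 'gain' | 'amplification'
    frequency: float


@dataclass(frozen=True)
class RelapseRegion:
    """A loss region whose carrier probability depends on relapse status."""

    chrom: str
    start_probe: int
    end_probe: int
    penetrance_relapse: float = 0.98
    penetrance_nonrelapse: float = 0.745


@dataclass(frozen=True)
class MutationModel:
    """Gene mutation frequency plus mutation-coupled instability: each
    mutated sample acquires ``extra_segments`` random CNA segments."""

    frequency: float
    extra_segments: int = 0
    segment_probes: tuple[int, int] = (10, 60)  # length range, probes


@dataclass(frozen=True)
class SurvivalModel:
    """Exponential DFS model: hazard = baseline * HR^stratum, censored at
    ``horizon_months``."""

    baseline_hazard: float = 0.012  # events per month in the reference stratum
    hazard_ratio: float = 4.0
    horizon_months: float = 120.0


def default_archetypes() -> list[ArchetypeRegion]:
    """CRC-typical recurrent CNAs on the scaled-down 5-chromosome genome:
    arm-level losses (1p/17p/18-like) and gains (7/13q/20q-like) plus a
    focal amplicon."""
    return [
        ArchetypeRegion("chr1", 0, 199, "loss", 0.35),
        ArchetypeRegion("chr2", 0, 399, "gain", 0.50),
        ArchetypeRegion("chr3", 100, 139, "amplification", 0.08),
        ArchetypeRegion("chr3", 200, 399, "gain", 0.45),
        ArchetypeRegion("chr4", 100, 299, "loss", 0.40),
        ArchetypeRegion("chr5", 0, 99, "loss", 0.25),
    ]


def default_mutation_models() -> dict[str, MutationModel]:
    """Mutation frequencies typical of MSS colon cancer panels; APC and
    TP53 couple to instability via extra random segments."""
    return {
        "APC": MutationModel(0.45, extra_segments=3),
        "TP53": MutationModel(0.50, extra_segments=4),
        "KRAS": MutationModel(0.40),
        "PIK3CA": MutationModel(0.15),
        "FBXW7": MutationModel(0.10),
        "SMAD4": MutationModel(0.10),
        "BRAF": MutationModel(0.05),
        "NRAS": MutationModel(0.05),
    }


@dataclass
class SimulationConfig:
    n_samples: int = 114
    n_probes_per_chrom: int = 400
    n_chromosomes: int = 5
    probe_spacing: int = 17_000
    noise_sd: float = 0.1
    wave_amplitude: float = 0.0
    wave_cycles: float = 1.5  # sinusoid cycles per chromosome
    enrichment_fraction: float = 0.02
    state_offsets: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_OFFSETS))
    archetype_regions: list[ArchetypeRegion] = field(default_factory=default_archetypes)
    relapse_region: RelapseRegion | None = field(
        default_factory=lambda: RelapseRegion("chr5", 150, 249)
    )
    relapse_rate_stage2: float = 22 / 57
    relapse_rate_stage3: float = 27 / 57
    mutation_models: dict[str, MutationModel] = field(default_factory=default_mutation_models)
    mapk_exclusive: bool = True  # draw at most one of KRAS/NRAS/BRAF per sample
    survival_model: SurvivalModel = field(default_factory=SurvivalModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        chroms = [f"chr{i + 1}" for i in range(self.n_chromosomes)]
        by_chrom: dict[str, list[ArchetypeRegion]] = {}
        regions = list(self.archetype_regions)
        for r in regions:
            if r.chrom not in chroms:
                raise ValueError(f"archetype on unknown chromosome {r.chrom}")
            if not (0 <= r.start_probe <= r.end_probe < self.n_probes_per_chrom):
                raise ValueError(f"archetype bounds out of range on {r.chrom}")
            if not 0 <= r.frequency <= 1:
                raise ValueError("archetype frequency must be in [0, 1]")
            if r.state not in STATE_CODES or r.state == "neutral":
                raise ValueError(f"invalid archetype state {r.state!r}")
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, rs in by_chrom.items():
            rs = sorted(rs, key=lambda r: r.start_probe)
            for a, b in zip(rs, rs[1:]):
                if b.start_probe <= a.end_probe:
                    raise ValueError(f"overlapping archetype regions on {chrom}")
        rr = self.relapse_region
        if rr is not None:
            if rr.chrom not in chroms or not (
                0 <= rr.start_probe <= rr.end_probe < self.n_probes_per_chrom
            ):
                raise ValueError("relapse region out of range")
            for p in (rr.penetrance_relapse, rr.penetrance_nonrelapse):
                if not 0 <= p <= 1:
                    raise ValueError("penetrance must be in [0, 1]")
        for gene, m in self.mutation_models.items():
            if not 0 <= m.frequency <= 1:
                raise ValueError(f"mutation frequency for {gene} must be in [0, 1]")
        if self.survival_model.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be > 0")
        if self.survival_model.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be > 0")


@dataclass
class GroundTruth:
    """Everything the generator knows: the basis for every recovery test."""

    states: np.ndarray  # (P, S) int8 true per-probe states
    segments: list[list[Segment]]  # per sample true segments (panel row coords)
    breakpoints: list[np.ndarray]  # per sample global probe rows of true breakpoints
    relapse: np.ndarray  # (S,) bool
    dfs_time: np.ndarray  # (S,) months
    event: np.ndarray  # (S,) bool
    mutations: pd.DataFrame  # sample x gene binary


def _make_panel(cfg: SimulationConfig, rng: np.random.Generator) -> ProbePanel:
    rows = []
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        for p in range(cfg.n_probes_per_chrom):
            pos = (p + 1) * cfg.probe_spacing
            rows.append((f"P_{chrom}_{p:05d}", chrom, pos))
    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])
    n = len(df)
    enrich = np.zeros(n, dtype=bool)
    k = int(round(cfg.enrichment_fraction * n))
    if k:
        enrich[rng.choice(n, size=k, replace=False)] = True
    df["is_enrichment"] = enrich
    return ProbePanel(df)


def _true_segments(
    states_col: np.ndarray, panel: ProbePanel, offsets: dict[int, float]
) -> tuple[list[Segment], np.ndarray]:
    """Run-length extraction of true segments (mean = true log2 offset)
    and internal breakpoints."""
    segs: list[Segment] = []
    bps: list[int] = []
    for chrom, lo, hi in panel.chrom_bounds():
        start = lo
        for i in range(lo + 1, hi + 1):
            if i == hi or states_col[i] != states_col[start]:
                segs.append(Segment(chrom, start, i - 1, offsets[int(states_col[start])]))
                if i < hi:
                    bps.append(i)
                start = i
    return segs, np.asarray(bps, dtype=int)


def simulate_survival(
    strata: np.ndarray, model: SurvivalModel, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with hazard = baseline * HR^stratum, censored
    at the follow-up horizon. Returns (dfs_time months, event flag)."""
    strata = np.asarray(strata)
    if strata.size == 0:
        raise ValueError("empty cohort")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hazard = model.baseline_hazard * model.hazard_ratio ** strata.astype(float)
    t = rng.exponential(1.0 / hazard)
    event = t < model.horizon_months
    return np.minimum(t, model.horizon_months), event


def simulate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[CopyNumberCohort, ClinicalTable, pd.DataFrame, GroundTruth]:
    """Generate a cohort with known ground truth.

    Returns (cohort, clinical, mutation_matrix, truth). The log2 ratio of
    probe p in sample s is the state offset of the covering true segment,
    plus an optional per-chromosome sinusoidal wave with random phase,
    plus Gaussian probe noise.
    """
    cfg = config if config is not None else SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    panel = _make_panel(cfg, rng)
    P = panel.n_probes
    S = cfg.n_samples
    L = cfg.n_probes_per_chrom
    samples = [f"S{idx + 1:03d}" for idx in range(S)]
    bounds = panel.chrom_bounds()
    chrom_start = {chrom: lo for chrom, lo, _ in bounds}

    # clinical skeleton: half stage II / half stage III, relapse counts
    # fixed per stage so cohort composition matches the configured rates
    stage = np.array(["II"] * (S - S // 2) + ["III"] * (S // 2))
    relapse = np.zeros(S, dtype=bool)
    for st, rate in (("II", cfg.relapse_rate_stage2), ("III", cfg.relapse_rate_stage3)):
        idx = np.flatnonzero(stage == st)
        k = int(round(rate * len(idx)))
        relapse[rng.choice(idx, size=k, replace=False)] = True

    # mutation matrix
    genes = list(cfg.mutation_models)
    mut = pd.DataFrame(0, index=samples, columns=genes, dtype=np.int8)
    mapk_present = [g for g in MAPK_GENES if g in cfg.mutation_models]
    for g in genes:
        if cfg.mapk_exclusive and g in mapk_present:
            continue
        mut[g] = (rng.random(S) < cfg.mutation_models[g].frequency).astype(np.int8)
    if cfg.mapk_exclusive and mapk_present:
        freqs = np.array([cfg.mutation_models[g].frequency for g in mapk_present])
        p_any = min(freqs.sum(), 1.0)
        hit = rng.random(S) < p_any
        choice = rng.choice(len(mapk_present), size=S, p=freqs / freqs.sum())
        for i, g in enumerate(mapk_present):
            mut[g] = (hit & (choice == i)).astype(np.int8)

    # per-probe true states
    states = np.zeros((P, S), dtype=np.int8)
    for reg in cfg.archetype_regions:
        carriers = rng.random(S) < reg.frequency
        lo = chrom_start[reg.chrom] + reg.start_probe
        hi = chrom_start[reg.chrom] + reg.end_probe
        states[lo : hi + 1, carriers] = STATE_CODES[reg.state]
    if cfg.relapse_region is not None:
        rr = cfg.relapse_region
        pen = np.where(relapse, rr.penetrance_relapse, rr.penetrance_nonrelapse)
        carriers = rng.random(S) < pen
        lo = chrom_start[rr.chrom] + rr.start_probe
        states[lo : lo + (rr.end_probe - rr.start_probe) + 1, carriers] = LOSS
    # mutation-coupled instability: random extra segments overwrite
    for g in genes:
        m = cfg.mutation_models[g]
        if m.extra_segments == 0:
            continue
        for s in np.flatnonzero(mut[g].to_numpy()):
            for _ in range(m.extra_segments):
                chrom, lo, hi = bounds[rng.integers(len(bounds))]
                length = int(rng.integers(m.segment_probes[0], m.segment_probes[1] + 1))
                start = lo + int(rng.integers(0, max(1, (hi - lo) - length + 1)))
                state = LOSS if rng.random() < 0.5 else GAIN
                states[start : start + length, s] = state

    # truth segments / breakpoints
    segments: list[list[Segment]] = []
    breakpoints: list[np.ndarray] = []
    for s in range(S):
        segs, bps = _true_segments(states[:, s], panel, cfg.state_offsets)
        segments.append(segs)
        breakpoints.append(bps)

    # signal = offsets + wave + noise
    offsets = np.zeros(5)
    for code, off in cfg.state_offsets.items():
        offsets[code + 1] = off
    ratios = offsets[states.astype(int) + 1]
    if cfg.wave_amplitude > 0:
        for chrom, lo, hi in bounds:
            x = np.arange(hi - lo) / L  # chromosome fraction
            phase = rng.uniform(0, 2 * np.pi, size=S)
            wave = cfg.wave_amplitude * np.sin(
                2 * np.pi * cfg.wave_cycles * x[:, None] + phase[None, :]
            )
            ratios[lo:hi] += wave
    ratios = ratios + rng.normal(0.0, cfg.noise_sd, size=(P, S))

    # DFS: relapsed samples experience the event before the horizon;
    # relapse-free samples are censored at their follow-up time
    sm = cfg.survival_model
    if sm.horizon_months <= 0:
        dfs = np.zeros(S)
        event = np.zeros(S, dtype=bool)
    else:
        hazard = sm.baseline_hazard * np.where(relapse, sm.hazard_ratio, 1.0)
        raw = rng.exponential(1.0 / hazard)
        dfs = np.where(relapse, np.minimum(raw, 0.95 * sm.horizon_months),
                       rng.uniform(0.3 * sm.horizon_months, sm.horizon_months, size=S))
        dfs = np.maximum(dfs, 0.1)
        event = relapse.copy()

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "stage": stage,
                "relapse": relapse.astype(int),
                "dfs_time": dfs,
                "event": event.astype(int),
                "adjuvant": (stage == "III").astype(int),
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    cohort = CopyNumberCohort(panel, samples, ratios)
    truth = GroundTruth(
        states=states,
        segments=segments,
        breakpoints=breakpoints,
        relapse=relapse,
        dfs_time=dfs,
        event=event,
        mutations=mut,
    )
    return cohort, clinical, mut, truth


def config_from_mapping(mapping: dict, seed: int | None = None) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain (YAML-friendly)
    mapping: nested region / model objects may be given as dicts."""
    kw = dict(mapping)
    if seed is not None:
        kw["seed"] = seed
    if "archetype_regions" in kw:
        kw["archetype_regions"] = [
            r if isinstance(r, ArchetypeRegion) else ArchetypeRegion(**r)
            for r in kw["archetype_regions"]
        ]
    if "relapse_region" in kw and isinstance(kw["relapse_region"], dict):
        kw["relapse_region"] = RelapseRegion(**kw["relapse_region"])
    if "mutation_models" in kw:
        kw["mutation_models"] = {
            g: m if isinstance(m, MutationModel) else MutationModel(**m)
            for g, m in kw["mutation_models"].items()
        }
    if "survival_model" in kw and isinstance(kw["survival_model"], dict):
        kw["survival_model"] = SurvivalModel(**kw["survival_model"])
    if "state_offsets" in kw:
        kw["state_offsets"] = {int(k): float(v) for k, v in kw["state_offsets"].items()}
    return SimulationConfig(**kw)


def sample_seed(base_seed: int, name: str) -> int:
    """Stable per-name sub-seed (< 2**31), order-independent."""
    return (base_seed * 2654435761 + zlib.crc32(name.encode())) % (2**31 - 1)
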