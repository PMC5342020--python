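"""Shared fixtures: scaled-down simulated cohorts with ground truth.

Heavy artifacts (the default-size cohort and its segmentations) are
session-scoped so the segmentation cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cnabreak import (
    ArchetypeRegion,
    ProbePanel,
    RelapseRegion,
    SimulationConfig,
    fit_call_mixture,
    call_states,
    reduce_regions,
    segment_cohort,
    simulate_cohort,
)


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """A 3-chromosome, 150-probe/chrom cohort that exercises all four
    copy-number states."""
    defaults = dict(
        n_samples=30,
        n_chromosomes=3,
        n_probes_per_chrom=150,
        archetype_regions=[
            ArchetypeRegion("chr1", 0, 59, "loss", 0.40),
            ArchetypeRegion("chr2", 0, 79, "gain", 0.50),
            ArchetypeRegion("chr3", 30, 49, "amplification", 0.15),
        ],
        relapse_region=RelapseRegion("chr3", 80, 129),
        enrichment_fraction=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def small_cohort(small_bundle):
    return small_bundle[0]


@pytest.fixture(scope="session")
def small_clinical(small_bundle):
    return small_bundle[1]


@pytest.fixture(scope="session")
def small_truth(small_bundle):
    return small_bundle[3]


@pytest.fixture(scope="session")
def small_segmented(small_cohort):
    return segment_cohort(small_cohort, seed=7)


@pytest.fixture(scope="session")
def small_mixture(small_segmented):
    return fit_call_mixture(small_segmented)


@pytest.fixture(scope="session")
def small_callset(small_segmented, small_mixture):
    return call_states(small_segmented, small_mixture)


@pytest.fixture(scope="session")
def small_regions(small_callset):
    return reduce_regions(small_callset)


@pytest.fixture(scope="session")
def default_bundle():
    """The generator's default study-sized cohort (114 samples)."""
    return simulate_cohort(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def default_segmented(default_bundle):
    return segment_cohort(default_bundle[0], seed=17)


def make_panel(n: int, chrom: str = "chr1", spacing: int = 1000) -> ProbePanel:
    return ProbePanel(
        pd.DataFrame(
            {
                "probe_id": [f"{chrom}_p{i}" for i in range(n)],
                "chrom": chrom,
                "pos": (np.arange(n) + 1) * spacing,
                "is_enrichment": False,
            }
        )
    )


def make_multi_panel(n_per_chrom: int, n_chroms: int, spacing: int = 1000) -> ProbePanel:
    frames = []
    for c in range(n_chroms):
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": [f"chr{c+1}_p{i}" for i in range(n_per_chrom)],
                    "chrom": f"chr{c+1}",
                    "pos": (np.arange(n_per_chrom) + 1) * spacing,
                    "is_enrichment": False,
                }
            )
        )
    return ProbePanel(pd.concat(frames, ignore_index=True))
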