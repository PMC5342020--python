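"""Cohort-level association statistics and chromosomal-instability scores.

Two-group testing of CNA regions uses the chi-square statistic on the
2x2 carrier table (no continuity correction) with a label-permutation
reference distribution: the permutation p-value is exact up to Monte
Carlo error and the permutation FDR is the averaged-exceedance
estimator — for each region, the average number of null statistics at
least as large as its observed statistic, divided by the number of
observed statistics at least as large.

Instability is summarized per sample by the CNA-score (number of probes
in a non-neutral state) and BP-score (number of CNA-associated
breakpoint locations); scores are compared between strata with two-sided
Mann-Whitney U tests. Samples are clustered on region-level call
posteriors (total-variation distance, Ward linkage).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import GAIN, LOSS, BreakpointSet, CallSet, RegionSet

DEFAULT_N_PERM = 10_000
DEFAULT_MIN_FREQ = 0.10
DEFAULT_FDR_CUT = 0.2


def chi2_2x2(table: np.ndarray) -> float:
    """Pearson chi-square for a 2x2 table, no continuity correction.
    Degenerate margins give statistic 0."""
    t = np.asarray(table, float)
    n = t.sum()
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    denom = r[0] * r[1] * c[0] * c[1]
    if denom == 0 or n == 0:
        return 0.0
    return float(n * (t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]) ** 2 / denom)


def _chi2_carriers(carr: np.ndarray, n1: np.ndarray, S: int, n_g1: int) -> np.ndarray:
    """Vectorized 2x2 chi-square from carrier counts.

    carr: per-region total carriers (R,); n1: per-region (or region x B)
    carriers in group 1; n_g1: group-1 size.
    """
    a = n1.astype(float)  # carriers, group 1
    b = carr.astype(float).reshape(-1, *([1] * (n1.ndim - 1))) - a  # carriers, group 2
    carr_f = a + b
    c = n_g1 - a
    d = (S - n_g1) - b
    r1 = carr_f
    r2 = S - carr_f
    denom = r1 * r2 * n_g1 * (S - n_g1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = S * (a * d - b * c) ** 2 / denom
    return np.where(denom > 0, stat, 0.0)


def permutation_fdr(obs: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Averaged-exceedance permutation FDR.

    For observed statistics t_i and a null matrix (tests x permutations):
    FDR_i = mean_b #{j : T_jb >= t_i} / #{j : t_j >= t_i}, clipped to 1.
    """
    obs = np.asarray(obs, float)
    B = null.shape[1]
    flat = np.sort(null.ravel())
    sorted_obs = np.sort(obs)
    null_ge = flat.size - np.searchsorted(flat, obs, side="left")
    obs_ge = sorted_obs.size - np.searchsorted(sorted_obs, obs, side="left")
    fdr = (null_ge / B) / np.maximum(obs_ge, 1)
    return np.minimum(fdr, 1.0)


def compare_groups(
    regions: RegionSet,
    labels: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    min_freq: float = DEFAULT_MIN_FREQ,
    fdr_cut: float = DEFAULT_FDR_CUT,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-region two-group chi-square tests with permutation p and FDR.

    Separate tests compare gains versus no-gains and losses versus
    no-losses (amplification counts as gain). Regions aberrant in fewer
    than ``min_freq`` of samples are excluded per aberration type; FDR is
    estimated within each type's family of tests.
    """
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError("labels must define exactly two groups")
    g1 = labels == levels[0]
    S = len(labels)
    if g1.sum() == 0 or g1.sum() == S:
        raise ValueError("both groups must be non-empty")
    if regions.calls.shape[1] != S:
        raise ValueError("labels not aligned to samples")
    rng = np.random.default_rng(seed)
    perms = np.empty((S, n_perm), dtype=bool)
    for b in range(n_perm):
        perms[:, b] = rng.permutation(g1)
    results = []
    for kind, carrier in (("gain", regions.calls >= GAIN), ("loss", regions.calls == LOSS)):
        freq = carrier.mean(axis=1)
        keep = np.flatnonzero(freq >= min_freq)
        if keep.size == 0:
            continue
        X = carrier[keep].astype(np.int32)
        carr = X.sum(axis=1)
        n_g1 = int(g1.sum())
        obs = _chi2_carriers(carr, X @ g1.astype(np.int32), S, n_g1)
        null = _chi2_carriers(carr, X @ perms.astype(np.int32), S, n_g1)
        p = (1.0 + (null >= obs[:, None]).sum(axis=1)) / (1.0 + n_perm)
        fdr = permutation_fdr(obs, null)
        f1 = X[:, g1].mean(axis=1)
        f2 = X[:, ~g1].mean(axis=1)
        for i, ridx in enumerate(keep):
            row = regions.regions.iloc[ridx]
            results.append(
                {
                    "region": int(ridx),
                    "chrom": row["chrom"],
                    "start_pos": row["start_pos"],
                    "end_pos": row["end_pos"],
                    "type": kind,
                    "stat": obs[i],
                    "p": p[i],
                    "fdr": fdr[i],
                    f"freq_{levels[0]}": f1[i],
                    f"freq_{levels[1]}": f2[i],
                    "significant": fdr[i] < fdr_cut,
                }
            )
    return pd.DataFrame(results)


def instability_scores(
    callset: CallSet, bpset: BreakpointSet | None = None
) -> pd.DataFrame:
    """Per-sample CNA-score (probes in a non-neutral state) and BP-score
    (CNA-associated breakpoint locations; requires a BreakpointSet, which
    is computed on the enrichment-filtered panel)."""
    cna = (callset.states != 0).sum(axis=0)
    out = pd.DataFrame({"cna_score": cna}, index=pd.Index(callset.samples, name="sample_id"))
    if bpset is not None:
        if list(bpset.samples) != list(callset.samples):
            raise ValueError("call set and breakpoint set sample lists differ")
        out["bp_score"] = bpset.sample_bp_scores()
    return out


def mann_whitney_scores(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two strata; exact null
    enumeration for combined n <= 20 (tie-free), normal approximation
    with tie correction otherwise. Returns (U of group 1, p)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError("labels must define exactly two groups")
    x = scores[labels == levels[0]]
    y = scores[labels == levels[1]]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(scores) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    exact = (len(x) + len(y) <= 20) and len(np.unique(scores)) == len(scores)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def sample_dissimilarity(posteriors: np.ndarray) -> np.ndarray:
    """Pairwise sample dissimilarity: mean over regions of the
    total-variation distance between 4-class posterior vectors."""
    P = np.asarray(posteriors, float)  # (R, S, 4)
    R, S, _ = P.shape
    D = np.zeros((S, S))
    for s in range(S):
        diff = np.abs(P[:, s : s + 1, :] - P).sum(axis=2) * 0.5  # (R, S)
        D[s] = diff.mean(axis=0)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def cluster_samples(
    regions: RegionSet, n_clusters: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ward-linkage hierarchical clustering of samples on region-level
    call posteriors. Returns (linkage matrix, flat cluster labels,
    dissimilarity matrix); deterministic for a given input."""
    if len(regions.samples) < 2:
        raise ValueError("need >= 2 samples to cluster")
    D = sample_dissimilarity(regions.posteriors)
    Z = hierarchy.linkage(squareform(D, checks=False), method="ward")
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, labels, D


def linkage_to_newick(Z: np.ndarray, names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def build(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = build(node.left), build(node.right)
        dl = max(node.dist - node.left.dist, 0.0)
        dr = max(node.dist - node.right.dist, 0.0)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return build(tree) + ";"


def fisher_exact(table: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided conditional (hypergeometric) Fisher exact test.

    Returns (odds_ratio, p, degenerate): the raw sample odds ratio
    (0 or inf when a cell is empty; a 0.5 continuity adjustment is a
    display matter left to callers), the two-sided p summing outcomes no
    more probable than the observed table, and a flag set when a margin
    is zero (p = 1, OR undefined).
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    margins = np.concatenate([t.sum(axis=0), t.sum(axis=1)])
    if (margins == 0).any():
        return np.nan, 1.0, True
    p = float(stats.fisher_exact(t.astype(int), alternative="two-sided")[1])
    num = t[0, 0] * t[1, 1]
    den = t[0, 1] * t[1, 0]
    odds = np.inf if den == 0 else float(num / den)
    return odds, p, False
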