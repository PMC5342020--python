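"""Kaplan-Meier, log-rank and Cox proportional-hazards analysis of
disease-free survival.

All three primitives are implemented for the univariate binary-covariate
setting the cohort analyses need. Ties are handled with the Breslow
convention in the Cox partial likelihood, which makes the log-rank
statistic identical to the Cox score test at beta = 0 on tie-free data —
a property the test suite exploits as a cross-method identity check.

Region-level DFS association uses log-rank tests with a permutation
reference distribution (survival tuples shuffled against call columns)
and the same averaged-exceedance permutation-FDR estimator as the
two-group CNA tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GAIN, LOSS, ClinicalTable, RegionSet
from .cohort_stats import DEFAULT_FDR_CUT, DEFAULT_MIN_FREQ, DEFAULT_N_PERM, permutation_fdr


def _check_times(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must align")
    if (t <= 0).any():
        raise ValueError("survival times must be > 0")
    return t, e


def km_estimate(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event time: time, n_risk, n_event,
    survival (censored observations at the same time leave the risk set
    after the events there).
    """
    t, e = _check_times(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    rows = []
    surv = 1.0
    n = len(t)
    for ut in np.unique(t[e]):
        n_risk = int(np.sum(t >= ut))
        d = int(np.sum(e & (t == ut)))
        surv *= 1.0 - d / n_risk
        rows.append((float(ut), n_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_event", "survival"])


def _logrank_stats(times: np.ndarray, events: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Log-rank chi-square for one or many binary group assignments.

    ``groups`` is (n,) or (n, B) of {0,1}; returns (B,) statistics using
    the hypergeometric variance at each distinct event time.
    """
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order].astype(float)
    G = np.asarray(groups, float)
    G = G[order] if G.ndim == 1 else G[order, :]
    if G.ndim == 1:
        G = G[:, None]
    n = len(t)
    # distinct-time blocks
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    n_at = n - starts  # at risk at each distinct time
    d_at = np.add.reduceat(e, starts)  # events at each distinct time
    d1_at = np.add.reduceat(e[:, None] * G, starts, axis=0)  # group-1 events
    # group-1 at risk: suffix sums of G evaluated at block starts
    suffix = np.cumsum(G[::-1], axis=0)[::-1]
    n1_at = suffix[starts]
    has_event = d_at > 0
    nt = n_at[has_event].astype(float)
    d = d_at[has_event]
    n1 = n1_at[has_event]
    d1 = d1_at[has_event]
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = d[:, None] * n1 / nt[:, None]
        var = (
            d[:, None]
            * (n1 / nt[:, None])
            * (1.0 - n1 / nt[:, None])
            * np.where(nt[:, None] > 1, (nt[:, None] - d[:, None]) / (nt[:, None] - 1), 0.0)
        )
    O_E = (d1 - expected).sum(axis=0)
    V = var.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, O_E**2 / V, 0.0)
    return chi2


def logrank_test(times: np.ndarray, events: np.ndarray, group: np.ndarray) -> tuple[float, float]:
    """Two-sided log-rank test for a binary group; returns (chi2, p)."""
    t, e = _check_times(times, events)
    g = np.asarray(group).astype(int)
    if set(np.unique(g)) - {0, 1}:
        raise ValueError("group must be binary 0/1")
    if g.min() == g.max():
        raise ValueError("both groups must be non-empty")
    if not e.any():
        return 0.0, 1.0
    chi2 = float(_logrank_stats(t, e, g)[0])
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class CoxResult:
    """Univariate Cox fit for a binary covariate (Breslow ties)."""

    hr: float
    ci_low: float
    ci_high: float
    p: float
    beta: float
    se: float
    converged: bool
    separated: bool = False


def cox_hr(
    times: np.ndarray,
    events: np.ndarray,
    covariate: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxResult:
    """Univariate Cox proportional-hazards fit by Newton iteration on the
    Breslow partial likelihood. HR = exp(beta); 95% CI = exp(beta +/-
    1.96 SE); Wald p. Monotone likelihood (all events in one covariate
    level, i.e. complete separation) is flagged and reported as an
    infinite (or zero) hazard ratio."""
    t, e = _check_times(times, events)
    x = np.asarray(covariate, float)
    if len(np.unique(x)) < 2:
        raise ValueError("covariate must take two values")
    if not ((e & (x == x.min())).any() and (e & (x == x.max())).any()):
        hr = np.inf if e[x == x.max()].sum() > 0 else 0.0
        beta = np.inf if hr == np.inf else -np.inf
        return CoxResult(hr, np.nan, np.nan, np.nan, beta, np.nan, False, separated=True)
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    n = len(t)
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    block_of = np.repeat(np.arange(len(starts)), np.diff(np.r_[starts, n]))
    beta = 0.0
    converged = False
    for _ in range(max_iter):
        w = np.exp(beta * x)
        s0 = np.cumsum(w[::-1])[::-1][starts]  # risk-set sums at block starts
        s1 = np.cumsum((w * x)[::-1])[::-1][starts]
        s2 = np.cumsum((w * x * x)[::-1])[::-1][starts]
        mb = s1 / s0
        vb = s2 / s0 - mb**2
        U = float(np.sum(e * (x - mb[block_of])))
        info = float(np.sum(e * vb[block_of]))
        if info <= 0:
            break
        step = U / info
        beta += step
        if abs(beta) > 20:
            return CoxResult(
                np.inf if beta > 0 else 0.0, np.nan, np.nan, np.nan,
                beta, np.nan, False, separated=True,
            )
        if abs(step) < tol:
            converged = True
            break
    se = 1.0 / np.sqrt(info)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return CoxResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        p=float(p),
        beta=float(beta),
        se=float(se),
        converged=converged,
    )


def cox_score_stat(times: np.ndarray, events: np.ndarray, covariate: np.ndarray) -> float:
    """Cox score test chi-square at beta = 0 (Breslow ties); equals the
    log-rank statistic on tie-free data."""
    t, e = _check_times(times, events)
    x = np.asarray(covariate, float)
    order = np.argsort(t, kind="stable")
    t, e, x = t[order], e[order], x[order]
    n = len(t)
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    block_of = np.repeat(np.arange(len(starts)), np.diff(np.r_[starts, n]))
    s0 = np.cumsum(np.ones(n)[::-1])[::-1][starts]
    s1 = np.cumsum(x[::-1])[::-1][starts]
    s2 = np.cumsum((x * x)[::-1])[::-1][starts]
    mb = s1 / s0
    vb = s2 / s0 - mb**2
    U = float(np.sum(e * (x - mb[block_of])))
    info = float(np.sum(e * vb[block_of]))
    return U**2 / info if info > 0 else 0.0


def logrank_permutation_regions(
    regions: RegionSet,
    clinical: ClinicalTable,
    n_perm: int = DEFAULT_N_PERM,
    min_freq: float = DEFAULT_MIN_FREQ,
    fdr_cut: float = DEFAULT_FDR_CUT,
    seed: int = 0,
    chunk: int = 200,
) -> pd.DataFrame:
    """Per-region DFS log-rank tests with permutation p-values and FDR.

    Calls are dichotomized per aberration type (gain carriers, loss
    carriers); regions below the frequency filter or with an empty group
    are skipped. Permutations shuffle the survival tuples against the
    (fixed) call columns.
    """
    aligned = clinical.aligned_to(regions.samples)
    times = aligned.data["dfs_time"].to_numpy(float)
    events = aligned.data["event"].to_numpy(bool)
    S = len(times)
    rng = np.random.default_rng(seed)
    results = []
    for kind, carrier in (("gain", regions.calls >= GAIN), ("loss", regions.calls == LOSS)):
        freq = carrier.mean(axis=1)
        keep = np.flatnonzero((freq >= min_freq) & (freq < 1.0))
        if keep.size == 0:
            continue
        G = carrier[keep].T.astype(float)  # (S, R)
        obs = _logrank_stats(times, events, G)
        R = keep.size
        null = np.empty((R, n_perm))
        done = 0
        # permuting survival against calls == shuffling call rows: batch
        # several permutations into one wide group matrix for speed
        while done < n_perm:
            m = min(chunk, n_perm - done)
            cols = [G[rng.permutation(S)] for _ in range(m)]
            stats_flat = _logrank_stats(times, events, np.hstack(cols))
            null[:, done : done + m] = stats_flat.reshape(m, R).T
            done += m
        p = (1.0 + (null >= obs[:, None]).sum(axis=1)) / (1.0 + n_perm)
        fdr = permutation_fdr(obs, null)
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
                    "freq": freq[ridx],
                    "significant": fdr[i] < fdr_cut,
                }
            )
    return pd.DataFrame(results)
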