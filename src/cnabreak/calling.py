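"""Copy-number state calling and region reduction.

Segments are classified into loss / neutral / gain / amplification with a
cohort-wide four-component Gaussian mixture fitted to probe-count-weighted
segment means (ordered means, the neutral mean constrained near 0).
Per-segment class posteriors follow from Bayes' rule with the probe-count-
weighted likelihood; a segment is assigned an aberrant state only when
that class's posterior exceeds 0.5, otherwise it is called neutral.

The probe x sample call matrix is then reduced to co-aberrant regions:
maximal runs of adjacent probes whose per-sample call signatures disagree
with the region consensus at an average rate of at most ``averror``
(default 0.015).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CLASS_ORDER,
    GAIN,
    LOSS,
    NEUTRAL,
    CallSet,
    RegionSet,
    SegmentedCohort,
)

logger = logging.getLogger(__name__)

DEFAULT_AVERROR = 0.015
_NEUTRAL_BOUND = 0.1  # the neutral component mean is confined to +/- this
_SD_FLOOR = 0.02


@dataclass
class CallMixture:
    """Fitted Gaussian mixture over segment means, ordered
    loss < neutral < gain < amplification. A dropped amplification
    component is represented with zero weight."""

    means: np.ndarray  # (4,)
    sds: np.ndarray  # (4,)
    weights: np.ndarray  # (4,)
    loglik: float = np.nan

    @property
    def n_effective(self) -> int:
        return int(np.sum(self.weights > 0))


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return np.interp(np.asarray(q) * cw[-1], cw, x[order])


def _em_fit(
    y: np.ndarray,
    w: np.ndarray,
    mu0: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Weighted EM for a k-component Gaussian mixture; the component whose
    initial mean is nearest 0 is treated as neutral and kept in
    [-0.1, 0.1]."""
    k = len(mu0)
    mu = mu0.astype(float).copy()
    neutral = int(np.argmin(np.abs(mu)))
    sd = np.full(k, 0.1)
    pi = np.full(k, 1.0 / k)
    wsum = w.sum()
    ll_old = -np.inf
    for _ in range(max_iter):
        logp = (
            np.log(pi)[None, :]
            - 0.5 * np.log(2 * np.pi * sd[None, :] ** 2)
            - 0.5 * ((y[:, None] - mu[None, :]) / sd[None, :]) ** 2
        )
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        tot = p.sum(axis=1, keepdims=True)
        r = p / tot
        ll = float(np.sum(w * (m[:, 0] + np.log(tot[:, 0]))))
        nk = (w[:, None] * r).sum(axis=0)
        pi = nk / wsum
        safe = np.maximum(nk, 1e-300)
        mu = (w[:, None] * r * y[:, None]).sum(axis=0) / safe
        # shared component variance: a free per-component variance lets a
        # rare component balloon into an outlier-soaker instead of
        # tracking its state's tight cluster
        var = (w[:, None] * r * (y[:, None] - mu[None, :]) ** 2).sum() / wsum
        sd = np.full(k, np.sqrt(max(var, _SD_FLOOR**2)))
        mu[neutral] = np.clip(mu[neutral], -_NEUTRAL_BOUND, _NEUTRAL_BOUND)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    return mu, sd, pi, ll


def fit_call_mixture(
    segmented: SegmentedCohort,
    n_restarts: int = 10,
    min_weight: float = 1e-4,
) -> CallMixture:
    """Fit the cohort-wide calling mixture to probe-count-weighted segment
    means.

    Initialization seeds the four component means at the 2.5%, 50%, 90%
    and 99% weighted quantiles of the segment means (loss / neutral /
    gain / amplification), with a fixed set of jittered restarts, keeping
    the best weighted likelihood, so the fit is deterministic. If the
    amplification component degenerates — weight below ``min_weight``,
    or its mean collapsing onto another component's — the mixture is
    refitted with three components and amplification kept as a
    zero-weight placeholder.
    """
    y, w = [], []
    for segs in segmented.segments:
        for seg in segs:
            y.append(seg.mean)
            w.append(seg.n_probes)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if len(np.unique(np.round(y, 12))) < 4:
        # effectively a single state: call everything neutral
        center = _weighted_quantile(y, w, np.array([0.5]))[0]
        return CallMixture(
            means=np.array([-0.6, np.clip(center, -0.1, 0.1), 0.45, 1.2]),
            sds=np.full(4, _SD_FLOOR),
            weights=np.array([0.0, 1.0, 0.0, 0.0]),
        )

    def run(variants: list[np.ndarray]) -> tuple:
        best = None
        for v, quantiles in enumerate(variants):
            base = _weighted_quantile(y, w, quantiles)
            for restart in range(n_restarts):
                rng = np.random.default_rng(1000 * v + restart)  # fixed restart seeds
                mu0 = base + (0.0 if restart == 0 else rng.normal(0, 0.03, size=len(base)))
                fit = _em_fit(y, w, np.sort(mu0))
                if best is None or fit[3] > best[3]:
                    best = fit
        return best

    # amplifications can be a sub-percent sliver of probe mass, so the top
    # component is seeded from both a moderate and an extreme quantile
    mu, sd, pi, ll = run(
        [np.array([0.025, 0.5, 0.9, 0.99]), np.array([0.025, 0.5, 0.9, 0.999])]
    )
    # degenerate amplification component: vanished weight, or collapsed
    # onto another component (no amplified segments in the cohort)
    collapsed = np.min(np.diff(np.sort(mu))) < 0.08
    if np.min(pi) < min_weight or collapsed:
        mu3, sd3, pi3, ll = run([np.array([0.025, 0.5, 0.95])])
        order = np.argsort(mu3)
        mu = np.append(mu3[order], max(1.2, mu3[order][-1] + 0.5))
        sd = np.append(sd3[order], _SD_FLOOR)
        pi = np.append(pi3[order], 0.0)
    order = np.argsort(mu)
    return CallMixture(means=mu[order], sds=sd[order], weights=pi[order], loglik=ll)


def segment_posteriors(mean: float, n_probes: int, mixture: CallMixture) -> np.ndarray:
    """4-class posterior for one segment: Bayes' rule with the probe-count-
    weighted likelihood (each probe contributes the component density at
    the segment mean)."""
    with np.errstate(divide="ignore"):
        logw = np.where(mixture.weights > 0, np.log(np.maximum(mixture.weights, 1e-300)), -np.inf)
    ll = (
        -0.5 * np.log(2 * np.pi * mixture.sds**2)
        - 0.5 * ((mean - mixture.means) / mixture.sds) ** 2
    )
    logpost = logw + n_probes * ll
    logpost -= logpost.max()
    post = np.exp(logpost)
    return post / post.sum()


def call_states(segmented: SegmentedCohort, mixture: CallMixture) -> CallSet:
    """Assign per-segment states by the posterior > 0.5 rule; probes
    inherit their segment's state and posterior. When no class reaches
    0.5, the segment is called neutral."""
    P = segmented.panel.n_probes
    S = len(segmented.samples)
    states = np.zeros((P, S), dtype=np.int8)
    posts = np.zeros((P, S, 4))
    neutral_idx = CLASS_ORDER.index(NEUTRAL)
    for s, segs in enumerate(segmented.segments):
        for seg in segs:
            post = segment_posteriors(seg.mean, seg.n_probes, mixture)
            best = int(np.argmax(post))
            state = CLASS_ORDER[best] if post[best] > 0.5 else NEUTRAL
            if best == neutral_idx:
                state = NEUTRAL
            states[seg.start : seg.end + 1, s] = state
            posts[seg.start : seg.end + 1, s, :] = post
    return CallSet(segmented.panel, list(segmented.samples), states, posts, segmented)


def reduce_regions(callset: CallSet, averror: float = DEFAULT_AVERROR) -> RegionSet:
    """Greedy left-to-right merge of adjacent probes into maximal runs in
    which every member probe's per-sample calls disagree with the region
    consensus (per-sample modal state) at an average rate <= averror."""
    states = callset.states
    S = len(callset.samples)
    pos = callset.panel.positions()
    cols = np.arange(S)

    def new_counts(i: int) -> np.ndarray:
        c = np.zeros((4, S), dtype=np.int32)
        c[_code_idx(states[i]), cols] += 1
        return c

    region_rows: list[tuple] = []
    for chrom, lo, hi in callset.panel.chrom_bounds():
        start = lo
        counts = new_counts(lo)  # state counts per sample in current run
        for i in range(lo + 1, hi):
            cand = counts.copy()
            cand[_code_idx(states[i]), cols] += 1
            consensus = np.argmax(cand, axis=0)  # modal state index per sample
            block = _code_idx(states[start : i + 1])
            disagrees = (block != consensus[None, :]).mean(axis=1)
            if np.all(disagrees <= averror):
                counts = cand
            else:
                region_rows.append((chrom, start, i - 1, int(pos[start]), int(pos[i - 1]), i - start))
                start = i
                counts = new_counts(i)
        region_rows.append((chrom, start, hi - 1, int(pos[start]), int(pos[hi - 1]), hi - start))
    regions = pd.DataFrame(
        region_rows,
        columns=["chrom", "start_row", "end_row", "start_pos", "end_pos", "n_probes"],
    )
    R = len(regions)
    calls = np.zeros((R, S), dtype=np.int8)
    posts = np.zeros((R, S, 4))
    codes = np.array(CLASS_ORDER, dtype=np.int8)
    for r, (a, b) in enumerate(zip(regions["start_row"], regions["end_row"])):
        block = _code_idx(states[a : b + 1])
        onehot = np.zeros((4, S), dtype=np.int32)
        for row in block:
            onehot[row, cols] += 1
        calls[r] = codes[np.argmax(onehot, axis=0)]
        posts[r] = callset.posteriors[a : b + 1].mean(axis=0)
    return RegionSet(callset.panel, list(callset.samples), regions, calls, posts)


def _code_idx(states: np.ndarray) -> np.ndarray:
    """Map state codes {-1,0,1,2} to class indices {0,1,2,3}."""
    return (np.asarray(states, dtype=np.int64) + 1).clip(0, 3)


def aberration_frequencies(
    calls: np.ndarray,
    labels: np.ndarray | None = None,
) -> pd.DataFrame | dict:
    """Per-row gain% and loss% (amplification counts as gain), overall or
    per group. ``calls`` is a region-or-probe x sample state matrix."""
    calls = np.asarray(calls)

    def freq(mat: np.ndarray) -> pd.DataFrame:
        if mat.shape[1] == 0:
            raise ValueError("empty group")
        gain = 100.0 * (mat >= GAIN).mean(axis=1)
        loss = 100.0 * (mat == LOSS).mean(axis=1)
        return pd.DataFrame({"gain_pct": gain, "loss_pct": loss})

    if labels is None:
        return freq(calls)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) < 2:
        raise ValueError("empty group: labels define fewer than two groups")
    return {lev: freq(calls[:, labels == lev]) for lev in levels}
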