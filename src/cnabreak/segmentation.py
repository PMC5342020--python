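"""Per-sample preprocessing and change-point segmentation.

The segmentation stage turns probe-level log2 ratios into ordered
constant-copy-number segments per sample:

1. median normalization (per-sample median log2 ratio set to 0),
2. optional robust detrending of low-frequency "genomic wave" artifacts,
3. recursive max-t change-point splitting per chromosome (binary splits
   plus interior arcs, the circular form of the statistic) with a
   within-window permutation p-value, local boundary refinement, and
   SD-undo re-merging of adjacent segments whose mean difference is
   small relative to the sample's residual noise (a stricter multiplier
   for long segments),
4. post-segmental mode normalization, re-centering the dominant
   (assumed copy-number-neutral) state at 0.

Residual noise per sample is estimated as MAD(lag-1 differences)/sqrt(2),
which is robust to the piecewise-constant signal itself; the same value
is the per-sample quality-control statistic (profiles with MAD >= 0.4
would be rejected in a real cohort).
"""

from __future__ import annotations

import logging

import numpy as np


from .core import CopyNumberCohort, ProbePanel, Segment, SegmentedCohort
from .simulate import sample_seed

logger = logging.getLogger(__name__)

MAD_QC_THRESHOLD = 0.4
#: segments longer than this many probes use the long-segment undo multiplier
UNDO_LONG_LENGTH = 30


def median_normalize(cohort: CopyNumberCohort) -> CopyNumberCohort:
    """Subtract each sample's median log2 ratio (per-sample median -> 0)."""
    out = cohort.copy()
    out.ratios -= np.median(out.ratios, axis=0, keepdims=True)
    return out


def _robust_smooth_trend(y: np.ndarray, frac_pos: np.ndarray, n_harmonics: int,
                         n_iter: int = 8) -> np.ndarray:
    """Low-frequency trend by robust harmonic regression.

    Fits an intercept plus the first ``n_harmonics`` Fourier pairs in the
    chromosome-position fraction with iteratively reweighted least
    squares (Tukey biweight). Genuine copy-number steps lie outside the
    smooth basis and are progressively downweighted, so they survive the
    subtraction while sinusoidal waves are captured almost exactly.
    """
    from scipy.ndimage import median_filter

    cols = [np.ones_like(frac_pos)]
    for k in range(1, n_harmonics + 1):
        cols.append(np.sin(2 * np.pi * k * frac_pos))
        cols.append(np.cos(2 * np.pi * k * frac_pos))
    B = np.column_stack(cols)
    # start from a running-median trend: its wide window rejects
    # copy-number steps, keeping the IRLS iteration in the wave-only basin
    window = max(11, 2 * (len(y) // (2 * n_harmonics)) + 1)
    trend = median_filter(y, size=window, mode="nearest")
    beta = np.zeros(B.shape[1])
    for _ in range(n_iter):
        resid = y - trend
        scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        if scale <= 0:
            break
        u = resid / (4.685 * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        Bw = B * w[:, None]
        beta = np.linalg.lstsq(Bw.T @ B, Bw.T @ y, rcond=None)[0]
        trend = B @ beta
    return B @ beta


def detrend_waves(cohort: CopyNumberCohort, span: float = 0.3) -> CopyNumberCohort:
    """Remove per-chromosome low-frequency "genomic wave" trends.

    ``span`` is the shortest trend wavelength to remove, as a fraction of
    the chromosome: the trend model keeps Fourier components with
    wavelength >= span (n_harmonics = round(1/span)). Estimation is
    robust (see :func:`_robust_smooth_trend`) so copy-number steps that
    are narrow relative to the trend wavelength are preserved.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    n_harmonics = max(1, round(1.0 / span))
    out = cohort.copy()
    pos = cohort.panel.positions().astype(float)
    for chrom, lo, hi in cohort.panel.chrom_bounds():
        if hi - lo < 10:
            logger.warning("detrend_waves: %s has <10 probes, passed through", chrom)
            continue
        x = pos[lo:hi]
        frac = (x - x[0]) / max(x[-1] - x[0], 1.0)
        for s in range(cohort.n_samples):
            y = out.ratios[lo:hi, s]
            out.ratios[lo:hi, s] = y - _robust_smooth_trend(y, frac, n_harmonics)
    return out


def qc_mad(sample_ratios: np.ndarray) -> tuple[float, bool]:
    """Per-sample noise estimate: normal-consistent MAD of lag-1
    differences scaled by 1/sqrt(2), i.e. an estimate of the probe-level
    noise SD. Pass iff < 0.4."""
    x = np.asarray(sample_ratios, float)
    if x.size < 2:
        raise ValueError("need >= 2 probes for MAD QC")
    mad = _residual_sd(x)
    return float(mad), bool(mad < MAD_QC_THRESHOLD)


def _residual_sd(x: np.ndarray) -> float:
    """Robust noise SD: MAD of first differences / sqrt(2), scaled to sigma."""
    d = np.diff(x)
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad * 1.4826 / np.sqrt(2.0))


def _arc_widths(n: int, min_width: int) -> np.ndarray:
    """Interior arc widths scanned by the max-t statistic: all short
    widths, then a geometric grid — enough resolution to catch focal
    segments without the full O(n^2) arc scan."""
    widths = []
    m = min_width
    while m <= n - min_width:
        widths.append(m)
        m = max(m + 1, int(m * 1.25))
    return np.asarray(widths, dtype=int)


def _max_arc_t(X: np.ndarray, s: float, min_width: int, return_arg: bool = False):
    """Max-t change-point statistic over candidate splits for each row of X.

    Candidates are binary splits (arc anchored at the window edge) at
    every position, plus interior arcs [i, i+w) on the width grid — the
    circular form of the statistic, which keeps power for focal segments
    embedded in long windows. Returns max t per row; with
    ``return_arg`` (single row) also the best (i, j) arc.
    """
    B, n = X.shape
    CS = np.zeros((B, n + 1))
    np.cumsum(X, axis=1, out=CS[:, 1:])
    tot = CS[:, -1:]
    best = np.full(B, -np.inf)
    arg = (0, n)
    # binary splits [0, k) vs [k, n)
    k = np.arange(min_width, n - min_width + 1)
    if k.size:
        m1 = CS[:, k] / k
        m2 = (tot - CS[:, k]) / (n - k)
        t = np.abs(m1 - m2) / (s * np.sqrt(1.0 / k + 1.0 / (n - k)))
        idx = np.argmax(t, axis=1)
        best = t[np.arange(B), idx]
        if return_arg:
            arg = (0, int(k[idx[0]]))
    for w in _arc_widths(n, min_width):
        i = np.arange(1, n - w)  # interior arcs only; edges covered above
        if i.size == 0:
            continue
        seg = CS[:, i + w] - CS[:, i]
        t = np.abs(seg / w - (tot - seg) / (n - w)) / (
            s * np.sqrt(1.0 / w + 1.0 / (n - w))
        )
        idx = np.argmax(t, axis=1)
        tmax = t[np.arange(B), idx]
        if return_arg and tmax[0] > best[0]:
            arg = (int(i[idx[0]]), int(i[idx[0]]) + w)
        best = np.maximum(best, tmax)
    if return_arg:
        return best[0], arg
    return best


def _split_p_value(
    x: np.ndarray,
    t_obs: float,
    s: float,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
    min_width: int,
    chunk: int = 250,
) -> float:
    """Permutation p-value of the max-t statistic, with early stopping
    once the estimate is clearly above alpha."""
    n = len(x)
    exceed = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        idx = rng.permuted(np.tile(np.arange(n), (m, 1)), axis=1)
        null = _max_arc_t(x[idx], s, min_width)
        exceed += int(np.sum(null >= t_obs))
        done += m
        if (exceed / done) > 4 * alpha and exceed >= 10:
            break
    return (1.0 + exceed) / (1.0 + done)


def _split_recursive(
    x: np.ndarray,
    offset: int,
    s: float,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
    min_width: int = 2,
) -> list[int]:
    """Recursive splitting; returns sorted split points (local to the
    chromosome, offset already applied). An interior arc split produces
    up to three sub-windows, each recursed."""
    n = len(x)
    if n < 2 * min_width:
        return []
    t_obs, (i, j) = _max_arc_t(x[None, :], s, min_width, return_arg=True)
    p = _split_p_value(x, t_obs, s, alpha, n_perm, rng, min_width)
    if p >= alpha:
        return []
    splits = [c for c in (i, j) if 0 < c < n]
    out: list[int] = []
    edges = [0] + splits + [n]
    for a, b in zip(edges[:-1], edges[1:]):
        out.extend(_split_recursive(x[a:b], offset + a, s, alpha, n_perm, rng, min_width))
    return sorted(out + [offset + c for c in splits])


def _refine_boundaries(x: np.ndarray, splits: list[int], s: float,
                       max_iter: int = 5) -> list[int]:
    """Re-locate each split point at the exact max-t position between its
    neighboring boundaries (the arc width grid finds splits only
    approximately)."""
    splits = sorted(set(splits))
    n = len(x)
    for _ in range(max_iter):
        changed = False
        edges = [0] + splits + [n]
        for idx in range(1, len(edges) - 1):
            u, v = edges[idx - 1], edges[idx + 1]
            if v - u < 2:
                continue
            xw = x[u:v]
            cs = np.cumsum(xw)
            k = np.arange(1, v - u)
            t = np.abs(cs[k - 1] / k - (cs[-1] - cs[k - 1]) / (v - u - k)) / (
                np.sqrt(1.0 / k + 1.0 / (v - u - k))
            )
            k_new = u + int(k[np.argmax(t)])
            if k_new != edges[idx]:
                edges[idx] = k_new
                changed = True
        splits = sorted(set(e for e in edges[1:-1] if 0 < e < n))
        if not changed:
            break
    return splits


def _undo_merge(
    bounds: list[int],
    x: np.ndarray,
    s: float,
    undo_sd_short: float,
    undo_sd_long: float,
    long_length: int = UNDO_LONG_LENGTH,
) -> list[int]:
    """SD-undo: repeatedly merge the adjacent segment pair whose mean
    difference is smallest relative to its undo threshold, while any pair
    falls below threshold. Long-segment pairs (both > long_length probes)
    use the larger multiplier, i.e. need a bigger step to stay split."""
    bounds = list(bounds)
    while bounds:
        edges = [0] + bounds + [len(x)]
        means = np.array([x[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
        lengths = np.diff(edges)
        best = None
        for i in range(len(bounds)):
            mult = (
                undo_sd_long
                if lengths[i] > long_length and lengths[i + 1] > long_length
                else undo_sd_short
            )
            diff = abs(means[i + 1] - means[i])
            ratio = diff / (mult * s) if s > 0 else np.inf
            if ratio < 1 and (best is None or ratio < best[1]):
                best = (i, ratio)
        if best is None:
            break
        del bounds[best[0]]
    return bounds


def cbs_segment(
    sample_ratios: np.ndarray,
    panel: ProbePanel,
    alpha: float = 0.01,
    n_perm: int = 1000,
    undo_sd_short: float = 2.0,
    undo_sd_long: float = 3.0,
    rng: np.random.Generator | int | None = None,
) -> list[Segment]:
    """Segment one sample's ratios (panel order) into constant segments."""
    x = np.asarray(sample_ratios, float)
    if x.shape != (panel.n_probes,):
        raise ValueError("sample_ratios length must match panel")
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    s = _residual_sd(x)
    if s <= 0:
        s = 1e-12  # noise-free input: any step is infinitely significant
    segs: list[Segment] = []
    for chrom, lo, hi in panel.chrom_bounds():
        xc = x[lo:hi]
        if hi - lo == 1:
            segs.append(Segment(chrom, lo, lo, float(xc[0])))
            continue
        splits = _split_recursive(xc, 0, s, alpha, n_perm, rng)
        splits = _refine_boundaries(xc, splits, s)
        splits = _undo_merge(splits, xc, s, undo_sd_short, undo_sd_long)
        splits = _refine_boundaries(xc, splits, s)
        edges = [0] + splits + [hi - lo]
        for a, b in zip(edges[:-1], edges[1:]):
            segs.append(Segment(chrom, lo + a, lo + b - 1, float(xc[a:b].mean())))
    return segs


def mode_normalize(segments: list[Segment], bandwidth: float = 0.05,
                   rel_height: float = 0.6) -> tuple[list[Segment], float]:
    """Re-center a sample so the modal (assumed copy-number-neutral)
    state of its probe-weighted segment-mean density sits at 0.

    Returns (shifted segments, shift applied). The kernel density uses a
    fixed absolute bandwidth in log2 units so resolution between states
    does not depend on the sample's dynamic range. In highly aberrant
    genomes the tallest peak may be an aberrant state that narrowly
    outweighs the neutral one; among peaks within ``rel_height`` of the
    tallest, the one nearest the probe-weighted median is chosen. All
    ingredients translate with the data, so the shift is equivariant
    under sample-wide additive offsets.
    """
    means = np.array([seg.mean for seg in segments])
    weights = np.array([seg.n_probes for seg in segments], float)
    if np.ptp(means) < 1e-12:
        shift = float(means[0])
    else:
        grid = np.linspace(means.min() - 3 * bandwidth, means.max() + 3 * bandwidth, 2048)
        dens = np.zeros_like(grid)
        for m, w in zip(means, weights):
            dens += w * np.exp(-0.5 * ((grid - m) / bandwidth) ** 2)
        interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
        peaks = np.flatnonzero(interior) + 1
        peaks = peaks[dens[peaks] >= rel_height * dens.max()]
        if peaks.size == 0:
            peaks = np.array([np.argmax(dens)])
        order = np.argsort(means)
        cw = np.cumsum(weights[order])
        wmedian = means[order][np.searchsorted(cw, 0.5 * cw[-1])]
        shift = float(grid[peaks[np.argmin(np.abs(grid[peaks] - wmedian))]])
    out = [Segment(s.chrom, s.start, s.end, s.mean - shift) for s in segments]
    return out, shift


def segment_cohort(
    cohort: CopyNumberCohort,
    alpha: float = 0.01,
    n_perm: int = 1000,
    undo_sd_short: float = 2.0,
    undo_sd_long: float = 3.0,
    detrend: bool = False,
    span: float = 0.3,
    mode_norm: bool = True,
    seed: int = 0,
) -> SegmentedCohort:
    """Full preprocessing + segmentation pipeline for a cohort.

    Per-sample randomness (permutation p-values) is seeded from the
    sample name, so results do not depend on sample order.
    """
    work = median_normalize(cohort)
    if detrend:
        work = detrend_waves(work, span=span)
    all_segments: list[list[Segment]] = []
    mads = np.empty(work.n_samples)
    for s, name in enumerate(work.samples):
        x = work.ratios[:, s]
        mads[s], _ = qc_mad(x)
        rng = np.random.default_rng(sample_seed(seed, name))
        segs = cbs_segment(
            x, work.panel, alpha=alpha, n_perm=n_perm,
            undo_sd_short=undo_sd_short, undo_sd_long=undo_sd_long, rng=rng,
        )
        if mode_norm:
            segs, _ = mode_normalize(segs)
        all_segments.append(segs)
    return SegmentedCohort(work.panel, list(work.samples), all_segments, mads)
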