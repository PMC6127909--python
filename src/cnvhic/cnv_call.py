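"""Copy-number estimation directly from a Hi-C contact map.

In raw cancer Hi-C data the genome-wide contact total of each bin is
proportional to its copy number, so the copy-number profile can be read off
the 1D coverage profile once the systematic Hi-C biases are removed.  The
pipeline is: 1D profile (per-bin row sums) -> Poisson-regression correction
for GC content, mappability and effective fragment length (additive
residual, recentered on 1) -> per-chromosome penalized least-squares
changepoint segmentation -> smoothing of the segment means into discrete
levels, with the modal level anchored at copy number 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .core import CNVProfile, ContactMatrix, GenomeBins, cis_mask


@dataclass
class CoverageProfile:
    """Per-bin 1D contact signal (masked bins are nan)."""

    values: np.ndarray
    mode: str = "all"
    corrected: bool = False


@dataclass
class Segmentation:
    """Per-chromosome changepoint segmentation of a 1D profile."""

    breakpoints: np.ndarray  # bin indices starting each segment (0 included)
    segment_means: np.ndarray
    bins: GenomeBins
    smoothed_levels: np.ndarray | None = None
    segments: list = field(default_factory=list)  # (start, end, mean)


def one_d_profile(
    C: ContactMatrix, mode: str = "all", mask: np.ndarray | None = None
) -> CoverageProfile:
    """Per-bin sum of contacts over all / cis / trans pairs."""
    if mode not in ("all", "cis", "trans"):
        raise ValueError(f"unknown mode: {mode!r}")
    counts = C.counts
    if mode != "all":
        cm = cis_mask(C.bins)
        counts = np.where(cm if mode == "cis" else ~cm, counts, 0.0)
    vals = np.nansum(counts, axis=1)
    all_nan = np.all(~np.isfinite(C.counts), axis=1)
    vals[all_nan] = np.nan
    if mask is not None:
        vals = np.where(mask, np.nan, vals)
    return CoverageProfile(vals, mode=mode, corrected=False)


def expected_coverage(C: ContactMatrix, mask: np.ndarray | None = None) -> np.ndarray:
    """Expected per-bin total under a flat copy-number profile.

    Each bin's expected 1D signal is the sum over partners of the empirical
    per-distance mean count (trans pairs use the mean trans count).  Bins
    near chromosome ends see fewer short-range partners, so their expected
    total is lower; using this as an exposure in the feature correction
    removes that purely positional trend, which would otherwise masquerade
    as copy-number structure on short chromosomes.
    """
    codes = C.bins.chrom_codes
    n = C.n
    d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    cis = codes[:, None] == codes[None, :]
    counts = C.counts
    valid = np.isfinite(counts)
    if mask is not None:
        keep = ~mask
        valid &= keep[:, None] & keep[None, :]
    cis_v = cis & valid
    sums = np.bincount(d[cis_v], weights=counts[cis_v], minlength=n)
    nums = np.bincount(d[cis_v], minlength=n).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_d = np.where(nums > 0, sums / nums, 0.0)
    tr_v = ~cis & valid
    mean_tr = counts[tr_v].mean() if np.any(tr_v) else 0.0
    exp = np.where(cis, mean_d[d], mean_tr)
    return exp.sum(axis=1)


def correct_features(
    profile: CoverageProfile, bins: GenomeBins, exposure: np.ndarray | None = None
) -> CoverageProfile:
    """Remove GC / mappability / fragment-length bias from a raw 1D profile.

    A Poisson regression (log link) of the per-bin totals on the
    standardized GC and effective-fragment-length covariates plus
    log-mappability gives fitted systematic values; the corrected profile
    is the additive residual (observed - fitted), affinely rescaled so its
    mean over unmasked bins is exactly 1.  Zero-variance covariates are
    dropped with a warning.

    ``exposure`` (e.g. from :func:`expected_coverage`) enters as a Poisson
    exposure term, absorbing positional coverage structure that is not
    attributable to the feature tracks or to copy number.
    """
    y = profile.values
    ok = np.isfinite(y)
    cols = []
    for name in ("gc", "eff_frag_len", "mappability"):
        v = getattr(bins, name)
        if v is None:
            continue
        vv = v[ok].astype(float)
        if name == "mappability":
            vv = np.log(np.clip(vv, 1e-6, None))
        if np.nanstd(vv) == 0:
            warnings.warn(f"covariate {name} has zero variance; dropped")
            continue
        cols.append((vv - np.nanmean(vv)) / np.nanstd(vv))
    X = sm.add_constant(np.column_stack(cols)) if cols else np.ones((ok.sum(), 1))
    offset = None
    if exposure is not None:
        offset = np.log(np.clip(exposure[ok], 1e-12, None))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y[ok], X, family=sm.families.Poisson(), offset=offset)
        fitted = model.fit().fittedvalues
    resid = y[ok] - fitted
    corrected_ok = 1.0 + (resid - resid.mean()) / np.mean(y[ok])
    out = np.full_like(y, np.nan)
    out[ok] = corrected_ok
    return CoverageProfile(out, mode=profile.mode, corrected=True)


def _segment_chromosome(
    x: np.ndarray, penalty: float, min_size: int
) -> list[int]:
    """Optimal-partition DP: changepoint positions (within x) minimizing
    SSE + penalty per changepoint, each segment >= min_size points."""
    m = x.size
    if m < 2 * min_size:
        return []
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))

    def sse(a: int, b: int) -> float:  # cost of x[a:b]
        s = c1[b] - c1[a]
        return (c2[b] - c2[a]) - s * s / (b - a)

    F = np.full(m + 1, np.inf)
    F[0] = -penalty
    last = np.zeros(m + 1, dtype=np.int64)
    for t in range(min_size, m + 1):
        best, arg = np.inf, 0
        for s in range(0, t - min_size + 1):
            if not np.isfinite(F[s]):
                continue
            v = F[s] + sse(s, t) + penalty
            if v < best:
                best, arg = v, s
        F[t], last[t] = best, arg
    cps = []
    t = m
    while t > 0:
        s = last[t]
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps)


def estimate_noise_sd(x: np.ndarray) -> float:
    """Robust noise scale from successive differences (MAD-based)."""
    d = np.diff(x)
    d = d[np.isfinite(d)]
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d))) / 0.6744898 / np.sqrt(2.0))


def segment(
    profile: CoverageProfile,
    bins: GenomeBins,
    penalty: float | None = None,
    min_segment_bins: int = 2,
    penalty_scale: float = 10.0,
) -> Segmentation:
    """Per-chromosome least-squares changepoint segmentation.

    The default penalty per changepoint is BIC-like: penalty_scale *
    sigma^2 * log(m), with sigma estimated robustly from successive
    differences and m the number of unmasked bins on the chromosome.  The
    scale factor compensates for the short-range correlation of the
    corrected signal (residual distance-decay structure), which the
    successive-difference estimate does not see; copy-number steps are an
    order of magnitude larger than sigma, so detection power is unaffected.
    The penalty may need adjusting to the signal-to-noise ratio of the data.
    """
    y = profile.values
    codes = bins.chrom_codes
    bps_all: list[int] = []
    for c in np.unique(codes):
        idx = np.flatnonzero((codes == c) & np.isfinite(y))
        if idx.size == 0:
            continue
        bps_all.append(int(idx[0]))  # chromosome start (implicit breakpoint)
        x = y[idx]
        pen = penalty
        if pen is None:
            sd = estimate_noise_sd(x)
            pen = penalty_scale * max(sd * sd, 1e-12) * np.log(max(x.size, 2))
        for cp in _segment_chromosome(x, pen, min_segment_bins):
            bps_all.append(int(idx[cp]))
    bps = np.asarray(sorted(bps_all), dtype=np.int64)
    bounds = np.append(bps, bins.n)
    segments = []
    means = []
    for k in range(bps.size):
        s, e = int(bounds[k]), int(bounds[k + 1])
        vals = y[s:e]
        mu = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else np.nan
        segments.append((s, e, mu))
        means.append(mu)
    return Segmentation(bps, np.asarray(means), bins, segments=segments)


def _merge_adjacent(segments: list, codes: np.ndarray, threshold: float) -> list:
    """Iteratively merge the closest adjacent same-chromosome pair whose
    mean difference is below threshold (length-weighted merged mean)."""
    segs = [list(s) for s in segments]
    while True:
        best, arg = np.inf, -1
        for k in range(len(segs) - 1):
            s1, e1, m1 = segs[k]
            s2, e2, m2 = segs[k + 1]
            if codes[s1] != codes[s2] or not (np.isfinite(m1) and np.isfinite(m2)):
                continue
            d = abs(m1 - m2)
            if d < threshold and d < best:
                best, arg = d, k
        if arg < 0:
            break
        s1, e1, m1 = segs[arg]
        s2, e2, m2 = segs[arg + 1]
        w1, w2 = e1 - s1, e2 - s2
        segs[arg] = [s1, e2, (m1 * w1 + m2 * w2) / (w1 + w2)]
        del segs[arg + 1]
    return [tuple(s) for s in segs]


def _cluster_levels(means: np.ndarray, lengths: np.ndarray, gap: float) -> np.ndarray:
    """1-D weighted centroid agglomeration of segment means.

    Repeatedly merges the two clusters with the closest length-weighted
    centers until every adjacent pair of centers is more than ``gap``
    apart.  Unlike single-linkage gap splitting, stray intermediate means
    are absorbed into the nearest heavy cluster instead of chaining two
    well-separated levels together.
    """
    ok = np.isfinite(means)
    idx_ok = np.flatnonzero(ok)
    order = idx_ok[np.argsort(means[idx_ok])]
    clusters = [[int(i)] for i in order]
    w = np.maximum(lengths, 1.0)

    def center(cl: list) -> float:
        return float(np.average(means[cl], weights=w[cl]))

    while len(clusters) > 1:
        centers = [center(cl) for cl in clusters]
        gaps = np.diff(centers)
        k = int(np.argmin(gaps))
        if gaps[k] > gap:
            break
        clusters[k] = clusters[k] + clusters[k + 1]
        del clusters[k + 1]
    level_of = np.full(means.size, np.nan)
    for cl in clusters:
        level_of[cl] = center(cl)
    return level_of


def smooth_levels(
    seg: Segmentation,
    merge_threshold: float = 0.25,
    level_gap: float = 0.25,
    anchor_cn: float = 2.0,
) -> CNVProfile:
    """Merge near-identical adjacent segments, cluster means into discrete
    levels, and anchor the modal level at copy number ``anchor_cn``.

    ``merge_threshold`` (mean-1 scale) controls the local adjacent-segment
    merge; ``level_gap`` is the minimum separation between genome-wide level
    centers — half the spacing of consecutive copy-number states as they
    appear on the corrected scale, so distinct states stay separate while
    within-state segmentation jitter collapses.
    """
    codes = seg.bins.chrom_codes
    merged = _merge_adjacent(seg.segments, codes, merge_threshold)
    means = np.array([m for _, _, m in merged])
    lengths = np.array([e - s for s, e, _ in merged], dtype=float)
    levels = _cluster_levels(means, lengths, gap=level_gap)
    # modal level = the one covering the most bins
    ok = np.isfinite(levels)
    uniq = np.unique(levels[ok])
    cover = np.array([lengths[ok][levels[ok] == u].sum() for u in uniq])
    modal = uniq[np.argmax(cover)]
    K = np.full(seg.bins.n, np.nan)
    for (s, e, _), lvl in zip(merged, levels):
        K[s:e] = max(lvl / modal * anchor_cn, 0.0)  # residual noise can dip below 0
    # masked bins inherit no level; fill for profile construction then re-mask
    filled = K.copy()
    if np.any(~np.isfinite(filled)):
        ok_idx = np.flatnonzero(np.isfinite(filled))
        for i in np.flatnonzero(~np.isfinite(filled)):
            same = ok_idx[codes[ok_idx] == codes[i]]
            if same.size:
                filled[i] = filled[same[np.argmin(np.abs(same - i))]]
            else:
                filled[i] = anchor_cn
    prof = CNVProfile.from_levels(filled, seg.bins)
    seg.smoothed_levels = levels
    return prof


def call_cnv(
    C: ContactMatrix,
    bins: GenomeBins | None = None,
    mask: np.ndarray | None = None,
    mode: str = "all",
    penalty: float | None = None,
    merge_threshold: float = 0.25,
    level_gap: float = 0.25,
) -> tuple[CNVProfile, Segmentation, CoverageProfile]:
    """Full Hi-C copy-number calling pipeline on a raw contact map."""
    bins = bins or C.bins
    prof = one_d_profile(C, mode=mode, mask=mask)
    exposure = expected_coverage(C, mask=mask)
    corrected = correct_features(prof, bins, exposure=exposure)
    seg = segment(corrected, bins, penalty=penalty)
    cnv = smooth_levels(seg, merge_threshold=merge_threshold, level_gap=level_gap)
    return cnv, seg, corrected


def random_cnv_profile(
    bins: GenomeBins,
    n_breakpoints: int | None = None,
    mean_breakpoints: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> CNVProfile:
    """Random piecewise-constant integer profile for simulation studies.

    Procedure: draw a number of breakpoints along the genome (Poisson with
    mean ``mean_breakpoints`` unless ``n_breakpoints`` fixes it); drop
    breakpoints landing in unmappable bins; draw each segment level as
    1 + Poisson(1); redraw any level equal to its left neighbour on the
    same chromosome.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = bins.n
    codes = bins.chrom_codes
    n_bp = int(n_breakpoints) if n_breakpoints is not None else int(rng.poisson(mean_breakpoints))
    # candidate interior positions (a breakpoint at bin i starts a new segment at i)
    candidates = np.flatnonzero(np.arange(n) > 0)
    candidates = candidates[codes[candidates] == codes[candidates - 1]]
    n_bp = min(n_bp, candidates.size)
    bps = rng.choice(candidates, size=n_bp, replace=False) if n_bp else np.array([], dtype=np.int64)
    if bins.mappable_flag is not None:
        bps = bps[bins.mappable_flag[bps]]
    starts = np.unique(np.concatenate(([0], np.flatnonzero(np.diff(codes)) + 1, bps)))
    bounds = np.append(starts, n)
    K = np.empty(n)
    prev_level = None
    prev_chrom = None
    for k in range(starts.size):
        s, e = int(bounds[k]), int(bounds[k + 1])
        lvl = 1 + int(rng.poisson(1.0))
        if prev_chrom is not None and codes[s] == prev_chrom:
            while lvl == prev_level:
                lvl = 1 + int(rng.poisson(1.0))
        K[s:e] = lvl
        prev_level, prev_chrom = lvl, codes[s]
    return CNVProfile.from_levels(K, bins)
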