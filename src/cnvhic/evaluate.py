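"""Metrics comparing normalized maps and called copy-number profiles.

Block-average errors quantify how much copy-number structure remains in a
normalized map relative to a ground-truth (CNV-free) map; breakpoint
recall/precision and profile correlations score copy-number calls against
a known profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .core import CNVProfile, ContactMatrix, GenomeBins, block_id_matrix


@dataclass
class ErrorMatrix:
    """Per-block mean log2 error, with an expanded n x n view."""

    values: np.ndarray  # per block id; nan for all-masked blocks
    ids: np.ndarray

    def expand(self) -> np.ndarray:
        return self.values[self.ids]

    def sum_squares(self) -> float:
        v = self.values[np.isfinite(self.values)]
        return float(np.dot(v, v))


def block_average_error(
    N: ContactMatrix,
    truth: ContactMatrix,
    profile: CNVProfile,
    mask: np.ndarray | None = None,
) -> ErrorMatrix:
    """Per-block log2 ratio of block-mean N to block-mean truth.

    Both matrices are first rescaled to equal totals over the shared valid
    entries, so the metric is invariant to a global rescaling of either
    map; 0 means perfect agreement within a block.  Comparing block means
    (rather than averaging per-entry log ratios) keeps sparse blocks
    usable: zero entries contribute to the mean instead of being dropped,
    which would bias the error of weakly covered blocks upward.  Blocks
    with no valid entries, or a zero mean on either side, are missing.
    """
    if N.n != truth.n:
        raise ValueError("matrices are on different bin sets")
    a, b = N.counts, truth.counts
    valid = np.isfinite(a) & np.isfinite(b) & (b >= 0)
    if mask is not None:
        keep = ~mask
        valid &= keep[:, None] & keep[None, :]
    scale = b[valid].sum() / a[valid].sum()
    ids, n_blocks = block_id_matrix(profile)
    values = np.full(n_blocks, np.nan)
    for k in range(n_blocks):
        sel = (ids == k) & valid
        if np.any(sel):
            ma, mb = a[sel].mean() * scale, b[sel].mean()
            if ma > 0 and mb > 0:
                values[k] = np.log2(ma / mb)
    return ErrorMatrix(values, ids)


def breakpoint_prf(
    called: CNVProfile,
    truth: CNVProfile,
    bins: GenomeBins,
    tol_bins: int = 2,
) -> tuple[float, float]:
    """Breakpoint recall and precision under greedy one-to-one matching.

    Only interior copy-number change points count (chromosome starts are
    implicit in both profiles and excluded).  A true breakpoint is recalled
    if an unmatched called one lies within ``tol_bins``; precision uses the
    same matching.  Empty call or truth sets score 0 on the undefined side.
    """
    t = truth.interior_breakpoints(bins)
    c = called.interior_breakpoints(bins)
    if t.size == 0 and c.size == 0:
        return 1.0, 1.0
    if t.size == 0 or c.size == 0:
        return 0.0, 0.0
    # greedy nearest: match pairs in order of increasing distance
    pairs = sorted(
        ((abs(int(ti) - int(cj)), i, j) for i, ti in enumerate(t) for j, cj in enumerate(c))
    )
    used_t: set[int] = set()
    used_c: set[int] = set()
    tp = 0
    for d, i, j in pairs:
        if d > tol_bins:
            break
        if i in used_t or j in used_c:
            continue
        used_t.add(i)
        used_c.add(j)
        tp += 1
    return tp / t.size, tp / c.size


def profile_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman correlation over bins where both profiles are finite."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("profiles have different lengths")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 shared unmasked bins")
    if np.all(a[ok] == a[ok][0]) or np.all(b[ok] == b[ok][0]):
        return np.nan
    rho = spearmanr(a[ok], b[ok]).statistic
    return float(rho)
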