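"""Impose a segmental copy-number profile on a diploid Hi-C map.

In a diploid map the expected contact count between two same-chromosome loci
decomposes into 2 cis contacts (within each homolog) plus 2 contacts between
the homologs; a trans pair sums 4 inter-homolog contacts.  Assuming
chromosome territories, inter-homolog contacts are estimated by the
trans background, so the copy-number state (K_i, K_j) rescales the expected
count of each pair by a ratio p_ij.  Simulated counts are then drawn by
binomial thinning of the observed diploid counts with probability
p_ij / max(p_ij) — thinning preserves Poisson / negative-binomial count laws,
at the cost that simulated counts can only shrink.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import (
    BlockPair,
    CNVProfile,
    ContactMatrix,
    block_id_matrix,
    cis_mask,
)

KPolicy = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


@dataclass
class ExpectedDecomposition:
    """Expected-count decomposition of a diploid map."""

    E_trans: float
    E_cis: np.ndarray  # same-chromosome pairs; nan for trans pairs
    E_rearranged: np.ndarray | None = None


@dataclass
class ScalingFactors:
    """Per-pair enrichment/depletion ratios p and their block-smoothed form."""

    p: np.ndarray
    p_smoothed: np.ndarray
    max_p: float


def default_k_policy(K_i: np.ndarray, K_j: np.ndarray, same_segment: np.ndarray) -> np.ndarray:
    """Number of true-cis interactions k for a same-chromosome pair.

    Within one segment every copy pairs with itself, so k = K_i = K_j.
    Across segments of the same chromosome the segments are assumed
    non-tandem, so the two parental homologs contribute k = 2 cis contacts,
    capped by min(K_i, K_j) when a loss removes a homolog.
    """
    kmin = np.minimum(K_i, K_j)
    k = np.where(kmin < 2, kmin, 2.0)
    return np.where(same_segment, K_i, k)


def estimate_trans_background(
    C: ContactMatrix, mask: np.ndarray | None = None, nonzero_only: bool = False
) -> float:
    """Median trans contact count over unmasked bin pairs.

    ``nonzero_only`` restricts the median to nonzero entries (useful for
    sparse deep maps where the all-entries median collapses to 0).
    """
    codes = C.bins.chrom_codes
    if np.unique(codes).size < 2:
        raise ValueError("trans background undefined for a single chromosome")
    trans = codes[:, None] != codes[None, :]
    if mask is not None:
        keep = ~mask
        trans &= keep[:, None] & keep[None, :]
    vals = C.counts[trans]
    vals = vals[np.isfinite(vals)]
    if nonzero_only:
        vals = vals[vals > 0]
    return float(np.median(vals))


def cis_component(C: ContactMatrix, E_trans: float) -> np.ndarray:
    """E_cis = max(C - E_trans, 0) on same-chromosome pairs, nan on trans."""
    E_cis = np.maximum(C.counts - E_trans, 0.0)
    E_cis[~cis_mask(C.bins)] = np.nan
    return E_cis


def expected_rearranged(
    C: ContactMatrix,
    profile: CNVProfile,
    decomposition: ExpectedDecomposition,
    k_policy: KPolicy = default_k_policy,
) -> np.ndarray:
    """Expected counts of the rearranged genome.

    Same chromosome: ``E = k * E_cis + (K_i K_j - k) * E_trans`` with k from
    the policy; different chromosomes: ``E = K_i K_j * E_trans``.
    """
    K = profile.K
    if K.size != C.n:
        raise ValueError("profile/matrix size mismatch")
    Ki = K[:, None]
    Kj = K[None, :]
    seg = profile.segment_of_bin()
    same_seg = seg[:, None] == seg[None, :]
    cis = cis_mask(C.bins)
    k = k_policy(np.broadcast_to(Ki, (C.n, C.n)), np.broadcast_to(Kj, (C.n, C.n)), same_seg)
    if np.any(cis & (Ki * Kj < k)):
        raise ValueError("k_policy inconsistent: K_i*K_j < k for some cis pair")
    Et = decomposition.E_trans
    E = np.where(
        cis,
        k * decomposition.E_cis + (Ki * Kj - k) * Et,
        Ki * Kj * Et,
    )
    return E


def scaling_factors(
    C: ContactMatrix,
    profile: CNVProfile,
    mask: np.ndarray | None = None,
    k_policy: KPolicy = default_k_policy,
    nonzero_trans_median: bool = False,
) -> ScalingFactors:
    """Per-pair enrichment ratios p, block-median smoothed.

    Cis: ``p = E / (2 E_cis + 2 E_trans)``; trans: ``p = K_i K_j / 4``.
    Smoothing replaces each entry by the median of its copy-number block,
    which also fills entries whose denominator vanished.
    """
    Et = estimate_trans_background(C, mask=mask, nonzero_only=nonzero_trans_median)
    E_cis = cis_component(C, Et)
    deco = ExpectedDecomposition(E_trans=Et, E_cis=E_cis)
    E = expected_rearranged(C, profile, deco, k_policy=k_policy)
    K = profile.K
    cis = cis_mask(C.bins)
    denom = 2.0 * E_cis + 2.0 * Et
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(cis, E / denom, K[:, None] * K[None, :] / 4.0)
    p[cis & (denom == 0)] = np.nan

    valid = np.isfinite(p)
    if mask is not None:
        keep = ~mask
        valid &= keep[:, None] & keep[None, :]
    ids, n_blocks = block_id_matrix(profile)
    p_smoothed = np.full_like(p, np.nan)
    for b in range(n_blocks):
        in_block = ids == b
        sel = in_block & valid
        if np.any(sel):
            p_smoothed[in_block] = np.median(p[sel])
    max_p = float(np.nanmax(p_smoothed[valid])) if np.any(valid) else np.nan
    return ScalingFactors(p=p, p_smoothed=p_smoothed, max_p=max_p)


def binomial_downsample(
    C: ContactMatrix, factors: ScalingFactors, seed: int | np.random.Generator = 0
) -> ContactMatrix:
    """Binomial thinning of C with probability p_smoothed / max_p.

    One draw per unordered pair, mirrored, so symmetry is exact; a fixed
    seed gives a reproducible matrix.  Simulated counts never exceed C.
    """
    if not C.is_integer():
        raise ValueError("binomial downsampling requires integer counts")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prob = factors.p_smoothed / factors.max_p
    if np.nanmin(prob) < 0 or np.nanmax(prob) > 1 + 1e-12:
        raise ValueError("smoothed scaling factors yield invalid probabilities")
    prob = np.clip(prob, 0.0, 1.0)
    n = C.n
    iu = np.triu_indices(n)
    counts = C.counts[iu].astype(np.int64)
    pr = prob[iu]
    out_u = np.where(np.isfinite(pr), 0, 0).astype(np.int64)
    ok = np.isfinite(pr)
    out_u[ok] = rng.binomial(counts[ok], pr[ok])
    sim = np.zeros((n, n))
    sim[iu] = out_u
    sim = sim + np.triu(sim, 1).T
    return ContactMatrix(sim, C.bins, is_normalized=False)


def simulate_cnv_map(
    C: ContactMatrix,
    profile: CNVProfile,
    mask: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    k_policy: KPolicy = default_k_policy,
) -> tuple[ContactMatrix, ScalingFactors]:
    """One-call pipeline: scaling factors then binomial thinning."""
    factors = scaling_factors(C, profile, mask=mask, k_policy=k_policy)
    sim = binomial_downsample(C, factors, seed=seed)
    return sim, factors
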