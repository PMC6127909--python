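"""CAIC: estimate and remove the copy-number block bias from a LOIC map.

The LOIC-normalized map is modelled as the product of a block-constant
copy-number effect B (one value per pair of CNV segments) and a monotone
distance-decay curve e(s):

    min over (e, B) of  sum_ij (N^LOIC_ij - B_ij e(s(i,j)))^2
    subject to          B block-constant, e non-increasing

solved by alternating exact conditional minimizers: a weighted isotonic
regression for e given B, and the per-block closed-form least-squares ratio
for B given e.  Trans pairs share one expected value e_trans and are fitted
independently of the cis decay.  B and e are each identifiable only up to a
scalar; the convention here fixes B = 1 on the modal-level (diploid-by-
diploid) blocks.  The corrected map is N^CAIC = N^LOIC / B, which by
construction satisfies N^CAIC ~= e(s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .core import CNVProfile, ContactMatrix, block_id_matrix, distance_matrix


@dataclass
class DecayCurve:
    """Non-increasing expected contact count per genomic distance."""

    distances: np.ndarray  # sorted unique cis distances (bp)
    e: np.ndarray  # expected count per distance, non-increasing
    e_trans: float = np.nan

    def __call__(self, s: np.ndarray) -> np.ndarray:
        """Evaluate e at distances s (bp); inf maps to e_trans."""
        s = np.asarray(s, dtype=float)
        out = np.interp(s, self.distances, self.e)
        out = np.where(np.isinf(s), self.e_trans, out)
        return out


@dataclass
class BlockBias:
    """Block-constant copy-number effect; one scalar per block pair."""

    values: np.ndarray  # per block id (block_id_matrix order); nan if undefined
    ids: np.ndarray  # n x n block-id matrix

    def expand(self) -> np.ndarray:
        return self.values[self.ids]


@dataclass
class _Workspace:
    """Precomputed pair indexing shared by the alternating fits."""

    iu: tuple  # upper-triangle pair indices actually fitted
    is_cis: np.ndarray
    dist_group: np.ndarray  # per cis pair, merged-distance group id
    group_dist: np.ndarray  # representative distance per group
    n_groups: int
    block: np.ndarray  # per pair, block id
    n_blocks: int
    dist: np.ndarray  # per pair, genomic distance


def _build_workspace(
    N: ContactMatrix,
    profile: CNVProfile,
    mask: np.ndarray | None,
    include_diagonal: bool,
    min_pairs_per_distance: int = 3,
) -> tuple[_Workspace, np.ndarray]:
    n = N.n
    d = distance_matrix(N.bins)
    ids, n_blocks = block_id_matrix(profile)
    iu = np.triu_indices(n, k=0 if include_diagonal else 1)
    vals = N.counts[iu]
    keep = np.isfinite(vals)
    if mask is not None:
        km = ~mask
        keep &= km[iu[0]] & km[iu[1]]
    iu = (iu[0][keep], iu[1][keep])
    vals = vals[keep]
    dist = d[iu]
    is_cis = np.isfinite(dist)
    # merge sparse distances (fewer unmasked pairs than the floor) into the
    # next larger distance before the isotonic fit
    cis_d = dist[is_cis]
    uniq, counts = np.unique(cis_d, return_counts=True)
    group_of_uniq = np.empty(uniq.size, dtype=np.int64)
    g = -1
    carried = 0
    rep: list[float] = []
    for k in range(uniq.size):
        if carried == 0:
            g += 1
            rep.append(uniq[k])
        group_of_uniq[k] = g
        carried += counts[k]
        if carried >= min_pairs_per_distance:
            carried = 0
    if carried:  # trailing sparse distances fold into the last group
        group_of_uniq[group_of_uniq == g] = max(g - 1, 0)
        if g > 0:
            rep.pop()
    n_groups = int(group_of_uniq.max()) + 1 if uniq.size else 0
    lookup = dict(zip(uniq, group_of_uniq))
    dist_group = np.full(dist.size, -1, dtype=np.int64)
    dist_group[is_cis] = [lookup[x] for x in cis_d]
    ws = _Workspace(
        iu=iu,
        is_cis=is_cis,
        dist_group=dist_group,
        group_dist=np.asarray(rep, dtype=float),
        n_groups=n_groups,
        block=ids[iu],
        n_blocks=n_blocks,
        dist=dist,
    )
    return ws, vals


def _fit_decay(vals: np.ndarray, B_pair: np.ndarray, ws: _Workspace) -> DecayCurve:
    """Exact e-minimizer given B: per merged distance, e = sum(B N)/sum(B^2),
    then weighted non-increasing isotonic regression over distance."""
    cis = ws.is_cis
    g = ws.dist_group[cis]
    bn = np.bincount(g, weights=(B_pair * vals)[cis], minlength=ws.n_groups)
    bb = np.bincount(g, weights=(B_pair**2)[cis], minlength=ws.n_groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(bb > 0, bn / bb, 0.0)
    if ws.n_groups > 1:
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        e = iso.fit_transform(ws.group_dist, ratio, sample_weight=np.maximum(bb, 1e-300))
    else:
        e = ratio
    e = np.maximum(e, 0.0)
    tr = ~cis
    if np.any(tr):
        num = float((B_pair[tr] * vals[tr]).sum())
        den = float((B_pair[tr] ** 2).sum())
        e_trans = num / den if den > 0 else np.nan
    else:
        e_trans = np.nan
    return DecayCurve(ws.group_dist, e, e_trans)


def _fit_block_bias(vals: np.ndarray, e_pair: np.ndarray, ws: _Workspace) -> np.ndarray:
    """Exact B-minimizer given e: per block, B = sum(N e)/sum(e^2)."""
    ne = np.bincount(ws.block, weights=vals * e_pair, minlength=ws.n_blocks)
    ee = np.bincount(ws.block, weights=e_pair**2, minlength=ws.n_blocks)
    with np.errstate(invalid="ignore", divide="ignore"):
        B = np.where(ee > 0, ne / ee, np.nan)
    return np.maximum(B, 0.0, where=np.isfinite(B), out=B)


def fit_decay(
    N: ContactMatrix,
    profile: CNVProfile,
    B: BlockBias | None = None,
    mask: np.ndarray | None = None,
    include_diagonal: bool = False,
) -> DecayCurve:
    """Weighted isotonic fit of the distance decay given a block bias."""
    ws, vals = _build_workspace(N, profile, mask, include_diagonal)
    B_pair = np.ones(vals.size) if B is None else B.values[ws.block]
    return _fit_decay(vals, np.nan_to_num(B_pair, nan=0.0), ws)


def fit_block_bias(
    N: ContactMatrix,
    profile: CNVProfile,
    e: DecayCurve,
    mask: np.ndarray | None = None,
    include_diagonal: bool = False,
) -> BlockBias:
    """Closed-form per-block least-squares bias given a decay curve."""
    ws, vals = _build_workspace(N, profile, mask, include_diagonal)
    e_pair = e(ws.dist)
    values = _fit_block_bias(vals, np.nan_to_num(e_pair, nan=0.0), ws)
    ids, _ = block_id_matrix(profile)
    return BlockBias(values, ids)


def _modal_rescale(
    B_vals: np.ndarray, e: DecayCurve, profile: CNVProfile, ws: _Workspace
) -> tuple[np.ndarray, DecayCurve]:
    """Fix the B/e scale ambiguity: modal-level blocks get B = 1.

    Cis and trans parts are rescaled by separate scalars, matching their
    independent fits; every block is purely cis or purely trans because
    segments never span a chromosome boundary.
    """
    seg_levels = np.array([lvl for _, _, lvl in profile.segments])
    seg_len = np.array([e_ - s_ for s_, e_, _ in profile.segments], dtype=float)
    lvls, inv = np.unique(seg_levels, return_inverse=True)
    modal = lvls[np.argmax(np.bincount(inv, weights=seg_len))]
    m = len(profile.segments)
    pair_levels = np.ones(ws.n_blocks)  # la*lb per block id
    is_modal = np.zeros(ws.n_blocks, dtype=bool)
    for a in range(m):
        for b in range(a, m):
            bid = a * m - a * (a - 1) // 2 + (b - a)
            pair_levels[bid] = seg_levels[a] * seg_levels[b]
            is_modal[bid] = np.isclose(seg_levels[a], modal) and np.isclose(
                seg_levels[b], modal
            )
    # fitted-pair counts per block: weights for the anchor average, and the
    # cis/trans identity of each block
    w_cis = np.bincount(ws.block[ws.is_cis], minlength=ws.n_blocks).astype(float)
    w_tr = np.bincount(ws.block[~ws.is_cis], minlength=ws.n_blocks).astype(float)
    B_vals = B_vals.copy()
    e_vals, e_trans = e.e.copy(), e.e_trans
    usable = np.isfinite(B_vals) & (B_vals > 0)
    for w, is_cis_part in ((w_cis, True), (w_tr, False)):
        ww = w * usable * is_modal
        if ww.sum() > 0:
            c = float(np.average(np.nan_to_num(B_vals), weights=ww))
        else:
            # no informative modal-by-modal block in this part: project every
            # block to its modal equivalent via the copy-number product ratio
            ww = w * usable
            if ww.sum() <= 0:
                continue
            proj = np.nan_to_num(B_vals * modal**2 / pair_levels)
            c = float(np.average(proj, weights=ww))
        if c <= 0:
            continue
        B_vals[w > 0] /= c
        if is_cis_part:
            e_vals = e_vals * c
        else:
            e_trans = e_trans * c
    return B_vals, DecayCurve(e.distances, e_vals, e_trans)


def caic(
    C_or_N: ContactMatrix,
    profile: CNVProfile,
    mask: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
    include_diagonal: bool = False,
    precomputed_loic: ContactMatrix | None = None,
) -> tuple[ContactMatrix, BlockBias, DecayCurve]:
    """Alternating estimation of (B, e) from a LOIC map; returns N_loic / B.

    Accepts either a raw matrix (LOIC is run first) or a precomputed LOIC
    map via ``precomputed_loic`` / an ``is_normalized`` input.
    """
    if precomputed_loic is not None:
        N = precomputed_loic
    elif C_or_N.is_normalized:
        N = C_or_N
    else:
        from .balance import loic as _loic

        N = _loic(C_or_N, profile, mask=mask).N
    ws, vals = _build_workspace(N, profile, mask, include_diagonal)
    B_pair = np.ones(vals.size)
    B_vals = np.ones(ws.n_blocks)
    e = _fit_decay(vals, B_pair, ws)
    prev_obj = np.inf
    for _ in range(max_iter):
        e_pair = e(ws.dist)
        B_vals = _fit_block_bias(vals, e_pair, ws)
        B_pair = np.nan_to_num(B_vals[ws.block], nan=0.0)
        e = _fit_decay(vals, B_pair, ws)
        e_pair = e(ws.dist)
        resid = vals - B_pair * e_pair
        obj = float(np.dot(resid, resid))
        if not np.isfinite(obj):
            raise FloatingPointError("CAIC objective is not finite")
        if prev_obj - obj < tol * max(prev_obj, 1e-300):
            prev_obj = obj
            break
        prev_obj = obj
    B_vals, e = _modal_rescale(B_vals, e, profile, ws)
    ids, _ = block_id_matrix(profile)
    B = BlockBias(B_vals, ids)
    with np.errstate(invalid="ignore", divide="ignore"):
        corrected = N.counts / B.expand()
    corrected[~np.isfinite(corrected)] = np.nan
    # keep symmetry and masked-bin missing-ness of the input
    N_caic = ContactMatrix(corrected, N.bins, is_normalized=True)
    return N_caic, B, e


def observed_over_expected(
    N: ContactMatrix, e: DecayCurve, mask: np.ndarray | None = None
) -> ContactMatrix:
    """O/E map: N / e(s), with the trans expectation for trans pairs."""
    d = distance_matrix(N.bins)
    exp = e(d)
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(exp > 0, N.counts / exp, np.nan)
    if mask is not None:
        oe[mask, :] = np.nan
        oe[:, mask] = np.nan
    return ContactMatrix(oe, N.bins, is_normalized=True)
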