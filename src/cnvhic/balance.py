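"""Matrix balancing: ICE and its copy-number-aware generalization LOIC.

Both methods factor the raw map as ``C_ij = beta_i beta_j N_ij`` and choose
the per-bin biases beta so that the normalized row sums match a target:
a single genome-wide constant under ICE's equal-visibility assumption, or
the mean raw total of each copy-number group under LOIC's local
equal-visibility assumption (bins sharing a copy-number level interact
equally much).  With a constant profile LOIC's target collapses to ICE's,
so the two solve the same balancing problem.

The solver is Sinkhorn–Knopp-style symmetric scaling: per sweep,
``beta <- beta * sqrt(rowsum / target)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CNVProfile, ContactMatrix


@dataclass
class BalanceResult:
    N: ContactMatrix
    beta: np.ndarray
    target: np.ndarray
    n_iter: int
    converged: bool


def _balance_to_target(
    counts: np.ndarray,
    target: np.ndarray,
    mask: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Symmetric scaling of the unmasked submatrix toward row-sum targets."""
    keep = ~mask
    sub = counts[np.ix_(keep, keep)].astype(float)
    t = target[keep]
    if np.any(t <= 0):
        raise ValueError("row-sum targets must be positive on unmasked bins")
    beta = np.ones(sub.shape[0])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        N = sub / np.outer(beta, beta)
        r = N.sum(axis=1)
        dev = np.max(np.abs(r / t - 1.0))
        if dev < tol:
            converged = True
            break
        beta *= np.sqrt(r / t)
    N = sub / np.outer(beta, beta)
    # total-count preservation (targets already sum to the raw total; this
    # removes the residual convergence slack)
    scale = sub.sum() / N.sum()
    N *= scale
    beta /= np.sqrt(scale)
    n = counts.shape[0]
    full_N = np.full((n, n), np.nan)
    full_N[np.ix_(keep, keep)] = N
    full_beta = np.full(n, np.nan)
    full_beta[keep] = beta
    return full_N, full_beta, it, converged


def ice(
    C: ContactMatrix,
    mask: np.ndarray | None = None,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> BalanceResult:
    """Iterative correction: equal visibility for every unmasked bin.

    Post-normalization, every unmasked row sum equals the mean unmasked raw
    row sum (within ``tol`` relative); equivalent to LOIC with a constant
    copy-number profile.
    """
    if mask is None:
        mask = np.zeros(C.n, dtype=bool)
    rowsum = np.nansum(C.counts, axis=1)
    t_val = rowsum[~mask].mean()
    target = np.full(C.n, t_val)
    N, beta, it, conv = _balance_to_target(C.counts, target, mask, max_iter, tol)
    target = np.where(mask, np.nan, target)
    return BalanceResult(
        ContactMatrix(N, C.bins, is_normalized=True), beta, target, it, conv
    )


def loic(
    C: ContactMatrix,
    profile: CNVProfile,
    mask: np.ndarray | None = None,
    max_iter: int = 300,
    tol: float = 1e-8,
    level_decimals: int = 2,
) -> BalanceResult:
    """Local iterative correction: equal visibility within copy-number groups.

    Each unmasked bin i is balanced so its normalized total equals the mean
    raw total over unmasked bins sharing its copy-number level (levels
    compared after rounding to ``level_decimals``, since estimated profiles
    are continuous).
    """
    if profile.K.size != C.n:
        raise ValueError("profile/matrix size mismatch")
    if mask is None:
        mask = np.zeros(C.n, dtype=bool)
    levels = np.round(profile.K, level_decimals)
    rowsum = np.nansum(C.counts, axis=1)
    target = np.full(C.n, np.nan)
    for lvl in np.unique(levels):
        sel = levels == lvl
        sel_keep = sel & ~mask
        if np.any(sel) and not np.any(sel_keep):
            raise ValueError(
                f"copy-number level {lvl} has no unmasked bins to define its target"
            )
        if np.any(sel_keep):
            target[sel] = rowsum[sel_keep].mean()
    N, beta, it, conv = _balance_to_target(C.counts, target, mask, max_iter, tol)
    target = np.where(mask, np.nan, target)
    return BalanceResult(
        ContactMatrix(N, C.bins, is_normalized=True), beta, target, it, conv
    )
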