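"""Shared data model for binned Hi-C maps.

A genome is partitioned into fixed-width bins (0-based, half-open
``[start, end)`` coordinates, concatenated genome-wide in chromosome order).
A Hi-C experiment is summarized by a symmetric ``n x n`` matrix of contact
counts between bins.  A copy-number profile is a piecewise-constant per-bin
vector ``K``; its segments induce a partition of the matrix into rectangular
blocks, which is the unit at which copy-number effects act throughout the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel genomic distance for inter-chromosomal bin pairs.
INFINITE = np.inf


@dataclass
class GenomeBins:
    """Ordered fixed-width genomic bins with optional per-bin feature tracks.

    Parameters
    ----------
    chrom
        Chromosome label per bin; bins must be grouped by chromosome and
        sorted by start within each chromosome.
    start, end
        0-based half-open coordinates; within a chromosome bins tile
        contiguously with one constant width.
    gc, mappability
        Fractions in [0, 1], or None when unavailable.
    eff_frag_len
        Mean effective restriction-fragment length per bin (bp, >= 0).
    mappable_flag
        Boolean per bin; unmappable bins are excluded from segmentation
        targets and breakpoint placement.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray | None = None
    mappability: np.ndarray | None = None
    eff_frag_len: np.ndarray | None = None
    mappable_flag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        n = self.chrom.size
        if not (self.start.size == self.end.size == n):
            raise ValueError("chrom/start/end length mismatch")
        if np.any(self.end <= self.start):
            raise ValueError("bins must satisfy start < end")
        for name in ("gc", "mappability"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.size != n:
                    raise ValueError(f"{name} length mismatch")
                if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                    raise ValueError(f"{name} must lie in [0, 1]")
                setattr(self, name, v)
        if self.eff_frag_len is not None:
            v = np.asarray(self.eff_frag_len, dtype=float)
            if v.size != n or np.nanmin(v) < 0:
                raise ValueError("eff_frag_len must be length-n and >= 0")
            self.eff_frag_len = v
        if self.mappable_flag is not None:
            self.mappable_flag = np.asarray(self.mappable_flag, dtype=bool)
        # contiguity / constant width within each chromosome
        codes = self.chrom_codes
        for c in np.unique(codes):
            sel = codes == c
            s, e = self.start[sel], self.end[sel]
            if np.any(np.diff(s) <= 0):
                raise ValueError("bins not sorted within chromosome")
            if s.size > 1 and (np.any(s[1:] != e[:-1]) or len(set(e - s)) != 1):
                raise ValueError("bins must tile contiguously with constant width")

    @property
    def n(self) -> int:
        return self.chrom.size

    def __len__(self) -> int:
        return self.n

    @property
    def chrom_codes(self) -> np.ndarray:
        """Integer chromosome code per bin, in order of first appearance."""
        _, idx = np.unique(self.chrom, return_index=True)
        order = {self.chrom[i]: k for k, i in enumerate(sorted(idx))}
        return np.array([order[c] for c in self.chrom], dtype=np.int64)

    @property
    def bin_size(self) -> int:
        return int(self.end[0] - self.start[0])

    @property
    def centers(self) -> np.ndarray:
        return (self.start + self.end) / 2.0

    def chromosomes(self) -> list:
        seen: list = []
        for c in self.chrom:
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class ContactMatrix:
    """Symmetric binned contact-count matrix with its bin annotation."""

    counts: np.ndarray
    bins: GenomeBins
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = self.bins.n
        if self.counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}")
        finite = np.isfinite(self.counts)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            self.counts[finite & finite.T], self.counts.T[finite & finite.T]
        ):
            raise ValueError("contact matrix must be symmetric")
        if np.nanmin(self.counts) < 0:
            raise ValueError("contact counts must be non-negative")

    @property
    def n(self) -> int:
        return self.bins.n

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.counts.copy(), self.bins, self.is_normalized)

    def is_integer(self) -> bool:
        c = self.counts[np.isfinite(self.counts)]
        return bool(np.all(c == np.round(c)))


@dataclass
class CNVProfile:
    """Piecewise-constant per-bin copy-number profile.

    ``segments`` is a list of ``(start_bin, end_bin, level)`` half-open bin
    ranges tiling ``[0, n)``; no segment spans a chromosome boundary.
    ``breakpoints`` are the bin indices where the level changes or a new
    chromosome starts (index 0 included).
    """

    K: np.ndarray
    segments: list = field(default_factory=list)
    breakpoints: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if np.nanmin(self.K) < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.segments:
            pos = 0
            for s, e, lvl in self.segments:
                if s != pos or e <= s:
                    raise ValueError("segments must tile [0, n) without gaps")
                if not np.allclose(self.K[s:e], lvl, equal_nan=True):
                    raise ValueError("K not constant within a segment")
                pos = e
            if pos != self.K.size:
                raise ValueError("segments do not cover all bins")
        if self.breakpoints is not None:
            self.breakpoints = np.asarray(self.breakpoints, dtype=np.int64)

    @classmethod
    def from_levels(cls, K, bins: GenomeBins) -> "CNVProfile":
        """Build segments/breakpoints from a per-bin level vector.

        Chromosome starts are implicit breakpoints: a run of equal levels
        crossing a chromosome boundary is split there.
        """
        K = np.asarray(K, dtype=float)
        if K.size != bins.n:
            raise ValueError("profile/bins length mismatch")
        codes = bins.chrom_codes
        change = np.zeros(K.size, dtype=bool)
        change[0] = True
        change[1:] = (K[1:] != K[:-1]) | (codes[1:] != codes[:-1])
        bps = np.flatnonzero(change)
        bounds = np.append(bps, K.size)
        segments = [
            (int(bounds[i]), int(bounds[i + 1]), float(K[bounds[i]]))
            for i in range(bps.size)
        ]
        return cls(K=K, segments=segments, breakpoints=bps)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_of_bin(self) -> np.ndarray:
        """Segment index per bin."""
        out = np.empty(self.K.size, dtype=np.int64)
        for k, (s, e, _) in enumerate(self.segments):
            out[s:e] = k
        return out

    def interior_breakpoints(self, bins: GenomeBins) -> np.ndarray:
        """Breakpoints where the level actually changes, excluding chromosome
        starts — the change points evaluated by breakpoint recall/precision."""
        codes = bins.chrom_codes
        bps = []
        for s, _, _ in self.segments[1:]:
            if codes[s] == codes[s - 1] and self.K[s] != self.K[s - 1]:
                bps.append(s)
        return np.asarray(bps, dtype=np.int64)


@dataclass(frozen=True)
class BlockPair:
    """Unordered pair of CNV segments and the matrix block they delimit."""

    block_a: int
    block_b: int
    rows: tuple  # (start, end) bin range of segment block_a
    cols: tuple  # (start, end) bin range of segment block_b
    level_a: float = np.nan
    level_b: float = np.nan
    is_trans: bool = False


def genomic_distance(bins: GenomeBins, i: int, j: int) -> float:
    """Distance in bp between bin centers; INFINITE across chromosomes."""
    n = bins.n
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"bin index out of range: ({i}, {j})")
    if bins.chrom[i] != bins.chrom[j]:
        return INFINITE
    c = bins.centers
    return float(abs(c[i] - c[j]))


def distance_matrix(bins: GenomeBins) -> np.ndarray:
    """Dense n x n genomic-distance matrix (bp; inf for trans pairs)."""
    c = bins.centers
    d = np.abs(c[:, None] - c[None, :])
    codes = bins.chrom_codes
    d[codes[:, None] != codes[None, :]] = INFINITE
    return d


def cis_mask(bins: GenomeBins) -> np.ndarray:
    codes = bins.chrom_codes
    return codes[:, None] == codes[None, :]


def block_partition(profile: CNVProfile, bins: GenomeBins | None = None) -> list:
    """All unordered segment pairs (including a segment with itself).

    Every matrix entry (i, j) belongs to exactly one block pair; block
    boundaries coincide with CNV breakpoints and chromosome boundaries.
    """
    if not profile.segments:
        raise ValueError("profile has no segments; use CNVProfile.from_levels")
    if bins is not None and profile.K.size != bins.n:
        raise ValueError("profile/bins length mismatch")
    codes = bins.chrom_codes if bins is not None else None
    out = []
    segs = profile.segments
    for a in range(len(segs)):
        sa, ea, la = segs[a]
        for b in range(a, len(segs)):
            sb, eb, lb = segs[b]
            trans = bool(codes is not None and codes[sa] != codes[sb])
            out.append(
                BlockPair(a, b, (sa, ea), (sb, eb), la, lb, is_trans=trans)
            )
    return out


def block_id_matrix(profile: CNVProfile) -> tuple[np.ndarray, int]:
    """Per-entry block-pair index (n x n) and the number of blocks.

    Entry (i, j) and (j, i) share the block id of the unordered pair of the
    segments containing i and j, numbered as in :func:`block_partition`.
    """
    seg = profile.segment_of_bin()
    m = len(profile.segments)
    a = np.minimum(seg[:, None], seg[None, :])
    b = np.maximum(seg[:, None], seg[None, :])
    # id of unordered pair (a, b), a<=b, in block_partition order
    ids = a * m - a * (a - 1) // 2 + (b - a)
    return ids, m * (m + 1) // 2


def filter_low_coverage(C: ContactMatrix, quantile: float = 0.02) -> np.ndarray:
    """Boolean mask of bins to exclude from balancing and segmentation.

    Masks bins with zero genome-wide coverage plus those whose total count
    falls below the given quantile of the nonzero totals.
    """
    if not 0 <= quantile < 1:
        raise ValueError("quantile must lie in [0, 1)")
    tot = np.nansum(C.counts, axis=1)
    mask = tot == 0
    nz = tot[tot > 0]
    if quantile > 0 and nz.size:
        mask |= tot < np.quantile(nz, quantile)
    return mask
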