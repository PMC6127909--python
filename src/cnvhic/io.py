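"""Readers and writers for the plain-text interchange formats.

Contact matrices travel as HiC-Pro-style sparse upper-triangle triplets
(``bin_id_i  bin_id_j  count``, whitespace-separated, bin ids 1-based)
with a companion BED file of bins (``chrom  start  end  bin_id``).
Copy-number profiles are BED with the level in column 4; feature tracks,
bias vectors and decay curves are TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import CNVProfile, ContactMatrix, GenomeBins
from .caic import BlockBias, DecayCurve


def read_bins(bed_path, features_path=None) -> GenomeBins:
    """Read a bins BED (chrom, start, end, bin_id) and optional feature TSV
    (bin_id, gc, mappability, eff_frag_len)."""
    bed = pd.read_csv(
        bed_path, sep=r"\s+", header=None,
        names=["chrom", "start", "end", "bin_id"], comment="#",
    )
    if not np.array_equal(bed["bin_id"].to_numpy(), np.arange(1, len(bed) + 1)):
        raise ValueError("bin ids must be 1..n in file order")
    kw = {}
    if features_path is not None:
        feats = pd.read_csv(features_path, sep="\t")
        feats = feats.sort_values("bin_id")
        if len(feats) != len(bed):
            raise ValueError("feature table does not cover all bins")
        for col in ("gc", "mappability", "eff_frag_len"):
            if col in feats:
                kw[col] = feats[col].to_numpy(dtype=float)
        if "mappability" in kw:
            kw["mappable_flag"] = kw["mappability"] >= 0.25
    return GenomeBins(
        chrom=bed["chrom"].to_numpy(),
        start=bed["start"].to_numpy(),
        end=bed["end"].to_numpy(),
        **kw,
    )


def write_bins(bins: GenomeBins, bed_path, features_path=None) -> None:
    bed = pd.DataFrame(
        {
            "chrom": bins.chrom,
            "start": bins.start,
            "end": bins.end,
            "bin_id": np.arange(1, bins.n + 1),
        }
    )
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    if features_path is not None:
        cols = {"bin_id": np.arange(1, bins.n + 1)}
        for name in ("gc", "mappability", "eff_frag_len"):
            v = getattr(bins, name)
            if v is not None:
                cols[name] = v
        pd.DataFrame(cols).to_csv(features_path, sep="\t", index=False)


def read_matrix(matrix_path, bed_path, features_path=None) -> ContactMatrix:
    """Read a HiC-Pro sparse triplet matrix and its companion BED."""
    bins = read_bins(bed_path, features_path)
    n = bins.n
    counts = np.zeros((n, n))
    seen: set[tuple[int, int]] = set()
    is_norm = False
    with open(matrix_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                i, j = int(parts[0]), int(parts[1])
                v = float(parts[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{matrix_path}: malformed line {lineno}") from exc
            if not (1 <= i <= n and 1 <= j <= n):
                raise ValueError(f"{matrix_path}: unknown bin id at line {lineno}")
            a, b = min(i, j) - 1, max(j, i) - 1
            if (a, b) in seen:
                raise ValueError(f"{matrix_path}: duplicate pair at line {lineno}")
            seen.add((a, b))
            counts[a, b] = counts[b, a] = v
            if v != int(v):
                is_norm = True
    return ContactMatrix(counts, bins, is_normalized=is_norm)


def write_matrix(C: ContactMatrix, matrix_path, bed_path=None) -> None:
    """Write the nonzero upper triangle as sorted 1-based triplets."""
    n = C.n
    iu = np.triu_indices(n)
    vals = C.counts[iu]
    keep = np.isfinite(vals) & (vals != 0)
    with open(matrix_path, "w") as fh:
        for i, j, v in zip(iu[0][keep], iu[1][keep], vals[keep]):
            if v == int(v):
                fh.write(f"{i + 1}\t{j + 1}\t{int(v)}\n")
            else:
                fh.write(f"{i + 1}\t{j + 1}\t{v:.15g}\n")
    if bed_path is not None:
        write_bins(C.bins, bed_path)


def read_cnv_profile(bed_path, bins: GenomeBins) -> CNVProfile:
    """Read a CNV BED (chrom, start, end, level) onto the given bins."""
    df = pd.read_csv(
        bed_path, sep=r"\s+", header=None,
        names=["chrom", "start", "end", "level"], comment="#",
    )
    K = np.full(bins.n, np.nan)
    for _, row in df.iterrows():
        sel = (
            (bins.chrom == row["chrom"])
            & (bins.start >= row["start"])
            & (bins.end <= row["end"])
        )
        K[sel] = row["level"]
    if np.any(~np.isfinite(K)):
        raise ValueError("CNV profile does not cover all bins")
    return CNVProfile.from_levels(K, bins)


def write_cnv_profile(profile: CNVProfile, bins: GenomeBins, bed_path) -> None:
    with open(bed_path, "w") as fh:
        for s, e, lvl in profile.segments:
            val = f"{lvl:.6g}"
            fh.write(
                f"{bins.chrom[s]}\t{bins.start[s]}\t{bins.end[e - 1]}\t{val}\n"
            )


def write_bias(beta: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        for k, b in enumerate(beta, start=1):
            fh.write(f"{k}\t{'NA' if not np.isfinite(b) else f'{b:.15g}'}\n")


def write_decay(e: DecayCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("distance\te\n")
        for d, v in zip(e.distances, e.e):
            fh.write(f"{int(d)}\t{v:.15g}\n")
        if np.isfinite(e.e_trans):
            fh.write(f"trans\t{e.e_trans:.15g}\n")


def write_block_bias(B: BlockBias, profile: CNVProfile, path) -> None:
    m = len(profile.segments)
    with open(path, "w") as fh:
        fh.write("block_a\tblock_b\tbias\n")
        for a in range(m):
            for b in range(a, m):
                bid = a * m - a * (a - 1) // 2 + (b - a)
                v = B.values[bid]
                fh.write(f"{a}\t{b}\t{'NA' if not np.isfinite(v) else f'{v:.15g}'}\n")


def ensure_path(p) -> Path:
    p = Path(p)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p
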