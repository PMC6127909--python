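"""Synthetic diploid Hi-C maps and per-bin feature tracks.

The generator produces the minimal structure the normalization and
copy-number machinery operates on: a power-law cis distance decay, a
constant trans background, optional smooth per-bin multiplicative biases
(GC, mappability, fragment length — so balancing has something to remove),
and Poisson or negative-binomial counting noise.  It deliberately does not
model TADs, compartments or loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import ContactMatrix, GenomeBins, distance_matrix


@dataclass
class FeatureEffects:
    """Multiplicative per-bin bias strengths.

    ``gc`` and ``frag_len`` are log-scale coefficients on the standardized
    tracks; ``mappability_power`` multiplies the bias by mappability^power.
    """

    gc: float = 0.3
    frag_len: float = 0.2
    mappability_power: float = 1.0


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic diploid map.

    Defaults give a desk-scale map (2 chromosomes x 200 bins of 500 kb)
    whose median cis count at one-bin separation is ~100 — deep enough
    that binomial thinning of gains leaves informative counts.
    """

    n_chroms: int = 2
    bins_per_chrom: int = 200
    bin_size: int = 500_000
    cis_scale: float = 100.0  # expected count at one-bin separation
    decay_exponent: float = 1.0  # power-law slope of the cis decay
    trans_rate: float = 2.0  # constant trans expectation per pair
    diag_scale: float = 2.0  # diagonal expectation = diag_scale * cis_scale
    noise: str = "poisson"  # {"poisson", "nbinom"}
    dispersion: float = 10.0  # nbinom size parameter (larger = closer to Poisson)
    feature_effects: FeatureEffects | None = None
    unmappable_fraction: float = 0.0
    telomere_mask: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cis_scale <= 0 or self.trans_rate <= 0 or self.decay_exponent <= 0:
            raise ValueError("cis_scale, trans_rate and decay_exponent must be > 0")
        if self.noise not in ("poisson", "nbinom"):
            raise ValueError(f"unknown noise law: {self.noise!r}")
        if self.noise == "nbinom" and self.dispersion <= 0:
            raise ValueError("nbinom dispersion must be > 0")


def _smooth_track(rng: np.random.Generator, n: int, lo: float, hi: float, sigma: float = 5.0) -> np.ndarray:
    raw = gaussian_filter1d(rng.normal(size=n), sigma)
    raw = (raw - raw.min()) / max(raw.max() - raw.min(), 1e-12)
    return lo + raw * (hi - lo)


def generate_feature_tracks(
    bins: GenomeBins,
    seed: int | np.random.Generator = 0,
    unmappable_fraction: float = 0.0,
    telomere_mask: bool = False,
    telomere_bins: int = 2,
    mappable_threshold: float = 0.25,
) -> GenomeBins:
    """Fill gc / mappability / eff_frag_len with smooth bounded tracks.

    GC stays in [0.3, 0.7]; mappability in [0.5, 1] except for unmappable
    bins (set to 0.1) placed at chromosome ends when ``telomere_mask`` is on
    and at random at rate ``unmappable_fraction``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = bins.n
    gc = _smooth_track(rng, n, 0.3, 0.7)
    mappability = _smooth_track(rng, n, 0.5, 1.0)
    frag = _smooth_track(rng, n, 200.0, 800.0)
    unmappable = np.zeros(n, dtype=bool)
    if unmappable_fraction > 0:
        unmappable |= rng.random(n) < unmappable_fraction
    if telomere_mask:
        codes = bins.chrom_codes
        for c in np.unique(codes):
            idx = np.flatnonzero(codes == c)
            unmappable[idx[:telomere_bins]] = True
            unmappable[idx[-telomere_bins:]] = True
    mappability = np.where(unmappable, 0.1, mappability)
    return GenomeBins(
        chrom=bins.chrom,
        start=bins.start,
        end=bins.end,
        gc=gc,
        mappability=mappability,
        eff_frag_len=frag,
        mappable_flag=mappability >= mappable_threshold,
    )


def make_bins(n_chroms: int, bins_per_chrom: int, bin_size: int) -> GenomeBins:
    """Bare fixed-width bins over ``n_chroms`` chromosomes."""
    chrom = np.repeat([f"chr{c + 1}" for c in range(n_chroms)], bins_per_chrom)
    start = np.tile(np.arange(bins_per_chrom) * bin_size, n_chroms)
    return GenomeBins(chrom=chrom, start=start, end=start + bin_size)


def expected_diploid(spec: SyntheticSpec, bins: GenomeBins) -> np.ndarray:
    """Noise-free expectation matrix of the diploid map (before biases)."""
    d = distance_matrix(bins)
    with np.errstate(divide="ignore"):
        mu = spec.cis_scale * (d / spec.bin_size) ** (-spec.decay_exponent)
    mu[np.isinf(d)] = spec.trans_rate
    np.fill_diagonal(mu, spec.diag_scale * spec.cis_scale)
    return mu


def generate_diploid(spec: SyntheticSpec) -> tuple[ContactMatrix, GenomeBins]:
    """Seeded synthetic diploid contact map with annotated bins."""
    rng = np.random.default_rng(spec.seed)
    bins = make_bins(spec.n_chroms, spec.bins_per_chrom, spec.bin_size)
    bins = generate_feature_tracks(
        bins,
        seed=rng,
        unmappable_fraction=spec.unmappable_fraction,
        telomere_mask=spec.telomere_mask,
    )
    mu = expected_diploid(spec, bins)
    if spec.feature_effects is not None:
        fe = spec.feature_effects
        z_gc = (bins.gc - bins.gc.mean()) / max(bins.gc.std(), 1e-12)
        z_fl = (bins.eff_frag_len - bins.eff_frag_len.mean()) / max(
            bins.eff_frag_len.std(), 1e-12
        )
        bias = np.exp(fe.gc * z_gc + fe.frag_len * z_fl)
        bias *= bins.mappability**fe.mappability_power
        mu = mu * np.outer(bias, bias)
    n = bins.n
    iu = np.triu_indices(n)
    mu_u = mu[iu]
    if spec.noise == "poisson":
        draws = rng.poisson(mu_u)
    else:
        r = spec.dispersion
        draws = rng.negative_binomial(r, r / (r + mu_u))
    counts = np.zeros((n, n))
    counts[iu] = draws
    counts = counts + np.triu(counts, 1).T
    return ContactMatrix(counts, bins), bins
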