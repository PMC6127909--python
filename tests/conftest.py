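import numpy as np
import pytest

from cnvhic.core import CNVProfile, ContactMatrix, GenomeBins
from cnvhic.synthetic import SyntheticSpec, generate_diploid


@pytest.fixture
def small_bins() -> GenomeBins:
    """Two chromosomes x 4 bins of 500 kb, with flat feature tracks."""
    chrom = np.repeat(["chr1", "chr2"], 4)
    start = np.tile(np.arange(4) * 500_000, 2)
    return GenomeBins(
        chrom=chrom,
        start=start,
        end=start + 500_000,
        gc=np.full(8, 0.5),
        mappability=np.ones(8),
        eff_frag_len=np.full(8, 400.0),
        mappable_flag=np.ones(8, dtype=bool),
    )


@pytest.fixture
def small_matrix(small_bins) -> ContactMatrix:
    rng = np.random.default_rng(7)
    n = small_bins.n
    counts = rng.poisson(20.0, size=(n, n)).astype(float)
    counts = np.triu(counts) + np.triu(counts, 1).T
    return ContactMatrix(counts, small_bins)


@pytest.fixture
def two_level_profile(small_bins) -> CNVProfile:
    """chr1 diploid, chr2 at copy number 4."""
    K = np.array([2, 2, 2, 2, 4, 4, 4, 4], dtype=float)
    return CNVProfile.from_levels(K, small_bins)


@pytest.fixture(scope="session")
def diploid_map():
    """Default-size synthetic diploid map, shared across tests (read-only)."""
    return generate_diploid(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def biased_diploid_map():
    from cnvhic.synthetic import FeatureEffects

    return generate_diploid(SyntheticSpec(seed=13, feature_effects=FeatureEffects()))
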