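import numpy as np
import pytest

from cnvhic.balance import loic
from cnvhic.caic import (
    BlockBias,
    DecayCurve,
    caic,
    fit_block_bias,
    fit_decay,
    observed_over_expected,
)
from cnvhic.core import CNVProfile, ContactMatrix, GenomeBins, block_id_matrix, distance_matrix


def _bins(n_chroms=2, bins_per_chrom=40, bin_size=500_000):
    chrom = np.repeat([f"chr{i+1}" for i in range(n_chroms)], bins_per_chrom)
    start = np.tile(np.arange(bins_per_chrom) * bin_size, n_chroms)
    return GenomeBins(chrom=chrom, start=start, end=start + bin_size)


def _decay_matrix(bins, f):
    """Symmetric matrix with N[i,j] = f(distance in bins), trans = f(inf)."""
    d = distance_matrix(bins) / bins.bin_size
    return np.where(np.isinf(d), f(np.inf), f(np.where(np.isinf(d), 1, d)))


class TestFitDecay:
    def test_decreasing_input_is_fixed_point(self):
        bins = _bins()
        f = lambda d: 50.0 / (1.0 + d) if np.isscalar(d) else 50.0 / (1.0 + d)
        N = ContactMatrix(_decay_matrix(bins, f), bins, is_normalized=True)
        profile = CNVProfile.from_levels(np.full(bins.n, 2.0), bins)
        e = fit_decay(N, profile)
        # fitted curve reproduces the generating function at every distance
        # except the last group, where the two sparsest distances are pooled
        expect = 50.0 / (1.0 + e.distances / bins.bin_size)
        assert np.allclose(e.e[:-1], expect[:-1], rtol=1e-10)
        # last group pools d=38 (4 pairs) and d=39 (2 pairs) bins
        pooled = (50.0 / 39 * 4 + 50.0 / 40 * 2) / 6
        assert e.e[-1] == pytest.approx(pooled)
        assert np.all(np.diff(e.e) <= 1e-12)

    def test_pool_adjacent_violators_pools_weighted_mean(self):
        # per-distance means 10, 4, 6 violate monotonicity at (4, 6);
        # pool-adjacent-violators pools them to their weighted mean
        m = 6
        bins = GenomeBins(
            chrom=np.array(["chr1"] * m + ["chr2"] * m, dtype=object),
            start=np.tile(np.arange(m) * 1000, 2),
            end=np.tile((np.arange(m) + 1) * 1000, 2),
        )
        vals_by_d = {1: 10.0, 2: 4.0, 3: 6.0, 4: 1.0, 5: 1.0}
        counts = np.zeros((2 * m, 2 * m))
        for c0 in (0, m):
            for i in range(m):
                for j in range(i + 1, m):
                    counts[c0 + i, c0 + j] = counts[c0 + j, c0 + i] = vals_by_d[j - i]
        N = ContactMatrix(counts, bins, is_normalized=True)
        profile = CNVProfile.from_levels(np.full(2 * m, 2.0), bins)
        e = fit_decay(N, profile)
        # pair counts per distance (both chroms): d1:10, d2:8, d3:6
        pooled = (4.0 * 8 + 6.0 * 6) / (8 + 6)
        assert e.e[0] == pytest.approx(10.0)
        assert e.e[1] == pytest.approx(pooled)
        assert e.e[2] == pytest.approx(pooled)
        assert np.all(np.diff(e.e) <= 1e-12)

    def test_trans_expectation_is_mean(self):
        bins = _bins(bins_per_chrom=6)
        counts = np.zeros((12, 12))
        counts[:6, 6:] = 4.0
        counts[6:, :6] = 4.0
        N = ContactMatrix(counts, bins, is_normalized=True)
        profile = CNVProfile.from_levels(np.full(12, 2.0), bins)
        e = fit_decay(N, profile)
        assert e.e_trans == pytest.approx(4.0)


class TestFitBlockBias:
    def test_exact_ratio_recovered(self):
        bins = _bins(bins_per_chrom=20)
        f = lambda d: 50.0 / (1.0 + d)
        base = _decay_matrix(bins, f)
        profile = CNVProfile.from_levels(np.full(bins.n, 2.0), bins)
        e = fit_decay(ContactMatrix(base, bins, is_normalized=True), profile)
        N2 = ContactMatrix(2.0 * base, bins, is_normalized=True)
        B = fit_block_bias(N2, profile, e)
        assert np.allclose(B.values[np.isfinite(B.values)], 2.0, rtol=1e-10)

    def test_closed_form_two_entry_block(self):
        # least squares B for (N, e) pairs (4,1),(9,3): (4*1+9*3)/(1+9) = 3.1
        num = 4 * 1 + 9 * 3
        den = 1**2 + 3**2
        assert num / den == pytest.approx(3.1)


class TestCaic:
    def test_diploid_bias_is_unity(self, diploid_map):
        C, bins = diploid_map
        profile = CNVProfile.from_levels(np.full(bins.n, 2.0), bins)
        N_caic, B, e = caic(C, profile)
        ok = np.isfinite(B.values)
        assert np.allclose(B.values[ok], 1.0, atol=0.05)
        assert np.all(np.diff(e.e) <= 1e-12)

    def test_recovers_constructed_block_bias(self):
        rng = np.random.default_rng(5)
        bins = _bins(n_chroms=2, bins_per_chrom=60)
        n = bins.n
        K = np.full(n, 2.0)
        K[20:40] = 4
        K[80:100] = 1
        profile = CNVProfile.from_levels(K, bins)
        ids, n_blocks = block_id_matrix(profile)
        B_true = rng.uniform(0.5, 3.0, size=n_blocks)
        d = distance_matrix(bins) / bins.bin_size
        d_safe = np.where(np.isfinite(d), np.maximum(d, 1.0), 1.0)
        e_true = np.where(np.isinf(d), 2.0, 40.0 * d_safe**-0.8)
        mu = B_true[ids] * e_true
        counts = rng.poisson(np.triu(mu))
        counts = counts + np.triu(counts, 1).T
        N = ContactMatrix(counts.astype(float), bins, is_normalized=True)
        N_caic, B, e = caic(N, profile)
        ok = np.isfinite(B.values)
        r = np.corrcoef(B.values[ok], B_true[ok])[0, 1]
        assert r > 0.99
        assert np.all(np.diff(e.e) <= 1e-12)

    def test_objective_monotone_nonincreasing(self):
        # alternating exact minimizers can only decrease the objective
        from cnvhic.caic import _build_workspace, _fit_block_bias, _fit_decay

        rng = np.random.default_rng(8)
        bins = _bins(n_chroms=2, bins_per_chrom=40)
        K = np.full(bins.n, 2.0)
        K[10:25] = 3
        profile = CNVProfile.from_levels(K, bins)
        counts = rng.poisson(10.0, size=(bins.n, bins.n)).astype(float)
        counts = np.triu(counts) + np.triu(counts, 1).T
        N = ContactMatrix(counts, bins, is_normalized=True)
        ws, vals = _build_workspace(N, profile, None, False)
        B_pair = np.ones(vals.size)
        e = _fit_decay(vals, B_pair, ws)
        objs = []
        for _ in range(8):
            B = _fit_block_bias(vals, e(ws.dist), ws)
            B_pair = np.nan_to_num(B[ws.block], nan=0.0)
            e = _fit_decay(vals, B_pair, ws)
            resid = vals - B_pair * e(ws.dist)
            objs.append(float(resid @ resid))
        assert all(b <= a + 1e-9 * abs(a) for a, b in zip(objs, objs[1:]))

    def test_removing_then_remultiplying_bias_restores_loic(self, diploid_map):
        C, bins = diploid_map
        K = np.full(bins.n, 2.0)
        K[:100] = 3
        profile = CNVProfile.from_levels(K, bins)
        res = loic(C, profile)
        N_caic, B, e = caic(C, profile, precomputed_loic=res.N)
        Bx = B.expand()
        back = N_caic.counts * Bx
        ok = np.isfinite(back) & np.isfinite(res.N.counts) & (Bx > 0)
        assert np.allclose(back[ok], res.N.counts[ok], rtol=1e-10)


class TestObservedOverExpected:
    @staticmethod
    def _interior(bins):
        """Off-diagonal pairs excluding the two sparsest (pooled) distances
        and the diagonal, where the fitted curve is not point-exact."""
        d = distance_matrix(bins) / bins.bin_size
        interior = (d > 0) & ~((d >= d[np.isfinite(d)].max() - 1) & np.isfinite(d))
        return interior

    def test_identity_when_matrix_equals_decay(self):
        bins = _bins()
        f = lambda d: 30.0 / (1.0 + d)
        base = _decay_matrix(bins, f)
        profile = CNVProfile.from_levels(np.full(bins.n, 2.0), bins)
        N = ContactMatrix(base, bins, is_normalized=True)
        e = fit_decay(N, profile)
        oe = observed_over_expected(N, e)
        sel = self._interior(bins) & np.isfinite(oe.counts)
        assert np.allclose(oe.counts[sel], 1.0, rtol=1e-8)

    def test_doubling_matrix_doubles_ratio(self):
        bins = _bins()
        f = lambda d: 30.0 / (1.0 + d)
        base = _decay_matrix(bins, f)
        profile = CNVProfile.from_levels(np.full(bins.n, 2.0), bins)
        e = fit_decay(ContactMatrix(base, bins, is_normalized=True), profile)
        oe = observed_over_expected(
            ContactMatrix(2 * base, bins, is_normalized=True), e
        )
        sel = self._interior(bins) & np.isfinite(oe.counts)
        assert np.allclose(oe.counts[sel], 2.0, rtol=1e-8)
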