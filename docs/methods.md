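# Methods

This note documents the models implemented in `cnvhic`, the assumptions
behind them, the tunable parameters and their defaults, and the known
limitations. Notation: a genome binned into *n* fixed-width windows, a
symmetric contact matrix *C*, a per-bin copy-number profile *K* (piecewise
constant, diploid = 2), genomic distance *s(i,j)* between bin centers
(∞ across chromosomes).

## Simulating CNV effects on a diploid map

In a diploid cell the observed count between same-chromosome loci sums two
cis contacts (one per homolog) and two inter-homolog ("transH") contacts;
a trans pair sums the four inter-chromosomal combinations. Assuming
chromosome territories, the inter-homolog contact rate is indistinguishable
from and estimated by the trans background, so under a segmental profile K:

* same chromosome: `E_ij = k·E_cis_ij + (K_i·K_j − k)·E_trans`
* different chromosomes: `E_ij = K_i·K_j·E_trans`

where *k* is the number of true-cis pairings. The default policy sets
`k = K_i` when *i* and *j* share a segment (each copy of the segment pairs
with itself) and `k = min(2, K_i, K_j)` across segments (the two parental
homologs, capped when a loss removes one). The policy is pluggable
(`simulate.KPolicy`) to allow tandem-duplication variants, which would
raise cross-segment k.

Estimation on a real diploid input: `E_trans` = median of unmasked trans
entries (flag to restrict to nonzero entries for sparse maps);
`E_cis = max(C − E_trans, 0)` — the clamp guards against counts below the
trans background, which the decomposition cannot represent. The enrichment
ratio is `p_ij = E_ij / (2·E_cis + 2·E_trans)` in cis and `K_i·K_j/4` in
trans, then replaced by its median within each block of the segment-pair
partition (robustness; also defines entries whose denominator vanished).
Simulated counts are one binomial draw per unordered pair,
`Binomial(C_ij, p_ij / max p)`, mirrored for symmetry. Thinning preserves
Poisson and negative-binomial laws and guarantees `C_sim ≤ C`; the price is
that the input must be deep, and that blocks whose ratio falls to zero
(far-cis pairs between single-copy segments at modest depth) are wiped.
With K ≡ 2 every ratio is identically 1 and the matrix is returned
bit-unchanged.

## ICE and LOIC

Both factor `C_ij = β_i β_j N_ij` and choose β by Sinkhorn–Knopp-style
symmetric scaling (`β ← β·√(rowsum/target)` per sweep) toward per-bin
row-sum targets:

* ICE: target = mean unmasked raw row sum (equal visibility);
* LOIC: target = mean raw total over the bins sharing the copy-number
  level of bin *i* (local equal visibility), so the normalized 1D profile
  is piecewise constant and proportional to copy number.

With a constant profile the LOIC target collapses to ICE's and the two are
identical. Convergence: max relative row-sum deviation < `tol`
(default 1e−8 — strict enough that the flatness contract holds at 1e−6
with margin; cost is a few extra sweeps), `max_iter` 300, non-convergence
flagged rather than raised. After convergence the map is rescaled to
preserve the raw total (the targets already sum to it; this removes the
residual slack). Copy-number levels are grouped after rounding to 2
decimals since estimated profiles are continuous. Masked bins (zero or
bottom-quantile coverage, default quantile 0.02) are excluded and emitted
as missing, never zero — zeros would bias 1D profiles and decay fits.

## CAIC

CAIC models the LOIC map as a block-constant copy-number effect times a
distance decay, `N^LOIC_ij ≈ B_ij · e(s(i,j))`, fit by

```
min_{e,B}  Σ_ij (N^LOIC_ij − B_ij e(s(i,j)))²
s.t.       B block-constant, e non-increasing
```

via alternating exact conditional minimizers from B ≡ 1: given B, the
unconstrained per-distance optimum is `Σ B·N / Σ B²`, made monotone by
weighted isotonic regression (weights Σ B² per distance); given e, each
block's optimum is `Σ N·e / Σ e²`. Each step is an exact minimizer, so the
objective is non-increasing; iteration stops at relative decrease < 1e−6
or 50 rounds (convergence is fast in practice, < 10 rounds). Trans pairs
share a single expected value `e_trans` and are fitted independently of
cis. Distances are exact bin multiples (uniform bins, no log-binning);
distances with fewer than 3 unmasked pairs are pooled with the next
distance before the isotonic fit. The diagonal is kept in matrices but
excluded from decay fitting and error metrics by default (self-ligation
artifacts; flag-controlled).

(B, e) are identifiable only up to a scalar per part (cis/trans). The
convention fixes B = 1 on modal-level-by-modal-level blocks, averaging
only blocks with positive fitted bias; if a part has no such block (e.g.
the modal level occupies a single chromosome, leaving no modal trans
block), every block of that part is projected to its modal equivalent via
the copy-number product ratio `modal²/(K_a·K_b)` before averaging.
Without this fallback the trans part would sit on an arbitrary scale and
skew the cis/trans balance of the corrected map.

The corrected map is `N^CAIC = N^LOIC / B` (so that `N^CAIC ≈ e(s)`, the
stated contract of the factorization); multiplying B back restores the
LOIC map exactly. `observed_over_expected` divides any map by `e(s)` to
remove proximity structure for block-level inspection.

## Copy-number calling from the 1D signal

The per-bin genome-wide contact sum of a raw cancer map is approximately
proportional to copy number. The pipeline:

1. **1D profile** — row sums over all (default), cis-only or trans-only
   pairs; masked bins missing.
2. **Feature correction** — Poisson regression (log link) of the totals on
   standardized GC and effective-fragment-length tracks plus
   log-mappability as a fitted covariate. A per-bin *exposure* — the
   expected total under a flat profile, computed from the map's own
   per-distance mean counts — absorbs the purely positional trend caused
   by chromosome-end truncation of the decay sum. On genome-length
   chromosomes this term is negligible, but on short (desk-scale)
   chromosomes it rivals a one-copy step. The corrected profile is the
   additive residual (observed − fitted) affinely rescaled to mean 1.
3. **Segmentation** — per-chromosome optimal-partition dynamic programming
   minimizing within-segment squared error plus a per-changepoint penalty,
   default `10·σ̂²·log m` with σ̂ the MAD of successive differences and *m*
   the chromosome length in unmasked bins. The factor 10 over the plain
   BIC form compensates for short-range correlation in the corrected
   signal (residual decay landscape) that the successive-difference
   estimate does not see; copy-number steps (≥ 0.25 on the corrected
   scale) remain an order of magnitude above the detection limit. Minimum
   segment length 2 bins. The penalty is the main knob to adjust to the
   signal-to-noise ratio of a dataset.
4. **Level smoothing** — adjacent same-chromosome segments whose means
   differ by < `merge_threshold` (default 0.25) are merged iteratively
   (closest pair first, length-weighted means); the merged segment means
   are then clustered genome-wide by 1-D weighted centroid agglomeration
   until all cluster centers are > `level_gap` (default 0.25) apart.
   Centroid agglomeration rather than gap splitting: stray intermediate
   means are absorbed into the nearest heavy cluster instead of chaining
   two genuine levels together. 0.25 is half the minimum level spacing on
   the corrected scale (one copy ≈ 0.5). The modal cluster (most bins) is
   anchored at copy number 2; levels below zero after residual noise are
   clamped. Masked bins inherit the nearest same-chromosome level for
   profile completeness but are never used to define levels. This
   merge-then-cluster procedure plays the false-positive-removal role that
   dedicated smoothing packages play in array-CGH pipelines; their
   internal model is not re-implemented, since downstream only the merged
   level contract matters.

Random validation profiles (`random_cnv_profile`) follow: draw a
breakpoint count (Poisson, mean 5, or fixed), place breakpoints uniformly,
drop those in unmappable bins, draw each segment level as 1 + Poisson(1),
redraw any level equal to its left same-chromosome neighbour.

## Synthetic diploid generator

`SyntheticSpec` defaults define the study conditions used throughout the
tests: 2 chromosomes × 200 bins of 500 kb; cis expectation
`α·(s/bin)^-γ` with α = 100 (median count ≈ 100 at one-bin separation —
"deep enough to thin") and γ = 1; diagonal expectation 2α; constant trans
expectation λ = 2 per pair, putting ≈ 28% of contacts in trans and the
cis/trans crossover at ~50 bins, in the realistic range for 500-kb maps;
Poisson noise by default, negative-binomial (dispersion 10) as an option
because thinning's law-preservation is itself worth testing. Optional
smooth GC / mappability / fragment-length tracks act as multiplicative
per-bin biases (GC and fragment length log-linear on standardized tracks,
mappability as a power), giving ICE/LOIC something to remove; unmappable
bins can be placed at chromosome ends (telomere mask) and at random.

What the generator does *not* emulate: TADs, compartments, loops,
translocation fusions, tandem-amplification proximity effects, and
genome-length chromosomes. Passing tests therefore demonstrate the
copy-number machinery under clean distance-decay + bias structure, not
robustness to the full structural complexity of real cancer maps.

## Evaluation metrics

* **Block-average error**: after rescaling both maps to equal totals over
  shared valid entries, per block `log2(mean N / mean truth)`; block means
  rather than per-entry log ratios so that zero entries in weakly covered
  blocks contribute instead of being dropped (which would bias loss blocks
  upward). Invariant to global rescaling of either map; isolated behind
  one function so the formula can be swapped.
* **Breakpoint recall/precision**: greedy one-to-one nearest matching of
  interior level-change points (chromosome starts excluded from both
  sides — they would match trivially), tolerance 2 bins by default.
  Symmetric: swapping called/truth swaps recall and precision.
* **Profile correlation**: Spearman over mutually finite bins; constant
  inputs yield missing.

## Numerical choices and degenerate inputs

Matrices are dense in memory (desk-scale, ≤ ~10⁴ bins; all algorithms are
O(n²) anyway) and sparse upper-triangle triplets on disk (1-based bin ids
in files, 0-based internally). Symmetry is enforced at construction of
every `ContactMatrix`. Single-chromosome maps make the trans background
undefined (error). A copy-number group with all bins masked has no LOIC
target (error). Blocks with no unmasked entries get a missing bias.
Chromosomes shorter than twice the minimum segment length return a single
segment. All stochastic steps take explicit seeds; fixed seeds give
bit-identical outputs.

## Known limitations

* The thinning simulator can only reduce counts; starting from a shallow
  map, loss-segment blocks at large distance can be wiped entirely.
* The copy-number effect B is constant per block; a distance-dependent
  effect within blocks is not modeled.
* The 1D level of a copy-number segment depends mildly on its length and
  on the surrounding landscape (short amplified segments keep less of
  their short-range cis mass), so called levels are exact in rank but
  approximate in magnitude; calling reports relative levels anchored at
  the modal level = 2.
* Sub-bin breakpoint resolution and allele-specific copy number are out of
  scope.
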