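# cnvhic

Copy-number-aware simulation, normalization and CNV calling for Hi-C
contact maps.

## The problem

Cancer genomes carry segmental copy-number variants (CNVs): whole stretches
of chromosome present in 1, 3, 4, … copies instead of the diploid 2. In a
binned Hi-C contact matrix *C* this shows up as rectangular blocks of
enriched or depleted counts, because the contact count between loci *i* and
*j* scales with the amount of genetic material at both ends. Standard
matrix balancing (ICE) assumes every bin should be equally visible — the
normalized genome-wide contact sum of each bin is forced to a constant —
which on a cancer map silently redistributes counts between gained and lost
regions instead of correcting technical bias only.

`cnvhic` implements the copy-number-aware alternatives and the machinery to
validate them without any external data:

* **simulate** — impose a copy-number profile *K* on a deep diploid map.
  The expected count decomposes into cis and inter-homolog (≈ trans)
  contacts: for same-chromosome pairs *E<sub>ij</sub> = k E<sup>cis</sup> +
  (K<sub>i</sub>K<sub>j</sub> − k) E<sup>trans</sup>*, for trans pairs
  *E<sub>ij</sub> = K<sub>i</sub>K<sub>j</sub> E<sup>trans</sup>*. The
  resulting enrichment ratio p<sub>ij</sub> (block-median smoothed) drives
  binomial thinning *C<sup>sim</sup><sub>ij</sub> ~
  B(C<sub>ij</sub>, p<sub>ij</sub>/max p)*, which preserves Poisson /
  negative-binomial count laws.
* **balance** — ICE and **LOIC**: balancing *C<sub>ij</sub> = β<sub>i</sub>
  β<sub>j</sub> N<sub>ij</sub>* with row-sum targets that are constant
  genome-wide (ICE) or constant within each copy-number group (LOIC's local
  equal-visibility assumption), so the normalized 1D profile stays
  proportional to copy number.
* **caic** — **CAIC** factorizes the LOIC map into a block-constant
  copy-number effect *B* and a non-increasing distance decay *e(s)* by
  alternating least squares (isotonic regression for *e*, closed-form
  ratios for *B*), then divides *B* out so that
  *N<sup>CAIC</sup><sub>ij</sub> ≈ e(s(i,j))*.
* **cnv_call** — estimate *K* directly from the map: per-bin 1D contact
  sums, Poisson-regression correction for GC / mappability / fragment
  length, penalized least-squares changepoint segmentation per chromosome,
  and smoothing of segment means into discrete levels anchored at the modal
  level = copy 2.
* **synthetic** / **evaluate** — a seeded diploid map generator (power-law
  cis decay, constant trans background, optional feature biases, Poisson or
  negative-binomial noise) and the metrics used to compare methods
  (block-average error matrices, breakpoint recall/precision, profile
  correlations).

## Worked example

```bash
cnvhic synth --seed 3 --out-prefix toy                 # diploid 2x200-bin map
printf 'chr1\t0\t30000000\t2\nchr1\t30000000\t100000000\t4\nchr2\t0\t100000000\t2\n' > cnv.bed
cnvhic simulate --matrix toy.matrix --bins toy.bed --cnv cnv.bed --seed 4 --out sim.matrix
cnvhic call-cnv --matrix sim.matrix --bins toy.bed --features toy.features.tsv --out called.bed
cnvhic normalize --method caic --matrix sim.matrix --bins toy.bed --cnv cnv.bed --out caic.matrix
cnvhic evaluate --pred caic.matrix --truth toy.matrix --bins toy.bed \
    --cnv cnv.bed --called-cnv called.bed --report report.tsv
cat report.tsv
```

```
sum_sq_block_error	0.0486725772850787
breakpoint_recall	1
breakpoint_precision	0.1
level_spearman	0.875549
```

The amplified chr1 segment boundary is recovered exactly (recall 1) and
`called.bed` shows the gained region called at levels ≈ 4.6–5.5 against
≈ 1–2 elsewhere. Precision is low on this single map because the amplified
block is internally noisy and gets split into sub-segments whose extra
boundaries count as false positives; `level_spearman` (rank correlation of
called vs true per-bin copy number) stays high because those sub-levels
all sit far above the diploid background. `sum_sq_block_error` sums the
squared per-block log2 deviations between the CAIC-normalized map and the
diploid reference after equal-total rescaling; small values mean the
copy-number blocks have been flattened out.

The same pipeline is available as library calls
(`cnvhic.generate_diploid`, `cnvhic.simulate_cnv_map`, `cnvhic.loic`,
`cnvhic.caic`, `cnvhic.call_cnv`, …); see `docs/methods.md` for the model
details and parameter guidance.

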