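# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the procedure was genuinely open.

## Coordinates and data model

All internal coordinates are 0-based half-open (`[start, end)`, the BED
convention). GWAS positions are 1-based as published and converted at
ingest; element tables may be declared 0- or 1-based via a reader flag
rather than guessed. Chromosome names are normalized to the `chr` dialect
so mixed inputs compare equal. Strand is ignored: no mapping rule uses it.
A 1-based position `pos` falls in bin `floor((pos-1)/resolution)`; an
element overlapping a window or bin by at least 1 bp counts as contained —
no minimum-overlap fraction is imposed.

## Contact significance

The stage assigns confidence to binned contacts with a binomial test
against a distance-dependent null, in the spirit of Fit-Hi-C but
deliberately simplified: instead of a spline-smoothed expected-count curve
with iterative refinement, intra-chromosomal pairs are sorted by genomic
distance and cut into equal-occupancy strata whose boundaries never split
pairs sharing one distance; all inter-chromosomal pairs form one extra
stratum. Within a stratum the expectation is flat:
`p_exp = total_count / (N * n_pairs)`, with `N` the total observed count
over all analyzed pairs. P-values are the upper binomial tail `P(X >= k)`,
q-values come from Benjamini–Hochberg applied jointly to every analyzed
pair (intra and inter), and the significant set is `q <= 0.05`, an
inclusive bound.

Numerical and scope choices:

* **Analyzed universe.** The records present in the input table are the
  analyzed pairs; zero-count bin pairs are not enumerated. Conditioning on
  observed pairs slightly inflates the stratum expectation at long range
  (zero truncation), which makes the test conservative there.
* **Stratum count.** Default `n_strata = 1000`. With a power-law decay
  (exponent near 1) a coarse stratification lumps the shortest distances —
  where the decay gradient is steepest and occupancy highest — into one
  stratum, so the flat expectation systematically over-calls short-range
  pairs and can let spurious neighbour contacts outrank genuine loops. At
  1000 strata the shortest distances get one stratum each (occupancy is
  high there) while far distances merge where the gradient is negligible.
  On small inputs the strata collapse gracefully to the number of distinct
  distances.
* **Diagonal.** Self-pairs (distance 0) are excluded; the minimum analyzed
  distance defaults to one bin and is configurable.
* **No bias correction.** Raw counts in; no ICE/KR matrix balancing and no
  per-bin bias vectors. The synthetic data are generated without coverage
  bias, so none is modelled.

## Variant mapping

SNPs with association p-value at or below 5×10⁻⁸ are high-risk. 1D mapping
searches a window of one Hi-C resolution centered on the SNP (half up-,
half downstream, clipped at the chromosome start). 3D mapping collects
every significant contact partner of the SNP's bin that contains at least
one regulatory element and selects a single fragment: minimal contact
q-value; at equal q the longest-range contact, with inter-chromosomal
contacts ranked above every intra-chromosomal one (the tie rule needs a
"longer than any distance" slot for them, as they have no linear distance);
any remaining tie falls back on (chromosome, bin index) order so selection
is a total order and permutation-invariant.

Whether "one fragment per SNP" is selected once over all elements or once
per element class is ambiguous in the source procedure; both are
implemented (`selection_scope = "per_class" | "joint"`) and `per_class` is
the default, guaranteeing each element class is represented whenever any
significant element-bearing contact exists.

Per-SNP aggregation: median DA over mapped enhancers; median DA over TFs
when numeric scores exist, otherwise the fraction of disease-associated
TFs; target genes are the union of the mapped elements' targets,
de-duplicated by symbol, with the median taken over their gene scores.
Target symbols missing from the gene score table are dropped (a gene
without a score cannot enter a median). SNPs with an empty mapping
contribute nothing to group distributions — they are never zero-filled.

Distribution summaries use linear interpolation between order statistics
(numpy's `linear` quantile method, configurable), `IQR = Q3 − Q1`, and
1.5·IQR fences for outliers; fences affect only violin whiskers, never the
reported quantiles.

## TAD calling

For boundary `i` (between bins `i` and `i+1`) the boundary signal is the
mean of the `w × w` submatrix spanning the boundary, truncated at
chromosome edges. Candidates are local minima within `i ± w` (plateau ties
keep the leftmost). Each candidate is tested with a one-sided
Mann–Whitney/rank-sum comparison of the cross-boundary cells against the
pooled within-side upper-triangle cells; the exact null distribution is
used up to a pooled sample size of 60, the normal approximation beyond.
Boundaries with `p < alpha` (default 0.05) stand; chromosome ends are
implicit boundaries; segments shorter than `min_tad_size` (default 2 bins)
merge into the preceding segment (a too-short first segment, having none,
merges forward). Runs of `>= w` zero-coverage bins are emitted as gaps and
excluded from TAD statistics.

The boundary statistics run by default on the observed/expected matrix
(each diagonal divided by its mean), exposed as
`normalize = "expected" | "raw"`. On raw counts with a steep decay the
cross-boundary cells sit at systematically larger distances than the
within-side cells, so the rank-sum filter detects the decay rather than
boundary depletion and passes at essentially every local minimum — on the
synthetic benchmark this produced ~3× over-segmentation, which in turn
washed out the SNP-rich vs control contrast. The O/E transform removes the
trend, calibrates the filter (uniform matrices yield a single
whole-chromosome TAD; planted boundaries are recovered with no false
boundaries at enrichment 2), and leaves boundary calls invariant under
global matrix scaling. Window size `w = 5` bins and `alpha = 0.05` are
conventional defaults, exposed as configuration.

TADs containing at least one high-risk SNP (half-open containment, so a
boundary-adjacent SNP belongs to exactly one TAD) are SNP-rich; the rest
are controls. Group summaries are computed over per-TAD values: the median
enhancer DA and the median TF DA (or disease-associated fraction) of the
elements each TAD contains; TADs without elements of a class are excluded
from that class's distribution.

## Synthetic data

The generator emulates the structure the pipeline is designed to detect,
with one simulated chromosome per study. Expected counts are

    mu_ij = A * |i-j|^(-alpha) * (1 + tau*[same TAD]) * (1 + lambda*[loop])

with Poisson noise by default (negative-binomial with configurable
dispersion for over-dispersion robustness checks); the matrix is symmetric
with a zero diagonal. Defaults describe a deeply sequenced 20 Mbp
chromosome: 2,000 bins at 10 kbp, nearest-neighbour expected count
`A = 300`, decay exponent `alpha = 1`, TAD sizes 20–60 bins (200–600 kbp,
the typical mammalian scale) at enrichment `tau = 2`, and 40 loops spanning
10–80 bins (100–800 kbp, the scale of enhancer–promoter loops) at
enrichment `lambda = 5`. `A` and the loop span were chosen when the
generator was designed so that a 6× count enrichment is statistically
resolvable at the weakest planted loop — the regime the benchmark presumes,
where planted loops are the unique minimal-q contacts of their anchors.
Loop endpoints occupy distinct bins, and each loop has one designated
anchor (SNP-bearing) side, so anchor and partner element populations never
share a bin; loops host a second SNP on the same side when there are more
high-risk SNPs (default 60) than loops.

Annotations: high-risk SNPs sit inside anchor bins with p-values
log-uniform on [1e-30, 5e-8]; background SNPs are uniform over the
chromosome with p-values log-uniform above the threshold. DA scores are
normal with sigma = 0.5, truncated at zero (implemented as clipping; at the
default means the truncated mass is < 3e-7): background mean 2.5,
associated mean 5.0 — a calibration to the roughly two-fold 1D-to-3D
ordering of the study the pipeline reimplements, not a claim about any real
score distribution. Associated elements (2 enhancers + 3 TF binding sites
per SNP) are planted in loop-partner bins; background elements flank each
SNP inside its 1D window; further background elements are scattered
genome-wide, and scattered elements falling inside a SNP-rich TAD have
their DA mean raised by `tad_da_shift = 1.0` (TF flag probability 0.67
instead of 0.33), emulating TAD-level co-localization. Each element targets
1–3 genes drawn from a class-specific pool whose scores follow the
element's class distribution.

What the generator does **not** emulate: coverage/mappability bias and
copy-number effects, hierarchical or nested TADs, A/B compartments,
linkage disequilibrium among SNPs, shared multi-way loop anchors, and any
sequence-level realism. Passing benchmarks therefore demonstrates that the
pipeline recovers planted structure of the stated kind under clean
conditions — not performance on real Hi-C libraries, where bias correction
and LD pruning would matter.

## Benchmark problem sizes

The acceptance checks run 20 seeds of the default study (2,000 bins,
~1M analyzed pairs each) for the 1D-vs-3D direction, partner recovery, TAD
boundary recall (±1 bin) and SNP-rich vs control contrast; 20 seeds of a
400-bin null (no loops, `tau = 0`) for significance calibration; exact
enumeration oracles for the binomial tail (all `k <= n <= 30` over a p
grid) and BH correction (100 random lists up to length 1,000); brute-force
scans as the mapping oracle; and a byte-identity rerun of the full pipeline
for determinism. `scripts/acceptance.py` reports medians over 5 study
seeds and 10 null seeds.

## Known limitations

* The equal-occupancy stratum expectation is a step-function approximation
  of the decay curve; residual within-stratum gradient makes the test
  mildly anti-conservative at the short-distance edge of coarse strata
  (hence the fine default stratification) and mildly conservative at long
  range (zero truncation).
* `N` (the binomial sample size) is the total count of the analyzed run,
  so p-values are comparable within one dataset but not across datasets of
  different depth.
* TAD calling emits a flat, non-overlapping segmentation; nested domain
  structure is out of scope.
* With flagged (score-less) TFs the per-SNP statistic is a fraction of a
  small count and therefore strongly discrete; group medians of such
  fractions move in coarse steps.
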