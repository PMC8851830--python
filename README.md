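# snp3d

Linking non-coding GWAS variants to gene-regulatory elements and their
target genes through the 3D genome structure.

Most disease-associated SNPs found by genome-wide association studies fall
in non-coding DNA, where their functional targets are unclear: the gene a
variant regulates may lie hundreds of kbp away in the linear genome yet be
physically adjacent in the folded chromatin. `snp3d` implements a pipeline
that compares two ways of assigning regulatory elements (enhancers and
transcription-factor binding sites, each with disease-association scores
and target genes) to high-risk variants:

* **1D mapping** — elements inside a window of one Hi-C resolution centered
  on the SNP in the linear genome;
* **3D mapping** — elements inside the chromatin fragment forming the most
  confident significant Hi-C contact with the SNP's fragment.

It additionally calls topologically associating domains (TADs) and asks
whether TADs carrying high-risk SNPs contain more disease-associated
elements than control TADs. Because the original analyses rest on large
external resources (deep Hi-C maps, full GWAS summary statistics, enhancer
and TF databases), the package ships a first-class synthetic-data module
that generates complete, ground-truthed input bundles at desk scale.

## The statistics at the core

**Contact significance.** Binned contacts (FitHiC-style
`chrom1 mid1 chrom2 mid2 count`) are stratified by genomic distance into
equal-occupancy strata (inter-chromosomal pairs form one extra stratum).
With N the total read-pair count, a pair in stratum s with observed count k
gets the upper-tail binomial p-value

    p = P(X >= k),  X ~ Binomial(N, p_exp),
    p_exp = (total count in s) / (N * pairs in s),

Benjamini–Hochberg correction across all intra- and inter-chromosomal pairs
jointly, and the significant set is q <= 0.05 (inclusive).

**SNP mapping.** High-risk SNPs are those with association p <= 5×10⁻⁸
(inclusive). In 3D, every significant partner fragment containing at least
one element is a candidate; one fragment per SNP is selected — lowest
contact q-value, ties broken toward the longest-range contact (an
inter-chromosomal contact counts as longer than any intra-chromosomal one).
Per SNP the pipeline reports the median disease-association (DA) score of
mapped enhancers, TFs and target genes, or the fraction of
disease-associated TFs when TFs carry flags instead of numeric scores.
Distributions over SNPs are summarized by quartiles and the inter-quartile
range (IQR).

**TAD calling.** For each inter-bin boundary the boundary signal is the
mean count of the w×w cross-boundary submatrix (computed on the
observed/expected matrix so distance decay does not mimic depletion);
boundaries are signal local minima whose one-sided rank-sum test
(cross-boundary vs within-side counts) is significant. TADs containing a
high-risk SNP are SNP-rich, the rest are controls; per-TAD element DA
medians are compared between the groups.

## Worked example

`examples/02_map_variants_1d_vs_3d.py` simulates a full study — one
2,000-bin chromosome at 10 kbp with 40 planted chromatin loops and 60
high-risk SNPs at loop anchors — and maps every high-risk SNP both ways:

```
high-risk SNPs: 60 of 500
enhancer DA                  1D median  2.64   3D median  4.90
target-gene DA               1D median  2.55   3D median  4.89
disease-assoc. TF fraction   1D median  0.33   3D median  0.67
```

Elements reached through significant chromatin contacts carry markedly
higher disease-association scores than those in the SNP's linear window,
and about two-thirds of TFs mapped in 3D are disease-associated versus
one-third in 1D. `examples/03_tad_stratification.py` shows the TAD
counterpart (SNP-rich TAD enhancer median 3.45 vs control 2.55), and
`examples/01_contact_significance.py` the significance calling itself
(15/15 planted loops recovered at q <= 0.05).

The same stages are scriptable from a shell via the `snp3d` command
(`snp3d simulate | contacts | map | tads | all`); `snp3d all` writes every
table plus a manifest (config echo and input checksums) that makes reruns
byte-identical.

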