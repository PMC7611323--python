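# Methods

This note describes the statistical model behind each stage of the `rrhp`
pipeline, the default parameters, and the deliberate limitations of the
synthetic-data generator.

## 1. Site cataloguing

RRHP reads begin at CCGG (MspI) restriction sites. CCGG is its own reverse
complement, so each genomic occurrence exposes one measurable cytosine per
strand: an occurrence whose first base is at 1-based position *p* yields the
plus-strand site (*p*, +) and the minus-strand site (*p* + 3, −). The
catalogue is the sorted list of (chromosome, position, strand) triples over
all occurrences; `N` bases never match. BED export converts to 0-based
half-open single-base intervals. Because CCGG has no non-trivial self-overlap
(no proper prefix equals a suffix), occurrences cannot overlap and the
catalogue size is exactly twice the substring count.

## 2. Count assembly and filtering

A sample's count at a site is the number of its reads starting exactly at
that (chromosome, position, strand) key. When a catalogue is supplied,
off-catalogue read starts are dropped and tallied. Sites observed in no
sample are excluded; filtering only ever removes rows, never modifies counts.

Two sequential filters control false 5hmC sites:

1. **Group-presence filter.** A tissue group fails at a site when the sum of
   its replicates' counts is below `group_threshold` (default 1, i.e. all
   zero); the site is removed when at least `min_failing_groups` (default 2
   of 3) groups fail. Equivalently, a surviving site is detected in at least
   two tissues.
2. **Global-median filter.** Let *m* be the median over *all* count cells of
   the matrix that survives filter 1 (computing *m* after filter 1 matters:
   all-zero rows would otherwise drag it down). A site is removed when at
   least one tissue has **all** replicates ≤ *m*; counts exactly equal to the
   median are treated as low (≤ removed, > kept). An alternative rule
   (`any_samples`) removes a site when at least `sample_quorum` (default 5)
   samples are ≤ *m* regardless of tissue.

Library sizes are column sums of whichever matrix they are asked of.

## 3. Differential hydroxymethylation

Counts are transformed to log2 counts per million with a 0.5 prior count:
`y = log2((k + 0.5) / (lib + 1) * 1e6)`. Each site is fit by ordinary least
squares under a tissue-means design (one indicator column per tissue), so
coefficients are tissue means and the residual degrees of freedom are
d = n − rank (12 for 3 × 5 samples).

Residual variances are shrunk toward a common prior assuming
s² ~ s0²·F(d, d0), the marginal of a scaled inverse-chi-square prior. The
hyperparameters are estimated by moments matching on z = log s²:
var(z) − ψ′(d/2) = ψ′(d0/2) determines d0 (infinite when the left side is
≤ 0; ψ′ is inverted by Newton iteration on 1/ψ′, which is nearly linear), and
mean(z) determines s0² via the digamma identity
`mean(z) = log s0² + ψ(d/2) − log(d/2) − [ψ(d0/2) − log(d0/2)]`.

The moderated statistic for contrast weights w is
`t = w'β / sqrt(s̃² · w'(X'X)⁻¹w)` with `s̃² = (d0 s0² + d s²) / (d0 + d)`
and d0 + d degrees of freedom; d0 = ∞ uses a normal reference and d0 = 0
reduces exactly to the ordinary t. Sites with zero posterior variance are
flagged `degenerate` (p = 0) rather than dropped. Two-sided p-values are
Benjamini–Hochberg adjusted within each contrast (step-up,
q(i) = min over j ≥ i of p(j)·m/j, capped at 1). A site is called
differentially hydroxymethylated when q is **strictly** below the contrast's
threshold — defaults 0.01 (muscle vs liver), 0.05 (muscle vs pituitary),
0.01 (liver vs pituitary) — and is *hyper* in the contrast's first tissue
when logFC > 0.

## 4. Annotation and enrichment

Each site is assigned to the transcript whose TSS is nearest by absolute
signed distance (ties broken by smaller gene id, then transcript id), and
then classified against **that** transcript with precedence
promoter > TTS > exon > intron > intergenic. Distances are signed in
transcript orientation (positive downstream). The promoter window is
(−1000, +100) around the TSS and the TTS window (−100, +1000) around the
transcription end site, both inclusive. Exons and introns carry a (k, n)
index in transcript orientation.

Direction-vs-feature enrichment is a two-sided Fisher exact test on the 2 × 2
table (hyper/hypo × in/out of feature), with the sample odds ratio
(a·d)/(b·c) and significance tiers at 0.05 / 0.01 / 0.001. Gene-level call
sets collapse called sites to their nearest genes per contrast and direction,
excluding genes whose description matches "uncharacterized"
(case-insensitive, configurable). Relative feature enrichment classifies each
site by the tissue with the highest mean log2-CPM (exact ties excluded and
tallied) and reports, per tissue and feature,
`100 · (p_tf / mean over other tissues of p·f − 1)` where p_tf is the share
of that tissue's top sites in the feature.

## 5. 5hmC–expression association

Expression counts are normalized with median-of-ratios size factors (genes
with any zero count are excluded from the geometric-mean reference; if no
gene qualifies the factors fall back to column-sum ratios and the result is
flagged). Normalized expression is the per-gene mean over replicates of
log2(count / size factor + 1).

Each focal-tissue site joins its replicate-mean 5hmC count, signed TSS
distance and nearest gene's expression. Three summaries are computed:

* **PCA** on the 3 × 3 correlation matrix, with loadings defined as
  variable–component correlations (eigenvector × √eigenvalue, the largest
  |loading| of each component made positive); eigenvalues sum to 3 and cos²
  rows sum to 1.
* **Spearman** rank correlations (mid-ranks for ties) between each variable
  pair.
* **High/low comparisons**: within a region class (promoter, first exon,
  first intron) sites are aggregated to genes by the maximum of their mean
  5hmC, genes are split at the median (ties go to the low group), and the two
  groups' expression distributions are compared by a two-sided two-sample
  Kolmogorov–Smirnov test (exact p when n_high · n_low ≤ 10,000, asymptotic
  otherwise), with quartile summaries for reporting.

## 6. Synthetic-data generator

The generator is seeded through a single `numpy.random.SeedSequence` whose
children feed the four stages in a fixed order (genome = 0, annotation = 1,
counts = 2, expression = 3), so any stage is reproducible in isolation.

* **Genome**: a random background is scrubbed of CCGG (the second C of any
  occurrence is mutated to A, which cannot re-create the motif), then motifs
  are planted with exponential gaps on top of the 4 bp footprint, giving
  Poisson-spaced occurrences at the target density (default 2.5/kb). Since
  the motif starts CC and ends GG, junctions cannot create extra occurrences,
  so the planted list *is* the genome's exact catalogue.
* **Annotation**: non-overlapping genes placed sequentially with uniform
  intergenic gaps, exon counts and exon/intron lengths; random strands; a
  configurable fraction (default 0.1) of "uncharacterized" descriptions.
* **RRHP counts**: 75% of sites are captured (the assay's typical capture
  rate); captured sites draw lognormal baselines (log2 mean log2(50), sd 1);
  10% of captured sites receive a planted |log2FC| = 2 in one tissue
  (tissues cycled, signs alternating) on a fixed baseline mean of 50; counts
  are negative-binomial (gamma–Poisson) with dispersion 0.1 around
  mean × per-sample library factor (uniform 0.7–1.3). All-zero rows are
  dropped from both the matrix and the planted-truth table.
* **Expression**: negative-binomial gene counts for the focal tissue's
  replicates, whose log2 means are shifted by
  `coupling[region] · z(log2(1 + gene region 5hmC))` per region class;
  the default coupling is −1.0 for promoter, first exon and first intron,
  emulating a negative 5hmC–expression association.

What the generator deliberately does **not** emulate: read-level sequencing
error or mapping ambiguity (read starts are exact), CpG-island structure or
any sequence composition beyond the uniform background, isoform diversity
(one transcript per gene), biological covariance between neighbouring sites,
and between-replicate batch effects beyond a scalar library factor.

## 7. Numerical and design choices

* Standard primitives are delegated to established libraries — FASTA parsing
  (Biopython), GFF3 (gffutils), Fisher exact / KS / Spearman (SciPy) — while
  the pipeline-specific statistics (log-CPM, the OLS fit, the variance-prior
  moments matching, the moderated t, BH adjustment, median-of-ratios size
  factors, all filters and windows) are implemented in the package and
  verified against independent brute-force oracles in the test suite
  (hypergeometric enumeration, step-up double loops, lattice-path ECDF
  counting, normal equations, per-base feature maps).
* All thresholds and windows are configuration with the documented values as
  defaults; nothing is hard-coded in the stages.
* Outputs are plain text (TSV/JSON with sorted keys, no timestamps), so runs
  are byte-identical given the same seed, whether executed via `run-all` or
  by chaining subcommands.
* The BH step-up uses a stable mergesort and a reversed cumulative minimum;
  trigamma inversion uses the Newton step
  `x += ψ′(x)·(1 − ψ′(x)/y) / ψ″(x)`, accurate to ~1e-8 across the useful
  range.

## Limitations

The moderated test assumes approximately normal log-CPM residuals with a
shared variance prior; very low counts (near the filter boundary) are only
approximately handled by the 0.5 prior count. The nearest-TSS gene assignment
ignores overlapping gene structures beyond the tie rule. The KS median split
discards the magnitude of 5hmC differences within groups. Calibration results
in the test suite (null p < 0.05 fraction within [0.04, 0.06]; FDP control at
q < 0.05) are established on the generator's conditions and need not transfer
to data violating its assumptions.
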