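# Methods

## The filtering cascade

`enhpro` treats regulatory-SNP prioritization as a conjunction of
independent evidence filters applied to a GWAS-derived SNP set. The
stages, in order:

**Association.** Index SNPs are rows of a TSV association table with
`pvalue < gwas_p_threshold` (default 5×10⁻⁸, strict inequality). Indels
and multi-allelic records are dropped with a logged count: the downstream
allele-specific scoring is defined for single-base substitutions only.

**LD expansion.** Every genotype-panel site within
±`proxy_search_window_bp` (default 500 kb) of an index SNP on the same
contig with *r*² ≥ `r2_threshold` (default 0.8) becomes a proxy carrying
the index rsid and the *r*² of the link. A site tagging several index
SNPs keeps its strongest link; index SNPs are retained unchanged. *r*² is
D²/(p_A p_a p_B p_b). For phased panels the two-locus haplotype
frequencies are exact counts over 2n chromosomes (vectorized as a squared
Pearson correlation of haplotype indicators, which is algebraically
identical). For unphased panels they are maximum-likelihood estimates
from the standard two-locus EM: all genotype classes except the double
heterozygote resolve to known haplotype counts; the double heterozygote's
AB/ab vs Ab/aB split is re-weighted each iteration by the current
frequency estimates. Numerical choices: convergence when the largest
frequency change is below `em_tol` (10⁻⁸), at most `em_max_iter` (1000)
iterations, initialization at linkage equilibrium *and* at both full
phase assignments of the double heterozygotes (the likelihood can have
two global optima; running from all three starts and keeping the best,
with a D ≥ 0 tie-break at equal likelihood, makes the estimator
deterministic). Missing genotypes are handled by pairwise-complete
deletion, not imputation. Monomorphic loci raise an undefined-LD error;
inside proxy expansion such sites are skipped and logged.

**EnhPro chromatin filtering.** A SNP at 1-based position *p* overlaps a
0-based half-open track interval [s, e) iff s ≤ p−1 < e; all
cross-format queries reduce to this law. A SNP is EnhPro iff its focal
chromatin state is strong (`strong_states`, default {1, 3, 8, 9}: state 1
strong promoter, 3/8/9 strong enhancer in the 18-state model), the count
of the 12 comparison cell types whose state at the SNP is strong is
≤ `state_max_other` (3), a focal H3K27ac narrowPeak overlaps the SNP with
≤ `k27ac_max_other` (3; relaxed protocol 4) comparison cell types
sharing a peak there, and a focal DHS peak overlaps the SNP. The
chromatin-sharing and peak-sharing ceilings are independent counters by
design: the relaxed protocol raises only the H3K27ac one. DHS is
required in the focal cell type only. Variants on contigs absent from a
track count as non-overlapping. Comparison panels of a size other than
12 trigger a warning and the ceilings are applied as absolute counts.

**Gene prioritization.** SNPs are linked to their reported genes when
those exist in the annotation; otherwise to the nearest TSS on the same
contig (tie on distance broken by gene id). Proxies inherit the reported
genes of their index SNP. Signed TSS distance is (pos − tss)/1000 for
+-strand genes and (tss − pos)/1000 for −-strand genes, so negative
always means upstream of the TSS in the gene's reading direction. A gene
is *preferentially expressed* when focal RPKM / median RPKM over the 11
comparison cultures > `expr_ratio_min` (5) and focal RPKM >
`expr_focal_min_rpkm` (1). A zero comparison median with positive focal
expression gives ratio = ∞ (preferential); all-zero rows give ratio 0.
A candidate gene must be linked to ≥ 1 EnhPro SNP and either be
preferential or appear on a curated relevance list — the curated list is
this package's stand-in for interactive GO-enrichment screening, which
is not reproducible offline. An exclusion list is subtracted last.

**Imputed augmentation.** Imputed summary-statistics tables are read at
their own thresholds (total-body DXA at the GWAS threshold, eBMD at
6.6×10⁻⁹) and restricted to ± `imputed_locus_buffer_bp` (500 kb) around
candidate-gene spans; survivors re-enter the chromatin stage and are
merged with the index/proxy set (a SNP present in both keeps the
combined source class "I/P, Imp"). The buffer is a package choice wide
enough to cover every SNP-to-gene distance the workflow is expected to
report; imputed SNPs cannot create new candidate genes.

**Allele-specific TFBS.** For each EnhPro SNP linked to a candidate
gene, the reference 21-mer centered on the SNP (odd `tfbs_window`; the
assembly base must equal the declared ref allele) and its alt-substituted
copy are scanned against every PWM at every placement covering the SNP,
on both strands. TRANSFAC count matrices get `pwm_pseudocount` (0.01)
per cell before row normalization so fold changes stay finite. The
"position probability" of the fivefold rule is read at the single
SNP-aligned matrix position, not from a whole-window score. A placement
is allele-specific iff the allele fold change strictly exceeds
`tfbs_fold_min` (5), the favored allele passes curation, and the
disfavored allele fails curation or scores strictly lower. Curation at a
placement: (a) at every *conserved* position (best probability ≥
`conserved_prob_min`, 0.85) the sequence base must be a best base;
(b) at most one *partly conserved* position (best probability in
[`partly_conserved_prob_min`, `conserved_prob_min`) = [0.5, 0.85)) may
carry a partial match, i.e. a non-best base with probability ≥
`partial_match_min_frac` (0.2) of the position's best; (c) no position
of any class may fall below that fraction. The conservation-class
thresholds parameterize a notion that TRANSFAC treats as internal, so
they are config knobs rather than fixed constants; the same applies to
the exact reading of "partial match", which is one consistent
formalization of a manual rule. Finally the TF must have focal RPKM ≥
`tf_min_rpkm` (0.8, inclusive). Results per PWM are ordered by
favored-allele log-probability sum, ties broken by strand (+ first) then
smaller offset; the per-SNP output is the deduplicated, sorted set of
(TF, favored allele) pairs.

**Tier-1 assembly and report.** A Tier-1 SNP is EnhPro, linked to a
candidate gene, and has ≥ 1 allele-specific, expression-gated TFBS
prediction. The report prints one row per (gene, SNP) with distance to
0.1 kb; genes are grouped in order of first appearance, rows within a
gene ordered by distance. The chromatin display label is "Str prom" for
state 1, "Str enh" for 3/8/9, and "Str enh/prom" when strong segments of
both kinds touch the SNP's ± `state_label_window_bp`/2 (100 bp)
neighborhood — mixed labels arise at promoter/enhancer boundaries.

Identical inputs and configuration produce byte-identical reports and
stage-count JSON: no stage uses randomness.

## Stage tracing

`run_pipeline` returns a result object carrying, besides the Tier-1
records and per-stage counts, enough state to answer "at which stage did
SNP *x* drop out": association (sub-threshold), ld (panel site never
linked at the threshold), enhpro, gene (EnhPro but no candidate-gene
link), tfbs, or tier1. The per-stage counts follow the index/proxy
chain (index input ≤ index+proxy ≥ state+K27ac survivors ≥ EnhPro);
imputed SNPs are counted separately since they join mid-pipeline.

## The synthetic-data generator

`simulate` emulates the statistical structure of the real inputs at desk
scale; it does not attempt genome-scale marginals, population-genetic
realism beyond block LD, or the size of public GWAS/epigenome snapshots.

*Genotypes.* A block-mosaic model: per 50 kb block, a pool of 4 founder
haplotypes with Bernoulli(½) alleles; each of the 120 haplotypes (60
samples) copies one founder per block, switching founders within a block
with per-site probability 0.01 and redrawing independently at block
boundaries. This yields high within-block *r*² and near-zero
between-block *r*² (the generated default exceeds a 10-fold separation);
panel sites sit every 500 bp on two 600 kb contigs (2,400 sites).
Planted sites are forced to a balanced founder pattern so they are
polymorphic and remain in LD with their block.

*Chromatin.* Mostly quiescent (state 15 background segments away from
the planted loci); each planted signal gets a focal strong-enhancer
segment (state 9, ± 150 bp) shared by 2 comparison cell types (4 for the
`too_shared_state` defect), an H3K27ac peak nested inside it shared by 2
comparison types (4 for `too_shared_k27ac`), and a focal DHS peak nested
inside the peak (withheld for `no_dhs`).

*Expression.* Planted genes: focal RPKM 10 vs 0.5 in every comparison
culture (ratio 20), or 5.0 (ratio 2) for `gene_not_preferential`; filler
genes draw long-tailed log-normal values. Planted TFs have focal RPKM 5
(0.1 for `tf_not_expressed`).

*PWMs.* One engineered 11-wide matrix per signal that reaches the TFBS
stage: near-delta conserved columns copying the genomic 11-mer, with the
SNP-aligned column set to a 52:5 favored:disfavored count contrast
(≈ 10-fold; the 52 keeps the column's best probability above the
partly-conserved threshold). The `fold_below_5` decoy uses 42:10
(fold 4.2, both alleles surviving curation); `curation_fail` mismatches
one conserved flank column against the genome. Filler matrices are
14-wide random conserved-core motifs, too specific to match planted
windows by chance.

Truth labels (rsid, defect, expected rejection stage) are a sidecar TSV
the pipeline never reads. Ten defect-free signals and one decoy per
defect class are planted by default; a passing recovery test shows the
cascade implements each filter correctly on inputs whose evidence is
unambiguous by construction — it does not show robustness to the noise,
annotation error and LD complexity of real panels.

## The published-table fixture

`make_table1_fixture` builds a deterministic miniature genome whose five
gene loci and fourteen SNPs reproduce, by construction, a published
Tier-1 set: SNP positions are placed at the printed TSS distances,
alleles and focal chromatin labels match the printed rows, per-row
engineered PWMs yield exactly the printed TF calls on the printed allele
side, and the three DAAM2 SNPs share their focal H3K27ac peak with four
comparison cultures so they appear only under the relaxed protocol. The
five locus-anchoring index SNPs sit in quiescent chromatin (the printed
SNPs enter as their perfect-LD proxies or through the imputed tables at
the eBMD/DXA thresholds), and four decoys each violate exactly one
criterion. Synthetic rs-identifiers (rs9xxxxx) mark constructed
stand-ins. The fixture is a consistency target for the implementation,
not evidence about real data: it verifies that the cascade's logic,
thresholds and report formatting compose to the documented output.

## Problem sizes

The test suite and the acceptance script run the fixture (≈ 2.3 Mb of
sequence, 19 panel sites) and the default synthetic genome (2,400 sites,
13 cell types, 60 genes, 24 PWMs); both complete in seconds on one CPU.

## Known limitations

- TFBS prediction ignores sequence context beyond the 21-mer, TF
  cooperativity, DNA shape and methylation; the fivefold single-position
  rule is a deliberate simplification with known false positives and
  negatives.
- The curated gene list replaces GO-term enrichment; results depend on
  its contents.
- The EM estimator assumes random union of gametes (Hardy–Weinberg at
  the diplotype level) and biallelic sites.
- No liftover, no remote data fetching, no bigWig/bigBed support, no
  Bayesian fine-mapping.
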