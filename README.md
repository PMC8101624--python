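# enhpro

Prioritization of GWAS-derived regulatory SNPs by cell-type-preferential
epigenomics, transcriptomics and allele-specific transcription-factor
binding-site (TFBS) prediction.

Most trait-associated variants from genome-wide association studies are
non-coding, and the index SNP at a locus drags along many proxy SNPs in
linkage disequilibrium (LD) that are statistically indistinguishable from
it. `enhpro` implements a filtering cascade that narrows such a SNP set to
a small number of credible *regulatory* candidates for a focal cell type —
the motivating application is osteoblasts (ostb) and bone mineral density
(BMD) GWAS — by requiring that a candidate SNP:

1. is genome-wide significant itself (index SNP, *p* < 5×10⁻⁸) or in strong
   LD with one (proxy SNP, *r*² ≥ 0.8, estimated from a genotype panel by
   haplotype counting or an EM maximum-likelihood fit);
2. overlaps strong promoter chromatin (18-state segmentation state 1) or
   strong enhancer chromatin (states 3, 8 or 9) in the focal cell type but
   in no more than 3 of 12 heterologous cell cultures, overlaps a focal
   H3K27ac narrowPeak shared by no more than 3 (relaxed: 4) of those 12,
   and overlaps a focal DNaseI-hypersensitivity (DHS) peak — an **EnhPro
   SNP**;
3. is linked to a gene that is preferentially expressed in the focal cell
   type (RPKM ratio over the median of 11 heterologous cultures > 5, focal
   RPKM > 1) or appears on a curated relevance list;
4. carries a predicted allele-specific TFBS: scanning both alleles' 21-mers
   against TRANSFAC-style position weight matrices, the PWM probability of
   the two allele bases at the SNP-aligned position must differ by more
   than fivefold, the favored allele's sequence must survive curation
   (exact match at every conserved matrix position, at most one partial
   match — ≥ 20% of the best probability — at a partly conserved position),
   and the TF must be expressed in the focal cell type (RPKM ≥ 0.8).

SNPs surviving all four stages are **Tier-1 SNPs**. Imputed
summary-statistics SNPs near the candidate genes (DXA BMD at *p* < 5×10⁻⁸,
eBMD at *p* < 6.6×10⁻⁹) are folded in after gene selection and re-enter the
chromatin and TFBS stages.

For LD, *r*² = D²/(p_A p_a p_B p_b) with D = p_AB − p_A p_B, where the
two-locus haplotype frequencies come from phased haplotype counts or, for
unphased genotypes, from an EM estimator that resolves the
double-heterozygote phase ambiguity (deterministic D ≥ 0 tie-break between
equal-likelihood optima).

## Worked example

The package ships a deterministic miniature-genome fixture with five gene
loci (BICC1, NPR3, LGR4, HMGA2, DAAM2), a phased 20-sample genotype panel,
13 chromatin segmentations with matching H3K27ac/DHS peaks, an expression
matrix and engineered PWMs. Build it and run the full pipeline with the
relaxed H3K27ac-sharing threshold:

```sh
enhpro fixture /tmp/fx
enhpro --config /tmp/fx/config_relaxed.toml run /tmp/fx --out-dir /tmp/out
```

The run logs per-stage counts and prints the stage-count JSON:

```
INFO enhpro.pipeline: stage association: 6 index SNPs
INFO enhpro.pipeline: stage ld: 19 index+proxy SNPs
INFO enhpro.pipeline: stage enhpro: 14 state+K27ac survivors, 13 EnhPro SNPs
INFO enhpro.pipeline: stage gene: 5 candidate genes
INFO enhpro.pipeline: stage tier1: 14 Tier-1 SNPs
{"n_candidate_genes": 5, "n_enhpro": 13, "n_imputed": 11, "n_index_input": 6,
 "n_index_proxy": 19, "n_state_k27ac": 14, "n_tier1": 14}
```

`/tmp/out/tier1_report.tsv` begins:

```
gene	tier1_snp	source	distance_to_tss_kb	alleles_ref_alt	chromatin_state	tf_ref	tf_alt
BICC1	rs112597538	I/P	-0.1	T/C	Str prom	SREBF1/2	None
BICC1	rs1896245	I/P, Imp	3.2	T/G	Str enh/prom	SATB1	None
BICC1	rs1896243	I/P, Imp	3.5	C/T	Str enh	None	TCF3
```

Each row is one Tier-1 SNP: its associated gene, whether it entered as an
index/proxy (`I/P`) or imputed (`Imp`) SNP, its signed distance to the gene
TSS in kb (negative = upstream relative to gene strand), its alleles, the
focal chromatin-state label at the SNP, and the TFs predicted to bind each
allele specifically. With the default (stringent) configuration the same
bundle yields 11 Tier-1 SNPs: the three DAAM2 SNPs appear only when the
H3K27ac sharing ceiling is raised from 3 to 4.

Synthetic data with planted ground truth for every filter is available via

```sh
enhpro --seed 1 simulate /tmp/sim
enhpro --config /tmp/sim/config.toml run /tmp/sim --out-dir /tmp/simout
```

where `truth_labels.tsv` records each planted SNP's defect class and the
stage at which the pipeline must reject it.

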