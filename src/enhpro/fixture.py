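"""Deterministic miniature-genome fixture encoding the published Tier-1 set.

Fourteen prioritized SNPs in five bone-related genes (BICC1, NPR3, LGR4,
HMGA2, DAAM2) are placed on toy contigs at offsets reproducing the printed
SNP-to-TSS distances, with chromatin segmentations, H3K27ac/DHS peaks,
expression values and engineered PWMs that reproduce each SNP's published
evidence: chromatin-state label, index/proxy vs imputed provenance, and the
allele side of every predicted TF.  The three DAAM2 SNPs share their ostb
H3K27ac peak with four comparison cell cultures, so they appear only under
the relaxed protocol (k27ac_max_other = 4).  Decoy SNPs that each fail
exactly one criterion are included with truth labels.

The five index SNPs and the decoys carry synthetic rs-identifiers: they are
stand-ins constructed for the fixture, not catalogued variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, tfbs
from .config import Config, dump_config
from .model import GeneModel, GenomeAssembly, GenomicInterval, ExpressionTable
from .pipeline import InputBundle

FOCAL = "ostb"
CHROMATIN_CELLS = [
    "fib_skin", "fib_lung", "fib_lung_fetal", "keratinocyte_fs",
    "keratinocyte_derm", "melanocyte", "astrocyte", "huvec", "myoblast",
    "hmec", "esc", "lcl",
]
EXPRESSION_CELLS = [c for c in CHROMATIN_CELLS if c != "keratinocyte_derm"]

_SEED = 20210319

# gene_id, chrom, strand, tss (1-based), span (0-based half-open), contig length
GENES = [
    ("BICC1", "chr10", "+", 300_001, (300_000, 350_000), 600_000),
    ("NPR3", "chr5", "+", 150_001, (150_000, 200_000), 400_000),
    ("LGR4", "chr11", "-", 150_000, (100_000, 150_000), 500_000),
    ("HMGA2", "chr12", "+", 300_001, (300_000, 350_000), 400_000),
    ("DAAM2", "chr6", "+", 100_001, (100_000, 150_000), 300_000),
    ("FILLER1", "chr20", "+", 50_001, (50_000, 60_000), 120_000),
]

# synthetic index SNPs anchoring each locus (quiescent chromatin, so they
# never become Tier-1 themselves)
INDEX_SNPS = [
    ("rs900001", "BICC1", "chr10", 310_000),
    ("rs900002", "NPR3", "chr5", 250_000),
    ("rs900003", "LGR4", "chr11", 330_000),
    ("rs900004", "HMGA2", "chr12", 70_000),
    ("rs900005", "DAAM2", "chr6", 160_000),
    ("rs900102", "FILLER1", "chr20", 52_001),  # gene-stage decoy, full chromatin
]

# rsid, gene, pos, ref, alt, chromatin label kind, source class, tf_ref,
# tf_alt, H3K27ac sharing count among the 12 comparison cultures
TIER1_SNPS = [
    ("rs112597538", "BICC1", 299_901, "T", "C", "prom", "I/P", ["SREBF1/2"], [], 3),
    ("rs1896245", "BICC1", 303_201, "T", "G", "enh_prom", "I/P, Imp", ["SATB1"], [], 3),
    ("rs1896243", "BICC1", 303_501, "C", "T", "enh", "I/P, Imp", [], ["TCF3"], 3),
    ("rs11006188", "BICC1", 360_601, "G", "C", "enh", "Imp", ["SMAD", "GLIS3"], ["NR2F6"], 3),
    ("rs1982173", "BICC1", 361_201, "G", "T", "enh", "Imp", ["RBPJ"], [], 3),
    ("rs1173771", "NPR3", 254_301, "A", "G", "enh", "I/P", ["SATB1"], [], 3),
    ("rs7733331", "NPR3", 268_101, "T", "C", "enh", "I/P", ["GTF2I"], [], 3),
    ("rs10835153", "LGR4", 331_000, "A", "T", "enh", "I/P, Imp", [], ["BPTF"], 3),
    ("rs80019710", "HMGA2", 68_901, "C", "T", "enh", "Imp", [], ["HMGA1"], 3),
    ("rs17101510", "HMGA2", 69_001, "C", "T", "enh", "I/P, Imp", [], ["YY1"], 3),
    ("rs12296417", "HMGA2", 69_501, "T", "A", "enh", "I/P, Imp", [], ["SATB1", "ZBTB20"], 3),
    ("rs2504105", "DAAM2", 162_401, "A", "G", "enh_prom", "I/P, Imp", ["SMAD"], [], 4),
    ("rs2504104", "DAAM2", 162_421, "A", "G", "enh_prom", "I/P, Imp", [], ["RUNX2/1", "CBFB"], 4),
    ("rs2504103", "DAAM2", 162_461, "C", "G", "enh_prom", "I/P, Imp", [], ["NFIC"], 4),
]

# decoys: rsid, gene, chrom, pos, defect, expected rejection stage
DECOYS = [
    ("rs900101", "BICC1", "chr10", 305_001, "no_dhs", "enhpro"),
    ("rs900102", "FILLER1", "chr20", 52_001, "gene_not_preferential", "gene"),
    ("rs900103", "NPR3", "chr5", 260_001, "fold_below_5", "tfbs"),
    ("rs900104", "FILLER1", "chr20", 55_001, "p_above_threshold", "association"),
]


@dataclass
class FixtureBundle:
    run_dir: Path
    bundle: InputBundle
    config: Config
    relaxed_config: Config


def _default_config() -> Config:
    return Config(
        focal_cell_type=FOCAL,
        chromatin_comparison_cell_types=tuple(CHROMATIN_CELLS),
        expression_comparison_cell_types=tuple(EXPRESSION_CELLS),
        rng_seed=_SEED,
    )


def _plant_cluster(segments, pos0_list, kind):
    """Append the ostb segment layout for one SNP cluster (0-based coords)."""
    if kind == "prom":
        (p,) = pos0_list
        segments.append((p - 150, p + 150, 1))
    elif kind == "enh":
        lo = min(pos0_list) - 150
        hi = max(pos0_list) + 150
        segments.append((lo, hi, 9))
    elif kind == "enh_prom":
        lo = min(pos0_list)
        hi = max(pos0_list)
        segments.append((lo - 60, lo + 20, 1))
        segments.append((lo + 20, hi + 100, 9))
    else:  # pragma: no cover
        raise ValueError(kind)


def _center_counts(consensus_base: str, favored: str, disfavored: str) -> list[float]:
    """Count row for the SNP-aligned PWM column: ~10-fold allele contrast."""
    counts = {b: 0.0 for b in "ACGT"}
    counts[favored] = 50.0
    counts[disfavored] = 5.0
    rest = [b for b in "ACGT" if b not in (favored, disfavored)]
    counts[rest[0]] = 40.0
    counts[rest[1]] = 5.0
    return [counts[b] for b in "ACGT"]


def _engineered_pwm(matrix_id, tf_name, window11, snp_index, favored, disfavored,
                    center_counts=None):
    """11-wide count matrix: conserved consensus, contrast at the SNP column."""
    rows = []
    for i, base in enumerate(window11):
        if i == snp_index:
            rows.append(
                center_counts
                if center_counts is not None
                else _center_counts(base, favored, disfavored)
            )
        else:
            rows.append([97.0 if b == base else 1.0 for b in "ACGT"])
    return (matrix_id, tf_name, np.array(rows))


def make_table1_fixture(out_dir) -> FixtureBundle:
    """Write the fixture into ``out_dir`` and return bundle + configs."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(_SEED)
    config = _default_config()
    relaxed = config.replace(k27ac_max_other=4)

    contig_lengths = {chrom: length for _, chrom, _, _, _, length in GENES}
    sequences = {
        chrom: "".join(rng.choice(list("ACGT"), size=length))
        for chrom, length in contig_lengths.items()
    }
    gene_by_id = {
        gid: GeneModel(gid, chrom, tss, strand, GenomicInterval(chrom, *span))
        for gid, chrom, strand, tss, span, _ in GENES
    }

    # pin the reference base at every variant position
    def set_base(chrom, pos, base):
        s = sequences[chrom]
        sequences[chrom] = s[: pos - 1] + base + s[pos:]

    for rsid, gene, pos, ref, alt, *_ in TIER1_SNPS:
        set_base(gene_by_id[gene].chrom, pos, ref)
    for rsid, gene, chrom, pos in INDEX_SNPS:
        set_base(chrom, pos, "A")
    for rsid, gene, chrom, pos, defect, stage in DECOYS:
        set_base(chrom, pos, "A")

    assembly = GenomeAssembly(sequences)
    io.write_fasta(assembly, d / "genome.fa")

    # --- gene models, expression, curated list
    io.write_gene_models_gtf(list(gene_by_id.values()), d / "genes.gtf")
    tf_names = sorted(
        {tf for row in TIER1_SNPS for tf in row[7] + row[8]} | {"DECOYTF", "SILENTTF"}
    )
    expr_rows = {
        "BICC1": 12.0, "NPR3": 8.0, "LGR4": 6.0, "DAAM2": 10.5,
        "HMGA2": 0.6, "FILLER1": 0.9,
    }
    frame_rows = {}
    for gene, focal_rpkm in expr_rows.items():
        frame_rows[gene] = [focal_rpkm] + [0.5] * len(EXPRESSION_CELLS)
    for tf in tf_names:
        rpkm = 0.1 if tf == "SILENTTF" else 5.0
        frame_rows[tf] = [rpkm] + [1.0] * len(EXPRESSION_CELLS)
    frame = pd.DataFrame.from_dict(
        frame_rows, orient="index", columns=[FOCAL, *EXPRESSION_CELLS]
    )
    io.write_expression_table(ExpressionTable(frame), d / "expression.tsv")
    io.write_gene_list(["HMGA2", "BMP5", "DLX6"], d / "curated_genes.txt")

    # --- chromatin tracks
    clusters: list[tuple[str, list[int], str, int]] = []  # chrom, pos0 list, kind, k27 share
    by_key: dict[tuple, list] = {}
    for rsid, gene, pos, ref, alt, kind, source, tf_ref, tf_alt, n_k27 in TIER1_SNPS:
        chrom = gene_by_id[gene].chrom
        by_key.setdefault((chrom, kind, n_k27, gene), []).append(pos - 1)
    # split BICC1 enh cluster members that are far apart into singletons
    for (chrom, kind, n_k27, gene), positions in by_key.items():
        positions.sort()
        group: list[int] = []
        for p in positions:
            if group and p - group[-1] > 1000:
                clusters.append((chrom, group, kind, n_k27))
                group = []
            group.append(p)
        clusters.append((chrom, group, kind, n_k27))
    # decoys with planted chromatin
    clusters.append(("chr10", [305_000], "enh", 3))  # rs900101 (DHS withheld)
    clusters.append(("chr20", [52_000], "enh", 3))  # rs900102
    clusters.append(("chr5", [260_000], "enh", 3))  # rs900103

    seg_by_cell: dict[str, list] = {c: [] for c in [FOCAL, *CHROMATIN_CELLS]}
    k27_by_cell: dict[str, list] = {c: [] for c in [FOCAL, *CHROMATIN_CELLS]}
    dhs_by_cell: dict[str, list] = {FOCAL: []}
    for chrom, positions, kind, n_k27 in clusters:
        focal_segments: list[tuple[int, int, int]] = []
        _plant_cluster(focal_segments, positions, kind)
        lo = min(s for s, _, _ in focal_segments)
        hi = max(e for _, e, _ in focal_segments)
        for s, e, state in focal_segments:
            seg_by_cell[FOCAL].append(GenomicInterval(chrom, s, e, str(state)))
        for cell in CHROMATIN_CELLS[:3]:  # strong chromatin shared by 3 others
            seg_by_cell[cell].append(GenomicInterval(chrom, lo, hi, "9"))
        for cell in [FOCAL, *CHROMATIN_CELLS[:n_k27]]:
            k27_by_cell[cell].append(GenomicInterval(chrom, lo - 20, hi + 20, "peak"))
        if positions != [305_000]:  # the no_dhs decoy gets no focal DHS
            dhs_by_cell[FOCAL].append(GenomicInterval(chrom, lo, hi, "dhs"))
    # quiescent background away from the planted loci
    for cell in [FOCAL, *CHROMATIN_CELLS]:
        for chrom in contig_lengths:
            seg_by_cell[cell].append(GenomicInterval(chrom, 0, 10_000, "15"))

    seg_dir, k27_dir, dhs_dir = d / "segmentation", d / "k27ac", d / "dhs"
    for sub in (seg_dir, k27_dir, dhs_dir):
        sub.mkdir(exist_ok=True)
    from .model import SegmentationTrack, PeakTrack

    for cell in [FOCAL, *CHROMATIN_CELLS]:
        io.write_segmentation_bed(
            SegmentationTrack(cell, seg_by_cell[cell]), seg_dir / f"{cell}.bed"
        )
        io.write_narrowpeak(
            PeakTrack(cell, "H3K27ac", k27_by_cell[cell]),
            k27_dir / f"{cell}.narrowPeak",
        )
        dhs_ivs = dhs_by_cell.get(cell, [])
        io.write_narrowpeak(
            PeakTrack(cell, "DHS", dhs_ivs), dhs_dir / f"{cell}.narrowPeak"
        )

    # --- association table, imputed tables
    assoc_rows = []
    for rsid, gene, chrom, pos in INDEX_SNPS:
        assoc_rows.append((rsid, chrom, pos, "A", "G", 1e-9, gene))
    assoc_rows.append(("rs900104", "chr20", 55_001, "A", "G", 1e-7, "FILLER1"))
    with open(d / "associations.tsv", "w") as fh:
        fh.write("rsid\tchrom\tpos\tref\talt\tpvalue\treported_genes\n")
        for rsid, chrom, pos, ref, alt, p, gene in assoc_rows:
            fh.write(f"{rsid}\t{chrom}\t{pos}\t{ref}\t{alt}\t{p}\t{gene}\n")

    tier1_by_rsid = {row[0]: row for row in TIER1_SNPS}
    imp_ebmd = [
        r for r in TIER1_SNPS if "Imp" in r[6] and r[0] != "rs11006188"
    ]
    with open(d / "imputed_ebmd.tsv", "w") as fh:
        fh.write("rsid\tchrom\tpos\tref\talt\tpvalue\treported_genes\n")
        for rsid, gene, pos, ref, alt, *_ in imp_ebmd:
            chrom = gene_by_id[gene].chrom
            fh.write(f"{rsid}\t{chrom}\t{pos}\t{ref}\t{alt}\t1e-10\t{gene}\n")
    with open(d / "imputed_dxa.tsv", "w") as fh:
        fh.write("rsid\tchrom\tpos\tref\talt\tpvalue\treported_genes\n")
        row = tier1_by_rsid["rs11006188"]
        fh.write(
            f"rs11006188\tchr10\t{row[2]}\t{row[3]}\t{row[4]}\t1e-9\tBICC1\n"
        )
        # far from every candidate gene: must be excluded by the buffer rule
        fh.write("rs900200\tchr20\t90000\tA\tG\t1e-12\tFILLER1\n")

    # --- genotype panel: index + I/P SNPs per locus in perfect LD
    from .ld import GenotypePanel, SiteRecord

    n_samples = 20
    samples = [f"S{i:02d}" for i in range(n_samples)]
    pattern = np.zeros(2 * n_samples, dtype=np.int8)
    pattern[:16] = 1  # alt-allele frequency 0.4, identical at linked sites
    loci, hap_cols = [], []
    for rsid, gene, chrom, pos in INDEX_SNPS:
        if gene == "FILLER1" and rsid == "rs900102":
            continue  # chr20 decoy index is deliberately absent from the panel
        loci.append(SiteRecord(rsid, chrom, pos, "A", "G"))
        hap_cols.append(pattern)
    for rsid, gene, pos, ref, alt, kind, source, *_ in TIER1_SNPS:
        if "I/P" not in source:
            continue
        chrom = gene_by_id[gene].chrom
        loci.append(SiteRecord(rsid, chrom, pos, ref, alt))
        hap_cols.append(pattern)
    for rsid, chrom, pos in [("rs900101", "chr10", 305_001), ("rs900103", "chr5", 260_001)]:
        loci.append(SiteRecord(rsid, chrom, pos, "A", "G"))
        hap_cols.append(pattern)
    haplotypes = np.stack(hap_cols, axis=1)
    dosage = haplotypes[0::2, :] + haplotypes[1::2, :]
    panel = GenotypePanel(
        samples=samples,
        loci=loci,
        dosage=dosage.astype(np.int8),
        phased=True,
        haplotypes=haplotypes,
    )
    io.write_vcf_panel(panel, d / "panel.vcf", contig_lengths)

    # --- engineered PWMs reproducing each row's allele-specific TF calls
    pwm_defs = []
    counter = 0
    for rsid, gene, pos, ref, alt, kind, source, tf_ref, tf_alt, _ in TIER1_SNPS:
        chrom = gene_by_id[gene].chrom
        window11 = assembly.fetch(chrom, pos - 1 - 5, pos + 5)
        for tf, favored, disfavored in (
            [(tf, ref, alt) for tf in tf_ref] + [(tf, alt, ref) for tf in tf_alt]
        ):
            counter += 1
            pwm_defs.append(
                _engineered_pwm(f"M{counter:04d}", tf, window11, 5, favored, disfavored)
            )
    # decoy: 4.2-fold contrast, both alleles survive curation, fails the rule
    window11 = assembly.fetch("chr5", 260_000 - 5, 260_000 + 6)
    decoy_center = {b: 0.0 for b in "ACGT"}
    decoy_center["A"] = 42.0  # ref
    decoy_center["G"] = 10.0  # alt: 10/42 partial match, fold 4.2
    rest = [b for b in "ACGT" if b not in "AG"]
    decoy_center[rest[0]] = 40.0
    decoy_center[rest[1]] = 8.0
    pwm_defs.append(
        _engineered_pwm(
            "M9001", "DECOYTF", window11, 5, "A", "G",
            center_counts=[decoy_center[b] for b in "ACGT"],
        )
    )
    tfbs.write_transfac(pwm_defs, d / "pwms.transfac")

    # --- truth labels (sidecar; never consumed by the pipeline)
    with open(d / "truth_labels.tsv", "w") as fh:
        fh.write("rsid\tdefect\texpected_rejection_stage\n")
        for rsid, *_ in TIER1_SNPS:
            fh.write(f"{rsid}\tnone\ttier1\n")
        for rsid, gene, chrom, pos, defect, stage in DECOYS:
            fh.write(f"{rsid}\t{defect}\t{stage}\n")

    dump_config(config, d / "config.toml")
    dump_config(relaxed, d / "config_relaxed.toml")
    bundle = InputBundle.from_dir(d, config)
    return FixtureBundle(run_dir=d, bundle=bundle, config=config, relaxed_config=relaxed)
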