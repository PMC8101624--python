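"""Readers and writers for every external format the pipeline touches.

Association tables, expression matrices and reports are TSV; chromatin
segmentations are BED4 with 18-state labels; peaks are narrowPeak (BED6+4);
gene models are GTF; reference sequence is FASTA.  Every writer round-trips
exactly through its reader.
"""

from __future__ import annotations

import logging
import warnings

import pandas as pd
import pyfaidx
import pyranges

from .model import (
    STATE_MNEMONICS,
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    ExpressionTable,
    PeakTrack,
    SegmentationTrack,
    Variant,
)

logger = logging.getLogger(__name__)

ASSOCIATION_COLUMNS = ["rsid", "chrom", "pos", "ref", "alt", "pvalue", "reported_genes"]


# ---------------------------------------------------------------------------
# association tables

def read_association_table(path, p_threshold: float | None) -> list[Variant]:
    """Load a GWAS association TSV, keeping rows with ``pvalue < p_threshold``.

    Pass ``p_threshold=None`` to keep all rows (used for stage tracing).
    Indels and multi-allelic records are dropped with a logged count; row
    order is preserved.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in ASSOCIATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    variants: list[Variant] = []
    n_dropped = 0
    for i, row in enumerate(table.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            pvalue = float(row.pvalue)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}, line {line_no}: unparsable p-value {row.pvalue!r}"
            ) from None
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or "," in str(row.alt):
            n_dropped += 1
            continue
        if p_threshold is not None and not pvalue < p_threshold:
            continue
        genes = []
        if isinstance(row.reported_genes, str) and row.reported_genes not in ("", "."):
            genes = [g.strip() for g in row.reported_genes.split(",") if g.strip()]
        variants.append(
            Variant(
                rsid=str(row.rsid),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_allele=ref,
                alt_allele=alt,
                source="index",
                pvalue=pvalue,
                reported_genes=genes,
            )
        )
    if n_dropped:
        logger.info("%s: dropped %d non-SNV record(s)", path, n_dropped)
    return variants


def write_association_table(variants: list[Variant], path) -> None:
    rows = [
        {
            "rsid": v.rsid,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref_allele,
            "alt": v.alt_allele,
            "pvalue": v.pvalue,
            "reported_genes": ",".join(v.reported_genes),
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# chromatin tracks

def _parse_state_label(label: str) -> int:
    """Accept both '9_EnhA1'-style mnemonics and bare integers."""
    head = label.split("_", 1)[0]
    try:
        state = int(head)
    except ValueError:
        raise ValueError(f"unknown chromatin state label {label!r}") from None
    if not 1 <= state <= 18:
        raise ValueError(f"chromatin state out of range 1..18: {label!r}")
    return state


def read_segmentation_bed(path, cell_type: str) -> SegmentationTrack:
    """BED4 segmentation; overlapping segments on one contig are an error."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: segmentation line has <4 columns: {line!r}")
            state = _parse_state_label(fields[3])
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), str(state))
            )
    return SegmentationTrack(cell_type, intervals)


def write_segmentation_bed(track: SegmentationTrack, path) -> None:
    ivs = sorted(track.intervals, key=lambda iv: (iv.chrom, iv.start))
    with open(path, "w") as fh:
        for iv in ivs:
            state = int(iv.label)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{state}_{STATE_MNEMONICS[state]}\n")


def read_narrowpeak(path, cell_type: str, mark: str) -> PeakTrack:
    """narrowPeak (BED6+4); column 10 is the summit offset, -1 = absent."""
    intervals, summits = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(
                    f"{path}: narrowPeak line has {len(fields)} columns, need 10"
                )
            start, end = int(fields[1]), int(fields[2])
            summit = int(fields[9])
            intervals.append(GenomicInterval(fields[0], start, end, fields[3]))
            summits.append(None if summit == -1 else summit)
    return PeakTrack(cell_type, mark, intervals, summits)


def write_narrowpeak(track: PeakTrack, path) -> None:
    with open(path, "w") as fh:
        for iv, summit in zip(track.intervals, track.summit_offsets):
            name = iv.label or "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t.\t0\t-1\t-1\t"
                f"{-1 if summit is None else summit}\n"
            )


# ---------------------------------------------------------------------------
# sequence

def read_fasta_assembly(path) -> GenomeAssembly:
    fasta = pyfaidx.Fasta(str(path), as_raw=True, rebuild=True)
    return GenomeAssembly({name: str(fasta[name][:]) for name in fasta.keys()})


def write_fasta(assembly: GenomeAssembly, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in assembly.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch_window(assembly: GenomeAssembly, chrom: str, pos: int, window: int) -> str:
    """Return the odd-length sequence window centered on a 1-based position.

    Windows clipped by a contig edge are an error (no padding); a window
    containing N emits a warning but is still returned.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    half = (window - 1) // 2
    seq = assembly.fetch(chrom, pos - 1 - half, pos + half)
    if "N" in seq:
        warnings.warn(f"window at {chrom}:{pos} contains N", stacklevel=2)
    return seq


def apply_allele(window: str, allele: str) -> str:
    """Copy of the window with the center base replaced by ``allele``."""
    if len(window) % 2 == 0:
        raise ValueError("window must have odd length")
    if allele not in "ACGT":
        raise ValueError(f"invalid allele {allele!r}")
    center = len(window) // 2
    return window[:center] + allele + window[center + 1 :]


# ---------------------------------------------------------------------------
# expression and gene models

def read_expression_table(path) -> ExpressionTable:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(frame)


def write_expression_table(table: ExpressionTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_models_gtf(path) -> list[GeneModel]:
    """Load 'gene' features from a GTF; TSS derived from strand."""
    gr = pyranges.read_gtf(str(path))
    df = gr.df
    df = df[df.Feature == "gene"]
    models = []
    for row in df.itertuples(index=False):
        start, end = int(row.Start), int(row.End)  # pyranges: 0-based half-open
        strand = str(row.Strand)
        tss = start + 1 if strand == "+" else end
        models.append(
            GeneModel(
                gene_id=str(row.gene_id),
                chrom=str(row.Chromosome),
                tss=tss,
                strand=strand,
                span=GenomicInterval(str(row.Chromosome), start, end),
            )
        )
    return models


def write_gene_models_gtf(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(
                f"{m.chrom}\tenhpro\tgene\t{m.span.start + 1}\t{m.span.end}\t.\t"
                f'{m.strand}\t.\tgene_id "{m.gene_id}"; gene_name "{m.gene_id}";\n'
            )


# ---------------------------------------------------------------------------
# genotype panels (VCF)

def read_vcf_panel(path):
    """Load biallelic SNVs from a VCF into a GenotypePanel.

    Multi-allelic and indel records are dropped with a logged count.  The
    panel is flagged phased only when every genotype is phased.
    """
    import cyvcf2

    from .ld import GenotypePanel, SiteRecord

    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    loci: list[SiteRecord] = []
    dosage_rows, hap_rows = [], []
    all_phased = True
    n_dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_dropped += 1
            continue
        if rec.REF not in "ACGT" or rec.ALT[0] not in "ACGT":
            n_dropped += 1
            continue
        loci.append(
            SiteRecord(
                rsid=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
            )
        )
        dos, haps = [], []
        for gt in rec.genotypes:
            a1, a2, phased = gt[0], gt[1], gt[2]
            if a1 < 0 or a2 < 0:
                dos.append(-1)
                haps.extend([-1, -1])
            else:
                dos.append(a1 + a2)
                haps.extend([a1, a2])
            all_phased = all_phased and bool(phased)
        dosage_rows.append(dos)
        hap_rows.append(haps)
    if n_dropped:
        logger.info("%s: dropped %d non-biallelic-SNV record(s)", path, n_dropped)
    import numpy as np

    dosage = np.array(dosage_rows, dtype=np.int8).T if dosage_rows else np.zeros((len(samples), 0), dtype=np.int8)
    haplotypes = np.array(hap_rows, dtype=np.int8).T if hap_rows else None
    return GenotypePanel(
        samples=samples,
        loci=loci,
        dosage=dosage,
        phased=all_phased and haplotypes is not None,
        haplotypes=haplotypes if all_phased else None,
    )


def write_vcf_panel(panel, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypePanel as a phased (or unphased) VCF."""
    sep = "|" if panel.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        order = sorted(range(len(panel.loci)), key=lambda i: (panel.loci[i].chrom, panel.loci[i].pos))
        for i in order:
            site = panel.loci[i]
            gts = []
            for s in range(len(panel.samples)):
                if panel.phased and panel.haplotypes is not None:
                    a1 = panel.haplotypes[2 * s, i]
                    a2 = panel.haplotypes[2 * s + 1, i]
                else:
                    d = panel.dosage[s, i]
                    if d < 0:
                        a1 = a2 = -1
                    else:
                        a1, a2 = (d + 1) // 2, d // 2
                gts.append(
                    "./." if a1 < 0 else f"{a1}{sep}{a2}"
                )
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.rsid}\t{site.ref}\t{site.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one id per line, '#' comments allowed."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genes.append(line)
    return genes


def write_gene_list(genes: list[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")
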