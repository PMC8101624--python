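"""End-to-end Tier-1 SNP prioritization.

Stages: read index SNPs -> LD proxy expansion -> EnhPro chromatin calling ->
gene linking and candidate selection -> imputed-SNP augmentation at the
candidate loci -> allele-specific TFBS prediction -> Tier-1 report.  A SNP
is Tier-1 iff it is EnhPro, linked to a candidate gene, and carries at least
one expressed-TF allele-specific binding prediction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import chromatin, genes as genes_mod, io, ld, tfbs
from .config import Config, load_config
from .model import GeneModel, Variant

logger = logging.getLogger(__name__)

STAGES = ("association", "ld", "enhpro", "gene", "tfbs", "tier1")


@dataclass
class InputBundle:
    """File paths for one pipeline run."""

    association: Path
    vcf: Path
    fasta: Path
    segmentation: dict[str, Path]
    k27ac: dict[str, Path]
    dhs: dict[str, Path]
    expression: Path
    gtf: Path
    transfac: Path
    curated: Path | None = None
    imputed_tables: list[tuple[Path, float]] = field(default_factory=list)

    @classmethod
    def from_dir(cls, run_dir, config: Config) -> "InputBundle":
        """Assemble a bundle from the layout simulate/fixture write."""
        d = Path(run_dir)
        cells = [config.focal_cell_type, *config.chromatin_comparison_cell_types]
        seg = {c: d / "segmentation" / f"{c}.bed" for c in cells}
        k27 = {c: d / "k27ac" / f"{c}.narrowPeak" for c in cells}
        dhs_dir = d / "dhs"
        dhs = {
            c: dhs_dir / f"{c}.narrowPeak"
            for c in cells
            if (dhs_dir / f"{c}.narrowPeak").exists()
        }
        imputed = []
        if (d / "imputed_dxa.tsv").exists():
            imputed.append((d / "imputed_dxa.tsv", config.gwas_p_threshold))
        if (d / "imputed_ebmd.tsv").exists():
            imputed.append((d / "imputed_ebmd.tsv", config.ebmd_imputed_p_threshold))
        curated = d / "curated_genes.txt"
        return cls(
            association=d / "associations.tsv",
            vcf=d / "panel.vcf",
            fasta=d / "genome.fa",
            segmentation=seg,
            k27ac=k27,
            dhs=dhs,
            expression=d / "expression.tsv",
            gtf=d / "genes.gtf",
            transfac=d / "pwms.transfac",
            curated=curated if curated.exists() else None,
            imputed_tables=imputed,
        )


@dataclass
class Tier1Record:
    """One row of the final report (Table-1 style)."""

    gene_id: str
    rsid: str
    source_class: str  # "I/P", "Imp" or "I/P, Imp"
    distance_to_tss_kb: float
    ref_allele: str
    alt_allele: str
    focal_chromatin_label: str
    tf_ref: list[str]
    tf_alt: list[str]

    def __post_init__(self) -> None:
        if not self.tf_ref and not self.tf_alt:
            raise ValueError(
                f"{self.rsid}: a Tier-1 SNP needs >=1 allele-specific TFBS"
            )


@dataclass
class StageCounts:
    """Per-stage counts along the index/proxy filter chain."""

    n_index_input: int = 0
    n_index_proxy: int = 0
    n_state_k27ac: int = 0
    n_enhpro: int = 0
    n_candidate_genes: int = 0
    n_imputed: int = 0
    n_tier1: int = 0

    def to_dict(self) -> dict[str, int]:
        return dict(self.__dict__)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class PipelineResult:
    tier1: list[Tier1Record]
    counts: StageCounts
    # tracing state (which rsids reached / failed which stage)
    association_pvalues: dict[str, float] = field(default_factory=dict)
    panel_rsids: set[str] = field(default_factory=set)
    expanded_rsids: set[str] = field(default_factory=set)
    enhpro_by_rsid: dict[str, chromatin.EnhProRecord] = field(default_factory=dict)
    candidate_gene_ids: set[str] = field(default_factory=set)
    candidate_linked_rsids: set[str] = field(default_factory=set)
    tfbs_calls: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    tier1_rsids: set[str] = field(default_factory=set)

    def rejection_stage(self, rsid: str) -> str:
        """First stage at which a SNP dropped out ('tier1' if it never did)."""
        if rsid in self.tier1_rsids:
            return "tier1"
        record = self.enhpro_by_rsid.get(rsid)
        if record is not None:
            if not record.is_enhpro:
                return "enhpro"
            if rsid not in self.candidate_linked_rsids:
                return "gene"
            return "tfbs"
        if rsid in self.association_pvalues and rsid not in self.expanded_rsids:
            return "association"
        if rsid in self.panel_rsids:
            return "ld"
        return "absent"


def chromatin_label(
    variant: Variant,
    track,
    config: Config,
) -> str:
    """Display label for the focal chromatin at a SNP.

    'Str prom' for state 1, 'Str enh' for 3/8/9; 'Str enh/prom' when the
    SNP's immediate neighborhood touches strong segments of both kinds.
    """
    half = config.state_label_window_bp // 2
    lo = max(0, variant.pos - 1 - half)
    hi = variant.pos - 1 + half + 1
    states = set()
    entry = track._by_contig.get(variant.chrom)
    if entry is not None:
        starts, ends, st = entry
        for s, e, state in zip(starts, ends, st):
            if s < hi and e > lo:
                states.add(state)
    strong = states & config.strong_states
    has_prom = 1 in strong
    has_enh = bool(strong - {1})
    if has_prom and has_enh:
        return "Str enh/prom"
    point_state = track.state_at_pos(variant.chrom, variant.pos)
    if point_state == 1:
        return "Str prom"
    if point_state in config.strong_states:
        return "Str enh"
    return ""


def augment_with_imputed(
    candidates: list[genes_mod.CandidateGene],
    imputed_tables: list[tuple[Path, float]],
    gene_models: list[GeneModel],
    config: Config,
) -> list[Variant]:
    """Imputed SNPs near the candidate genes, each table at its own p cutoff.

    A SNP is kept when it lies within ``imputed_locus_buffer_bp`` of any
    candidate gene's span; its reported genes are set to those candidates.
    """
    by_id = {g.gene_id: g for g in gene_models}
    loci = [
        by_id[c.gene_id] for c in candidates if c.gene_id in by_id
    ]
    merged: dict[str, Variant] = {}
    for path, threshold in imputed_tables:
        for v in io.read_association_table(path, threshold):
            nearby = [
                g.gene_id
                for g in loci
                if g.chrom == v.chrom
                and g.span.start - config.imputed_locus_buffer_bp
                <= v.pos - 1
                < g.span.end + config.imputed_locus_buffer_bp
            ]
            if not nearby:
                continue
            if v.rsid not in merged:
                merged[v.rsid] = Variant(
                    rsid=v.rsid,
                    chrom=v.chrom,
                    pos=v.pos,
                    ref_allele=v.ref_allele,
                    alt_allele=v.alt_allele,
                    source="imputed",
                    pvalue=v.pvalue,
                    reported_genes=sorted(nearby),
                )
    return sorted(merged.values(), key=lambda v: (v.chrom, v.pos, v.rsid))


def run_pipeline(config: Config, bundle: InputBundle) -> PipelineResult:
    counts = StageCounts()
    result = PipelineResult(tier1=[], counts=counts)

    # --- association + LD expansion
    all_assoc = io.read_association_table(bundle.association, None)
    result.association_pvalues = {v.rsid: v.pvalue for v in all_assoc}
    index_snps = [v for v in all_assoc if v.pvalue < config.gwas_p_threshold]
    counts.n_index_input = len(index_snps)
    logger.info("stage association: %d index SNPs", counts.n_index_input)

    panel = io.read_vcf_panel(bundle.vcf)
    result.panel_rsids = {site.rsid for site in panel.loci}
    variants = ld.expand_proxies(
        index_snps,
        panel,
        r2_threshold=config.r2_threshold,
        search_window_bp=config.proxy_search_window_bp,
        tol=config.em_tol,
        max_iter=config.em_max_iter,
    )
    result.expanded_rsids = {v.rsid for v in variants}
    counts.n_index_proxy = len(variants)
    logger.info("stage ld: %d index+proxy SNPs", counts.n_index_proxy)

    # --- chromatin tracks
    focal = config.focal_cell_type
    others = list(config.chromatin_comparison_cell_types)
    segmentations = {
        c: io.read_segmentation_bed(p, c) for c, p in bundle.segmentation.items()
    }
    k27ac = {c: io.read_narrowpeak(p, c, "H3K27ac") for c, p in bundle.k27ac.items()}
    dhs = {c: io.read_narrowpeak(p, c, "DHS") for c, p in bundle.dhs.items()}

    enhpro_records = chromatin.classify_enhpro(
        variants, focal, others, segmentations, k27ac, dhs, config
    )
    result.enhpro_by_rsid = {r.variant.rsid: r for r in enhpro_records}
    counts.n_state_k27ac = sum(
        r.focal_strong
        and r.n_other_strong <= config.state_max_other
        and r.k27ac_focal
        and r.n_other_k27ac <= config.k27ac_max_other
        for r in enhpro_records
    )
    counts.n_enhpro = sum(r.is_enhpro for r in enhpro_records)
    logger.info(
        "stage enhpro: %d state+K27ac survivors, %d EnhPro SNPs",
        counts.n_state_k27ac,
        counts.n_enhpro,
    )

    # --- gene prioritization
    gene_models = io.read_gene_models_gtf(bundle.gtf)
    expression = io.read_expression_table(bundle.expression)
    curated = io.read_gene_list(bundle.curated) if bundle.curated else []
    expr_summaries = genes_mod.preferential_expression(
        expression, focal, list(config.expression_comparison_cell_types), config
    )
    enhpro_links = []
    for record in enhpro_records:
        if record.is_enhpro:
            enhpro_links.extend(
                genes_mod.link_snp_to_gene(record.variant, gene_models)
            )
    candidates = genes_mod.select_candidates(
        enhpro_links, expr_summaries, curated, config.excluded_genes
    )
    result.candidate_gene_ids = {c.gene_id for c in candidates}
    counts.n_candidate_genes = len(candidates)
    logger.info("stage gene: %d candidate genes", counts.n_candidate_genes)

    # --- imputed augmentation: new SNPs re-enter the chromatin stage
    imputed = augment_with_imputed(
        candidates, bundle.imputed_tables, gene_models, config
    )
    imputed_rsids = {v.rsid for v in imputed}
    counts.n_imputed = len(imputed)
    new_imputed = [v for v in imputed if v.rsid not in result.expanded_rsids]
    if new_imputed:
        for record in chromatin.classify_enhpro(
            new_imputed, focal, others, segmentations, k27ac, dhs, config
        ):
            result.enhpro_by_rsid[record.variant.rsid] = record

    # --- TFBS scoring of candidate-linked EnhPro SNPs
    assembly = io.read_fasta_assembly(bundle.fasta)
    pwms = tfbs.read_transfac_pwm(bundle.transfac, config)
    all_links: dict[str, list[genes_mod.SnpGeneLink]] = {}
    for record in list(result.enhpro_by_rsid.values()):
        if not record.is_enhpro:
            continue
        links = [
            link
            for link in genes_mod.link_snp_to_gene(record.variant, gene_models)
            if link.gene_id in result.candidate_gene_ids
        ]
        if links:
            all_links[record.variant.rsid] = links
            result.candidate_linked_rsids.add(record.variant.rsid)

    records: list[Tier1Record] = []
    for rsid in all_links:
        record = result.enhpro_by_rsid[rsid]
        v = record.variant
        calls = tfbs.predict_allele_specific_tfbs(
            v, assembly, pwms, expression, config
        )
        result.tfbs_calls[rsid] = calls
        if not calls:
            continue
        tf_ref = sorted(tf for tf, allele in calls if allele == "ref")
        tf_alt = sorted(tf for tf, allele in calls if allele == "alt")
        in_ip = v.source in ("index", "proxy")
        in_imp = v.rsid in imputed_rsids or v.source == "imputed"
        if in_ip and in_imp:
            source_class = "I/P, Imp"
        elif in_ip:
            source_class = "I/P"
        else:
            source_class = "Imp"
        label = chromatin_label(v, segmentations[focal], config)
        for link in all_links[rsid]:
            records.append(
                Tier1Record(
                    gene_id=link.gene_id,
                    rsid=rsid,
                    source_class=source_class,
                    distance_to_tss_kb=link.distance_to_tss_kb,
                    ref_allele=v.ref_allele,
                    alt_allele=v.alt_allele,
                    focal_chromatin_label=label,
                    tf_ref=tf_ref,
                    tf_alt=tf_alt,
                )
            )

    # group by gene in order of first appearance, distances ascending within
    gene_order: dict[str, int] = {}
    for r in records:
        gene_order.setdefault(r.gene_id, len(gene_order))
    records.sort(
        key=lambda r: (gene_order[r.gene_id], r.distance_to_tss_kb, r.rsid)
    )
    result.tier1 = records
    result.tier1_rsids = {r.rsid for r in records}
    counts.n_tier1 = len(result.tier1_rsids)
    logger.info("stage tier1: %d Tier-1 SNPs", counts.n_tier1)
    return result


REPORT_COLUMNS = [
    "gene",
    "tier1_snp",
    "source",
    "distance_to_tss_kb",
    "alleles_ref_alt",
    "chromatin_state",
    "tf_ref",
    "tf_alt",
]


def make_table1_report(records: list[Tier1Record], path) -> None:
    """Write the Table-1-style TSV report (distances to 0.1 kb)."""
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.rsid}\t{r.source_class}\t"
                f"{r.distance_to_tss_kb:.1f}\t"
                f"{r.ref_allele}/{r.alt_allele}\t{r.focal_chromatin_label}\t"
                f"{', '.join(r.tf_ref) if r.tf_ref else 'None'}\t"
                f"{', '.join(r.tf_alt) if r.tf_alt else 'None'}\n"
            )


def read_table1_report(path) -> list[Tier1Record]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != REPORT_COLUMNS:
            raise ValueError(f"{path}: unexpected report header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            ref, alt = f[4].split("/")
            records.append(
                Tier1Record(
                    gene_id=f[0],
                    rsid=f[1],
                    source_class=f[2],
                    distance_to_tss_kb=float(f[3]),
                    ref_allele=ref,
                    alt_allele=alt,
                    focal_chromatin_label=f[5],
                    tf_ref=[] if f[6] == "None" else f[6].split(", "),
                    tf_alt=[] if f[7] == "None" else f[7].split(", "),
                )
            )
    return records
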