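"""Gene linking and prioritization by focal-cell-preferential expression.

A gene is preferentially expressed when its focal-cell RPKM is more than
``expr_ratio_min`` times the median RPKM over the 11 heterologous comparison
cell types and exceeds ``expr_focal_min_rpkm`` in the focal cell type.
Candidate genes must be linked to at least one EnhPro SNP and either pass
the preferential-expression rule or appear on a curated bone-relevance list
(which stands in for GO-term screening).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .config import Config
from .model import ExpressionTable, GeneModel, Variant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneExpressionSummary:
    gene_id: str
    focal_rpkm: float
    median_other_rpkm: float
    ratio: float  # may be inf when the comparison median is 0
    preferential: bool


@dataclass(frozen=True)
class SnpGeneLink:
    """A SNP-gene link with a strand-aware signed TSS distance.

    Negative distances always mean upstream of the TSS relative to the
    gene's strand.
    """

    rsid: str
    gene_id: str
    distance_to_tss_kb: float
    link_source: str  # "reported" or "nearest"


@dataclass(frozen=True)
class CandidateGene:
    gene_id: str
    selected_by: frozenset[str]  # subset of {preferential_expression, curated_list}

    def __post_init__(self) -> None:
        if not self.selected_by:
            raise ValueError(f"{self.gene_id}: selected_by must be non-empty")


def preferential_expression(
    table: ExpressionTable,
    focal: str,
    others: list[str],
    config: Config,
) -> list[GeneExpressionSummary]:
    """One expression summary per gene; genes with missing values are skipped."""
    for cell in [focal, *others]:
        if cell not in table.cell_types:
            raise ValueError(f"cell type {cell!r} absent from expression table")
    sub = table.frame[[focal, *others]]
    n_skipped = 0
    summaries = []
    for gene, row in sub.iterrows():
        values = row.to_numpy(dtype=float)
        if np.isnan(values).any():
            n_skipped += 1
            continue
        focal_rpkm = float(values[0])
        median_other = float(np.median(values[1:]))
        if median_other > 0:
            ratio = focal_rpkm / median_other
        elif focal_rpkm > 0:
            ratio = math.inf
        else:
            ratio = 0.0
        preferential = (
            ratio > config.expr_ratio_min and focal_rpkm > config.expr_focal_min_rpkm
        )
        summaries.append(
            GeneExpressionSummary(
                gene_id=str(gene),
                focal_rpkm=focal_rpkm,
                median_other_rpkm=median_other,
                ratio=ratio,
                preferential=preferential,
            )
        )
    if n_skipped:
        logger.info("excluded %d gene(s) with missing expression values", n_skipped)
    return summaries


def tss_distance_kb(variant_pos: int, gene: GeneModel) -> float:
    """Signed distance from SNP to TSS in kb; negative = upstream."""
    if gene.strand == "+":
        return (variant_pos - gene.tss) / 1000.0
    return (gene.tss - variant_pos) / 1000.0


def link_snp_to_gene(
    variant: Variant,
    genes: list[GeneModel],
    association_genes: list[str] | None = None,
) -> list[SnpGeneLink]:
    """Link a SNP to its reported genes, or to the nearest TSS as fallback."""
    if association_genes is None:
        association_genes = variant.reported_genes
    by_id = {g.gene_id: g for g in genes}
    links = []
    for gene_id in association_genes:
        gene = by_id.get(gene_id)
        if gene is None:
            continue
        links.append(
            SnpGeneLink(
                rsid=variant.rsid,
                gene_id=gene_id,
                distance_to_tss_kb=tss_distance_kb(variant.pos, gene),
                link_source="reported",
            )
        )
    if links:
        return links
    on_contig = [g for g in genes if g.chrom == variant.chrom]
    if not on_contig:
        logger.info("%s: no gene on contig %s; unlinked", variant.rsid, variant.chrom)
        return []
    nearest = min(on_contig, key=lambda g: (abs(variant.pos - g.tss), g.gene_id))
    return [
        SnpGeneLink(
            rsid=variant.rsid,
            gene_id=nearest.gene_id,
            distance_to_tss_kb=tss_distance_kb(variant.pos, nearest),
            link_source="nearest",
        )
    ]


def select_candidates(
    enhpro_links: list[SnpGeneLink],
    expr: list[GeneExpressionSummary],
    curated: list[str],
    excluded: list[str] | tuple[str, ...] = (),
) -> list[CandidateGene]:
    """Genes linked to >=1 EnhPro SNP and passing either evaluation path.

    ``excluded`` genes (e.g. ones already analyzed elsewhere) are subtracted
    last.  Output order is deterministic and independent of input order.
    """
    linked = {link.gene_id for link in enhpro_links}
    preferential = {s.gene_id for s in expr if s.preferential}
    curated_set = set(curated)
    candidates = []
    for gene_id in sorted(linked):
        selected_by = set()
        if gene_id in preferential:
            selected_by.add("preferential_expression")
        if gene_id in curated_set:
            selected_by.add("curated_list")
        if selected_by and gene_id not in set(excluded):
            candidates.append(CandidateGene(gene_id, frozenset(selected_by)))
    return candidates


def write_candidate_table(
    candidates: list[CandidateGene],
    expr: list[GeneExpressionSummary],
    path,
) -> None:
    by_gene = {s.gene_id: s for s in expr}
    with open(path, "w") as fh:
        fh.write("gene_id\tselected_by\tfocal_rpkm\tmedian_other_rpkm\tratio\n")
        for c in candidates:
            s = by_gene.get(c.gene_id)
            fh.write(
                f"{c.gene_id}\t{','.join(sorted(c.selected_by))}\t"
                f"{'' if s is None else f'{s.focal_rpkm:.4g}'}\t"
                f"{'' if s is None else f'{s.median_other_rpkm:.4g}'}\t"
                f"{'' if s is None else f'{s.ratio:.4g}'}\n"
            )
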