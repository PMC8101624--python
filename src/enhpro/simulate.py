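"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The genotype panel follows a block-mosaic coalescent caricature: within each
LD block every haplotype copies one of four founder haplotypes (with a small
per-site founder-switch probability), and founder pools are redrawn at block
boundaries, so r-squared is high within blocks and near zero between them.
Chromatin segmentations are mostly quiescent with strong enhancer segments
planted around signal SNPs; H3K27ac and DHS peaks nest inside those
segments; expression is long-tailed log-normal with planted focal-cell
enriched genes; PWMs have conserved cores with an engineered allele-contrast
column at each signal SNP.

Every planted signal carries a defect label; defect-free signals must
survive the whole pipeline and each decoy must be rejected at the stage its
defect targets.  Truth labels are written as a sidecar TSV that the pipeline
never reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, tfbs
from .config import Config, dump_config
from .ld import GenotypePanel, SiteRecord
from .model import (
    ExpressionTable,
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    PeakTrack,
    SegmentationTrack,
)
from .pipeline import InputBundle

DEFECTS = (
    "none", "no_dhs", "too_shared_state", "too_shared_k27ac",
    "gene_not_preferential", "fold_below_5", "tf_not_expressed",
    "curation_fail", "p_above_threshold", "r2_below_threshold",
)

EXPECTED_STAGE = {
    "none": "tier1",
    "no_dhs": "enhpro",
    "too_shared_state": "enhpro",
    "too_shared_k27ac": "enhpro",
    "gene_not_preferential": "gene",
    "fold_below_5": "tfbs",
    "tf_not_expressed": "tfbs",
    "curation_fail": "tfbs",
    "p_above_threshold": "association",
    "r2_below_threshold": "ld",
}

FOCAL = "ostb"
COMPARISON_CELLS = [f"cell{i:02d}" for i in range(1, 13)]
EXPRESSION_CELLS = COMPARISON_CELLS[:11]


@dataclass(frozen=True)
class PlantedSignal:
    rsid: str
    defect: str
    expected_rejection_stage: str

    def __post_init__(self) -> None:
        if self.defect not in DEFECTS:
            raise ValueError(f"unknown defect {self.defect!r}")
        if self.defect == "none" and self.expected_rejection_stage != "tier1":
            raise ValueError("defect-free signals must reach tier1")


def default_planted(n_clean: int = 10) -> list[PlantedSignal]:
    """n_clean defect-free signals plus one decoy per defect class."""
    planted = [
        PlantedSignal(f"rs{1000000 + i}", "none", "tier1") for i in range(n_clean)
    ]
    for j, defect in enumerate(d for d in DEFECTS if d != "none"):
        planted.append(
            PlantedSignal(f"rs{2000000 + j}", defect, EXPECTED_STAGE[defect])
        )
    return planted


@dataclass
class SimulationSpec:
    rng_seed: int = 1
    n_contigs: int = 2
    contig_length_bp: int = 600_000
    n_samples: int = 60
    n_index_snps: int = 20
    site_spacing_bp: int = 500
    ld_block_length_bp: int = 50_000
    within_block_recomb_prob: float = 0.01
    n_founders: int = 4
    n_cell_types: int = 13
    n_genes: int = 60
    n_pwms: int = 24
    planted: list[PlantedSignal] = field(default_factory=default_planted)

    def __post_init__(self) -> None:
        for name in ("n_contigs", "contig_length_bp", "n_samples",
                     "site_spacing_bp", "ld_block_length_bp", "n_founders",
                     "n_cell_types", "n_genes", "n_pwms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cell_types != 1 + len(COMPARISON_CELLS):
            raise ValueError("n_cell_types must be 13 (focal + 12 comparison)")


@dataclass
class SimBundle:
    run_dir: Path
    bundle: InputBundle
    config: Config
    truth: pd.DataFrame  # rsid, defect, expected_rejection_stage


def _sim_config(seed: int) -> Config:
    return Config(
        focal_cell_type=FOCAL,
        chromatin_comparison_cell_types=tuple(COMPARISON_CELLS),
        expression_comparison_cell_types=tuple(EXPRESSION_CELLS),
        rng_seed=seed,
    )


def _mosaic_haplotypes(
    spec: SimulationSpec, rng: np.random.Generator, n_sites: int, sites_per_block: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(founder alleles, haplotype alleles, per-site founder index) for one contig."""
    n_hap = 2 * spec.n_samples
    n_blocks = int(np.ceil(n_sites / sites_per_block))
    founder = rng.integers(0, 2, size=(n_blocks, spec.n_founders, sites_per_block))
    haps = np.empty((n_hap, n_sites), dtype=np.int8)
    fidx = np.empty((n_hap, n_sites), dtype=np.int8)
    for h in range(n_hap):
        for b in range(n_blocks):
            lo = b * sites_per_block
            hi = min(n_sites, lo + sites_per_block)
            f = rng.integers(0, spec.n_founders)  # new pool: independent draw
            switches = rng.random(hi - lo) < spec.within_block_recomb_prob
            for k in range(hi - lo):
                if switches[k]:
                    f = rng.integers(0, spec.n_founders)
                fidx[h, lo + k] = f
                haps[h, lo + k] = founder[b, f, k]
    return founder, haps, fidx


def simulate(spec: SimulationSpec, out_dir) -> SimBundle:
    """Write the full synthetic input bundle into ``out_dir``."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)
    config = _sim_config(spec.rng_seed)

    sites_per_contig = spec.contig_length_bp // spec.site_spacing_bp
    sites_per_block = spec.ld_block_length_bp // spec.site_spacing_bp
    blocks_per_contig = sites_per_contig // sites_per_block
    contigs = [f"chr{c + 1}" for c in range(spec.n_contigs)]

    # --- assign each planted signal its own LD block
    placements: dict[str, tuple[int, int]] = {}  # rsid -> (contig idx, block idx)
    used_blocks: set[tuple[int, int]] = set()
    k = 0
    for signal in spec.planted:
        while True:
            slot = (k % spec.n_contigs, k // spec.n_contigs)
            k += 1
            if slot[1] >= blocks_per_contig:
                raise ValueError("planted signals exceed available LD blocks")
            if slot not in used_blocks:
                break
        placements[signal.rsid] = slot
        used_blocks.add(slot)
    n_background_index = max(
        0,
        spec.n_index_snps
        - sum(
            1
            for s in spec.planted
            if s.defect not in ("p_above_threshold", "r2_below_threshold")
        ),
    )
    background_slots = []
    while len(background_slots) < n_background_index:
        slot = (k % spec.n_contigs, k // spec.n_contigs)
        k += 1
        if slot[1] >= blocks_per_contig:
            raise ValueError("background index SNPs exceed available LD blocks")
        if slot not in used_blocks:
            background_slots.append(slot)
            used_blocks.add(slot)

    def block_mid_site(block: int) -> int:
        return block * sites_per_block + sites_per_block // 2

    def site_pos(site: int) -> int:  # 1-based
        return site * spec.site_spacing_bp + 250

    # --- haplotypes per contig, with planted sites forced polymorphic
    founder_by_contig, haps_by_contig, fidx_by_contig = [], [], []
    for c in range(spec.n_contigs):
        founder, haps, fidx = _mosaic_haplotypes(
            spec, rng, sites_per_contig, sites_per_block
        )
        founder_by_contig.append(founder)
        haps_by_contig.append(haps)
        fidx_by_contig.append(fidx)
    for rsid, (c, b) in list(placements.items()) + [
        (f"bg{i}", slot) for i, slot in enumerate(background_slots)
    ]:
        site = block_mid_site(b)
        within = site - b * sites_per_block
        pattern = np.zeros(spec.n_founders, dtype=np.int8)
        pattern[: spec.n_founders // 2] = 1  # balanced founder pattern
        founder_by_contig[c][b, :, within] = pattern
        # re-derive alleles from each haplotype's founder index at that site,
        # preserving within-block LD with neighboring sites
        haps_by_contig[c][:, site] = pattern[fidx_by_contig[c][:, site]]

    # --- genome sequence; site ref alleles taken from the sequence
    base_arr = {
        chrom: rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=spec.contig_length_bp)
        for chrom in contigs
    }
    loci: list[SiteRecord] = []
    hap_cols: list[np.ndarray] = []
    planted_site_rsids = {
        (c, block_mid_site(b)): rsid for rsid, (c, b) in placements.items()
    }
    bases = "ACGT"
    for c, chrom in enumerate(contigs):
        for site in range(sites_per_contig):
            pos = site_pos(site)
            ref = base_arr[chrom][pos - 1].decode()
            alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
            rsid = planted_site_rsids.get((c, site), f"rs9{c:02d}{site:05d}")
            loci.append(SiteRecord(rsid, chrom, pos, ref, alt))
            hap_cols.append(haps_by_contig[c][:, site])
    haplotypes = np.stack(hap_cols, axis=1).astype(np.int8)
    dosage = (haplotypes[0::2, :] + haplotypes[1::2, :]).astype(np.int8)
    panel = GenotypePanel(
        samples=[f"S{i:03d}" for i in range(spec.n_samples)],
        loci=loci,
        dosage=dosage,
        phased=True,
        haplotypes=haplotypes,
    )
    contig_lengths = {chrom: spec.contig_length_bp for chrom in contigs}
    io.write_vcf_panel(panel, d / "panel.vcf", contig_lengths)
    assembly = GenomeAssembly(
        {chrom: base_arr[chrom].tobytes().decode() for chrom in contigs}
    )
    io.write_fasta(assembly, d / "genome.fa")

    site_record = {s.rsid: s for s in loci}

    # --- association table
    with open(d / "associations.tsv", "w") as fh:
        fh.write("rsid\tchrom\tpos\tref\talt\tpvalue\treported_genes\n")
        for signal in spec.planted:
            if signal.defect == "r2_below_threshold":
                continue  # panel-only site: must never enter through LD
            s = site_record[signal.rsid]
            p = 1e-6 if signal.defect == "p_above_threshold" else 1e-9
            fh.write(
                f"{s.rsid}\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{p}\t"
                f"GENE_{s.rsid}\n"
            )
        for i, (c, b) in enumerate(background_slots):
            s = loci[c * sites_per_contig + block_mid_site(b)]
            fh.write(f"{s.rsid}\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t1e-9\t\n")

    # --- chromatin: quiescent background with planted strong segments
    seg_by_cell: dict[str, list] = {cell: [] for cell in [FOCAL, *COMPARISON_CELLS]}
    k27_by_cell: dict[str, list] = {cell: [] for cell in [FOCAL, *COMPARISON_CELLS]}
    dhs_by_cell: dict[str, list] = {cell: [] for cell in [FOCAL, *COMPARISON_CELLS]}
    for signal in spec.planted:
        s = site_record[signal.rsid]
        p0 = s.pos - 1
        n_state_share = 4 if signal.defect == "too_shared_state" else 2
        n_k27_share = 4 if signal.defect == "too_shared_k27ac" else 2
        seg_by_cell[FOCAL].append(GenomicInterval(s.chrom, p0 - 150, p0 + 150, "9"))
        for cell in COMPARISON_CELLS[:n_state_share]:
            seg_by_cell[cell].append(GenomicInterval(s.chrom, p0 - 150, p0 + 150, "9"))
        k27_iv = GenomicInterval(s.chrom, p0 - 120, p0 + 120, "peak")
        k27_by_cell[FOCAL].append(k27_iv)
        for cell in COMPARISON_CELLS[:n_k27_share]:
            k27_by_cell[cell].append(k27_iv)
        if signal.defect != "no_dhs":
            dhs_by_cell[FOCAL].append(GenomicInterval(s.chrom, p0 - 80, p0 + 80, "dhs"))
    for cell in [FOCAL, *COMPARISON_CELLS]:
        for chrom in contigs:
            seg_by_cell[cell].append(GenomicInterval(chrom, 0, 5_000, "15"))

    for sub in ("segmentation", "k27ac", "dhs"):
        (d / sub).mkdir(exist_ok=True)
    for cell in [FOCAL, *COMPARISON_CELLS]:
        io.write_segmentation_bed(
            SegmentationTrack(cell, seg_by_cell[cell]),
            d / "segmentation" / f"{cell}.bed",
        )
        io.write_narrowpeak(
            PeakTrack(cell, "H3K27ac", k27_by_cell[cell]),
            d / "k27ac" / f"{cell}.narrowPeak",
        )
        io.write_narrowpeak(
            PeakTrack(cell, "DHS", dhs_by_cell[cell]),
            d / "dhs" / f"{cell}.narrowPeak",
        )

    # --- gene models and expression
    gene_models = []
    for signal in spec.planted:
        s = site_record[signal.rsid]
        tss = s.pos + 5_000
        gene_models.append(
            GeneModel(
                f"GENE_{s.rsid}", s.chrom, tss, "+",
                GenomicInterval(s.chrom, tss - 1, tss - 1 + 10_000),
            )
        )
    n_filler_genes = max(0, spec.n_genes - len(gene_models))
    for j in range(n_filler_genes):
        chrom = contigs[j % spec.n_contigs]
        tss = 6_000 + (j // spec.n_contigs) * 13_000
        gene_models.append(
            GeneModel(
                f"FGENE{j:03d}", chrom, tss, "+",
                GenomicInterval(chrom, tss - 1, tss - 1 + 2_000),
            )
        )
    io.write_gene_models_gtf(gene_models, d / "genes.gtf")

    cells = [FOCAL, *EXPRESSION_CELLS]
    frame_rows: dict[str, list[float]] = {}
    for signal in spec.planted:
        if signal.defect == "gene_not_preferential":
            frame_rows[f"GENE_{signal.rsid}"] = [10.0] + [5.0] * len(EXPRESSION_CELLS)
        else:
            frame_rows[f"GENE_{signal.rsid}"] = [10.0] + [0.5] * len(EXPRESSION_CELLS)
        rpkm_tf = 0.1 if signal.defect == "tf_not_expressed" else 5.0
        frame_rows[f"TF_{signal.rsid}"] = [rpkm_tf] + [1.0] * len(EXPRESSION_CELLS)
    for j in range(n_filler_genes):
        frame_rows[f"FGENE{j:03d}"] = list(
            np.round(rng.lognormal(mean=0.0, sigma=1.2, size=len(cells)), 3)
        )
    frame_rows["FILLER_TF"] = [5.0] + [1.0] * len(EXPRESSION_CELLS)
    frame = pd.DataFrame.from_dict(frame_rows, orient="index", columns=cells)
    io.write_expression_table(ExpressionTable(frame), d / "expression.tsv")
    io.write_gene_list([], d / "curated_genes.txt")

    # --- PWMs
    pwm_defs = []
    alternate = 0
    for signal in spec.planted:
        if signal.defect in (
            "no_dhs", "too_shared_state", "too_shared_k27ac",
            "gene_not_preferential", "p_above_threshold", "r2_below_threshold",
        ):
            continue
        s = site_record[signal.rsid]
        window11 = assembly.fetch(s.chrom, s.pos - 1 - 5, s.pos + 5)
        alternate += 1
        favored, disfavored = (
            (s.ref, s.alt) if alternate % 2 else (s.alt, s.ref)
        )
        rows = []
        for i, base in enumerate(window11):
            if i == 5:
                counts = {b: 0.0 for b in "ACGT"}
                if signal.defect == "fold_below_5":
                    counts[favored] = 42.0
                    counts[disfavored] = 10.0  # fold 4.2, both pass curation
                    rest = [b for b in "ACGT" if b not in (favored, disfavored)]
                    counts[rest[0]] = 40.0
                    counts[rest[1]] = 8.0
                else:
                    counts[favored] = 52.0
                    counts[disfavored] = 5.0
                    rest = [b for b in "ACGT" if b not in (favored, disfavored)]
                    counts[rest[0]] = 38.0
                    counts[rest[1]] = 5.0
                rows.append([counts[b] for b in "ACGT"])
            elif i == 2 and signal.defect == "curation_fail":
                wrong = bases[(bases.index(base) + 1) % 4]
                rows.append([97.0 if b == wrong else 1.0 for b in "ACGT"])
            else:
                rows.append([97.0 if b == base else 1.0 for b in "ACGT"])
        pwm_defs.append((f"M_{signal.rsid}", f"TF_{signal.rsid}", np.array(rows)))
    n_filler_pwms = max(0, spec.n_pwms - len(pwm_defs))
    for j in range(n_filler_pwms):
        consensus = rng.choice(list("ACGT"), size=14)
        rows = [[97.0 if b == cb else 1.0 for b in "ACGT"] for cb in consensus]
        pwm_defs.append((f"M_F{j:03d}", "FILLER_TF", np.array(rows)))
    tfbs.write_transfac(pwm_defs, d / "pwms.transfac")

    # --- truth labels (sidecar)
    truth = pd.DataFrame(
        [
            {
                "rsid": s.rsid,
                "defect": s.defect,
                "expected_rejection_stage": s.expected_rejection_stage,
            }
            for s in spec.planted
        ]
    )
    truth.to_csv(d / "truth_labels.tsv", sep="\t", index=False)
    dump_config(config, d / "config.toml")
    return SimBundle(
        run_dir=d,
        bundle=InputBundle.from_dir(d, config),
        config=config,
        truth=truth,
    )
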