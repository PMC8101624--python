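"""EnhPro calling: focal-cell-preferential regulatory chromatin at SNPs.

An EnhPro SNP sits in strong enhancer (states 3/8/9) or strong promoter
(state 1) chromatin in the focal cell type but in no more than
``state_max_other`` of the 12 comparison cell types, overlaps a focal
H3K27ac narrow peak shared by no more than ``k27ac_max_other`` comparison
cell types, and overlaps a focal DNaseI-hypersensitivity peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .config import Config
from .model import PeakTrack, SegmentationTrack, Variant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StateCall:
    """Chromatin state of one cell type at one SNP (None = unsegmented)."""

    rsid: str
    cell_type: str
    state: int | None


@dataclass
class EnhProRecord:
    """A variant with the full evidence behind its EnhPro decision."""

    variant: Variant
    focal_state: int | None
    focal_strong: bool
    n_other_strong: int
    k27ac_focal: bool
    n_other_k27ac: int
    dhs_focal: bool
    is_enhpro: bool

    def recompute(self, config: Config) -> bool:
        """EnhPro flag re-derived from the stored evidence fields."""
        return (
            self.focal_strong
            and self.n_other_strong <= config.state_max_other
            and self.k27ac_focal
            and self.n_other_k27ac <= config.k27ac_max_other
            and self.dhs_focal
        )


def state_at(variant: Variant, track: SegmentationTrack) -> StateCall:
    """Point query: the segment satisfying start <= pos-1 < end, else absent."""
    return StateCall(
        rsid=variant.rsid,
        cell_type=track.cell_type,
        state=track.state_at_pos(variant.chrom, variant.pos),
    )


def is_strong_regulatory(state: int | None, config: Config) -> bool:
    """True iff the state is strong promoter/enhancer chromatin."""
    return state is not None and state in config.strong_states


def classify_enhpro(
    variants: list[Variant],
    focal: str,
    others: list[str],
    segmentations: dict[str, SegmentationTrack],
    k27ac: dict[str, PeakTrack],
    dhs: dict[str, PeakTrack],
    config: Config,
) -> list[EnhProRecord]:
    """Score every variant against the EnhPro criteria.

    All variants come back with their full evidence, EnhPro or not.  DHS is
    required in the focal cell type only; there is no DHS sharing counter.
    """
    if len(others) != 12:
        logger.warning(
            "comparison panel has %d cell types (expected 12); sharing "
            "ceilings are interpreted as absolute counts",
            len(others),
        )
    missing = [c for c in [focal, *others] if c not in segmentations]
    if missing:
        raise ValueError(f"missing segmentation track(s) for {missing}")
    missing_peaks = [c for c in [focal, *others] if c not in k27ac]
    if missing_peaks:
        raise ValueError(f"missing H3K27ac peak track(s) for {missing_peaks}")
    if focal not in dhs:
        raise ValueError(f"missing DHS peak track for focal cell type {focal!r}")

    records = []
    for v in variants:
        focal_state = segmentations[focal].state_at_pos(v.chrom, v.pos)
        focal_strong = is_strong_regulatory(focal_state, config)
        n_other_strong = sum(
            is_strong_regulatory(
                segmentations[c].state_at_pos(v.chrom, v.pos), config
            )
            for c in others
        )
        k27ac_focal = k27ac[focal].overlaps_pos(v.chrom, v.pos)
        n_other_k27ac = sum(
            k27ac[c].overlaps_pos(v.chrom, v.pos) for c in others
        )
        dhs_focal = dhs[focal].overlaps_pos(v.chrom, v.pos)
        record = EnhProRecord(
            variant=v,
            focal_state=focal_state,
            focal_strong=focal_strong,
            n_other_strong=n_other_strong,
            k27ac_focal=k27ac_focal,
            n_other_k27ac=n_other_k27ac,
            dhs_focal=dhs_focal,
            is_enhpro=False,
        )
        record.is_enhpro = record.recompute(config)
        records.append(record)
    return records


def write_enhpro_table(records: list[EnhProRecord], path) -> None:
    """Emit the EnhPro evidence TSV."""
    with open(path, "w") as fh:
        fh.write(
            "rsid\tchrom\tpos\tfocal_state\tn_other_strong\tk27ac_focal\t"
            "n_other_k27ac\tdhs_focal\tis_enhpro\n"
        )
        for r in records:
            v = r.variant
            fh.write(
                f"{v.rsid}\t{v.chrom}\t{v.pos}\t"
                f"{'' if r.focal_state is None else r.focal_state}\t"
                f"{r.n_other_strong}\t{int(r.k27ac_focal)}\t{r.n_other_k27ac}\t"
                f"{int(r.dhs_focal)}\t{int(r.is_enhpro)}\n"
            )
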