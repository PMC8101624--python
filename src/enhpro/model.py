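"""Domain types shared by every pipeline stage.

Coordinate conventions follow the file formats they come from: BED-derived
interval types are 0-based half-open, variant positions are 1-based (VCF
convention).  A variant at 1-based position ``p`` overlaps the interval
``[start, end)`` iff ``start <= p - 1 < end``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

VALID_BASES = frozenset("ACGT")

#: Mnemonic suffixes used when emitting segmentation BED files.  State 1 is
#: strong (active-TSS) promoter chromatin; states 3, 8 and 9 are strong
#: enhancer chromatin; state 15 is the quiescent background state.
STATE_MNEMONICS = {
    1: "TssA", 2: "TssFlnk", 3: "EnhA1", 4: "TxFlnk", 5: "Tx", 6: "TxWk",
    7: "EnhG", 8: "EnhA2", 9: "EnhA3", 10: "EnhWk1", 11: "EnhWk2",
    12: "ZNF_Rpts", 13: "Het", 14: "TssBiv", 15: "Quies", 16: "ReprPC",
    17: "ReprPCWk", 18: "QuiesLow",
}


@dataclass
class Variant:
    """A single-nucleotide variant with its GWAS provenance.

    ``source`` is one of ``index`` (genome-wide significant association),
    ``proxy`` (linked to an index SNP through LD) or ``imputed`` (from an
    imputed summary-statistics table).  Proxies carry the identifier of the
    index SNP they tag and the r-squared of that link.
    """

    rsid: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    source: str = "index"
    pvalue: float | None = None
    index_rsid: str | None = None
    r2_to_index: float | None = None
    reported_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValueError(
                f"{self.rsid}: alleles must be single A/C/G/T bases, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.rsid}: ref and alt alleles are identical")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1, got {self.pos}")
        if self.source not in ("index", "proxy", "imputed"):
            raise ValueError(f"{self.rsid}: unknown source {self.source!r}")
        if (self.source == "proxy") != (self.r2_to_index is not None):
            raise ValueError(
                f"{self.rsid}: r2_to_index must be present iff source is 'proxy'"
            )


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval with a free-text label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def contains_pos(self, pos: int) -> bool:
        """Overlap test against a 1-based point position."""
        return self.start <= pos - 1 < self.end


class SegmentationTrack:
    """Chromatin-state segmentation for one cell type (18-state model).

    Intervals must not overlap within a contig: a segmentation assigns at
    most one state to any base.  Point queries run on sorted per-contig
    arrays via binary search.
    """

    def __init__(self, cell_type: str, intervals: list[GenomicInterval]):
        self.cell_type = cell_type
        self.intervals = list(intervals)
        self._by_contig: dict[str, tuple[list[int], list[int], list[int]]] = {}
        per_contig: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            state = int(iv.label)
            if not 1 <= state <= 18:
                raise ValueError(f"state code out of range 1..18: {iv.label!r}")
            per_contig.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in per_contig.items():
            ivs.sort(key=lambda iv: iv.start)
            for prev, cur in zip(ivs, ivs[1:]):
                if cur.start < prev.end:
                    raise ValueError(
                        f"{cell_type}: overlapping segments on {chrom}: "
                        f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
                    )
            self._by_contig[chrom] = (
                [iv.start for iv in ivs],
                [iv.end for iv in ivs],
                [int(iv.label) for iv in ivs],
            )

    def state_at_pos(self, chrom: str, pos: int) -> int | None:
        """State at a 1-based position, or None outside all segments."""
        entry = self._by_contig.get(chrom)
        if entry is None:
            return None
        starts, ends, states = entry
        i = bisect.bisect_right(starts, pos - 1) - 1
        if i >= 0 and pos - 1 < ends[i]:
            return states[i]
        return None


class PeakTrack:
    """narrowPeak intervals (H3K27ac or DHS) for one cell type.

    Peaks may overlap each other; point queries use sorted starts with a
    running maximum of ends, which is exact for the point-overlap case.
    """

    def __init__(
        self,
        cell_type: str,
        mark: str,
        intervals: list[GenomicInterval],
        summit_offsets: list[int | None] | None = None,
    ):
        if mark not in ("H3K27ac", "DHS"):
            raise ValueError(f"unknown peak mark {mark!r}")
        self.cell_type = cell_type
        self.mark = mark
        self.intervals = list(intervals)
        if summit_offsets is None:
            summit_offsets = [None] * len(self.intervals)
        if len(summit_offsets) != len(self.intervals):
            raise ValueError("summit_offsets length mismatch")
        for iv, s in zip(self.intervals, summit_offsets):
            if s is not None and not 0 <= s < iv.end - iv.start:
                raise ValueError(
                    f"summit offset {s} outside peak {iv.chrom}:{iv.start}-{iv.end}"
                )
        self.summit_offsets = list(summit_offsets)
        self._by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        per_contig: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            per_contig.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in per_contig.items():
            pairs.sort()
            starts = np.array([p[0] for p in pairs], dtype=np.int64)
            # running max of ends makes "any earlier peak still open?" O(log n)
            ends = np.maximum.accumulate(
                np.array([p[1] for p in pairs], dtype=np.int64)
            )
            self._by_contig[chrom] = (starts, ends)

    def overlaps_pos(self, chrom: str, pos: int) -> bool:
        """True iff any peak covers the 1-based position."""
        entry = self._by_contig.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        i = int(np.searchsorted(starts, pos - 1, side="right")) - 1
        return i >= 0 and pos - 1 < int(ends[i])


class ExpressionTable:
    """Gene-by-cell-type RPKM matrix (thin wrapper over a DataFrame)."""

    def __init__(self, frame):
        import pandas as pd

        if not isinstance(frame, pd.DataFrame):
            raise TypeError("ExpressionTable expects a pandas DataFrame")
        if frame.columns.duplicated().any():
            raise ValueError("duplicate cell-type columns")
        numeric = frame.to_numpy(dtype=float, na_value=np.nan)
        if np.nanmin(numeric, initial=0.0) < 0:
            raise ValueError("RPKM values must be non-negative")
        self.frame = frame

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.frame.columns)

    def rpkm(self, gene: str, cell_type: str) -> float | None:
        if gene not in self.frame.index or cell_type not in self.frame.columns:
            return None
        value = self.frame.at[gene, cell_type]
        return None if np.isnan(value) else float(value)


@dataclass
class GeneModel:
    """A gene's TSS, strand and genomic span."""

    gene_id: str
    chrom: str
    tss: int  # 1-based
    strand: str
    span: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not (self.span.start <= self.tss - 1 <= self.span.end):
            raise ValueError(f"{self.gene_id}: TSS outside gene span")


class GenomeAssembly:
    """In-memory reference sequence; out-of-bounds queries are rejected."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if set(seq) - set("ACGTN"):
                raise ValueError(f"contig {name}: non-ACGTN characters")
            self.sequences[name] = seq

    def contig_length(self, chrom: str) -> int:
        if chrom not in self.sequences:
            raise KeyError(f"unknown contig {chrom!r}")
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice; raises on out-of-bounds queries."""
        n = self.contig_length(chrom)
        if not (0 <= start < end <= n):
            raise ValueError(
                f"query {chrom}:{start}-{end} outside contig bounds (length {n})"
            )
        return self.sequences[chrom][start:end]

    def base_at(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position."""
        return self.fetch(chrom, pos - 1, pos)
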