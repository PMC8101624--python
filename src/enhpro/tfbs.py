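"""Allele-specific transcription-factor binding-site prediction.

Both alleles' 21-mers are scanned against TRANSFAC-style position weight
matrices on both strands at every placement covering the SNP.  A prediction
is allele-specific when the PWM probability of the two allele bases at the
SNP-aligned matrix position differs by more than fivefold and the favored
allele's sequence survives curation: exact matches at all conserved matrix
positions, at most one partial match at a partly conserved position, and no
base below 20% of its position's best probability.  Predicted TFs must also
be appreciably expressed in the focal cell type.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from Bio import motifs as bio_motifs

from .config import Config
from .model import ExpressionTable, GenomeAssembly, Variant
from .io import apply_allele, fetch_window

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

CONSERVED = "conserved"
PARTLY_CONSERVED = "partly_conserved"
UNCONSTRAINED = "unconstrained"


class AlleleOrientationError(ValueError):
    """The assembly base at the SNP does not equal the declared ref allele."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Per-position base-probability matrix with conservation classes.

    ``probs`` is width x 4 over A,C,G,T; rows sum to 1.  A position is
    conserved when its best base reaches ``conserved_prob_min``, partly
    conserved when it reaches ``partly_conserved_prob_min``, else
    unconstrained.
    """

    tf_name: str
    matrix_id: str
    probs: np.ndarray
    position_class: list[str]

    def __post_init__(self) -> None:
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be width x 4")
        if self.width < 4:
            raise ValueError(f"{self.matrix_id}: PWM width must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.matrix_id}: position probabilities must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def reverse_complemented(self) -> "PWM":
        rc = self.probs[::-1, ::-1].copy()  # reverse positions, swap A<->T, C<->G
        return PWM(self.tf_name, self.matrix_id, rc, self.position_class[::-1])


def classify_positions(probs: np.ndarray, config: Config) -> list[str]:
    classes = []
    for row in probs:
        top = float(row.max())
        if top >= config.conserved_prob_min:
            classes.append(CONSERVED)
        elif top >= config.partly_conserved_prob_min:
            classes.append(PARTLY_CONSERVED)
        else:
            classes.append(UNCONSTRAINED)
    return classes


def pwm_from_counts(
    tf_name: str,
    matrix_id: str,
    counts: np.ndarray,
    config: Config,
    pseudocount: float | None = None,
) -> PWM:
    """Normalize a width x 4 count matrix (plus pseudocount) into a PWM."""
    if pseudocount is None:
        pseudocount = config.pwm_pseudocount
    counts = np.asarray(counts, dtype=float) + pseudocount
    probs = counts / counts.sum(axis=1, keepdims=True)
    return PWM(tf_name, matrix_id, probs, classify_positions(probs, config))


def read_transfac_pwm(
    path, config: Config, pseudocount: float | None = None
) -> list[PWM]:
    """Parse a TRANSFAC flat file of count matrices into PWMs."""
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "TRANSFAC")
        except ValueError as exc:
            raise ValueError(f"{path}: malformed TRANSFAC file: {exc}") from exc
    pwms = []
    for motif in records:
        matrix_id = motif.get("ID") or motif.get("AC") or "?"
        tf_name = motif.get("NA") or matrix_id
        counts = np.array(
            [[motif.counts[b][i] for b in BASES] for i in range(motif.counts.length)],
            dtype=float,
        )
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError(f"{path}: invalid counts in matrix {matrix_id}")
        pwms.append(pwm_from_counts(tf_name, matrix_id, counts, config, pseudocount))
    return pwms


def write_transfac(pwm_counts: list[tuple[str, str, np.ndarray]], path) -> None:
    """Write (matrix_id, tf_name, width x 4 counts) triples as TRANSFAC."""
    with open(path, "w") as fh:
        for matrix_id, tf_name, counts in pwm_counts:
            fh.write(f"AC  {matrix_id}\nXX\nID  {matrix_id}\nXX\nNA  {tf_name}\nXX\n")
            fh.write("P0      A      C      G      T\n")
            for i, row in enumerate(np.asarray(counts), start=1):
                cells = "  ".join(f"{v:>5g}" for v in row)
                fh.write(f"{i:02d}  {cells}\n")
            fh.write("XX\n//\n")


@dataclass
class AlleleScanResult:
    rsid: str
    tf_name: str
    strand: str
    offset: int
    snp_pwm_index: int
    ref_center_prob: float
    alt_center_prob: float
    fold_change: float
    favored_allele: str  # "ref" or "alt"
    ref_curation_pass: bool
    alt_curation_pass: bool
    allele_specific: bool


def curate(
    window: str, strand: str, offset: int, pwm: PWM, config: Config
) -> tuple[bool, list[str]]:
    """Apply the manual-curation rules to one PWM placement.

    Pass iff (a) every conserved position matches its best base, (b) at most
    one partly conserved position carries a partial match (a non-best base
    at >= ``partial_match_min_frac`` of the best probability), and (c) no
    position's base falls below that fraction of the best probability.
    """
    w = pwm.width
    if strand == "+":
        segment = window[offset : offset + w]
        probs = pwm.probs
        classes = pwm.position_class
    else:
        segment = reverse_complement(window[offset : offset + w])
        probs = pwm.probs
        classes = pwm.position_class
    reasons: list[str] = []
    n_partial = 0
    for k, base in enumerate(segment):
        row = probs[k]
        p = float(row[_BASE_INDEX[base]])
        top = float(row.max())
        is_best = p >= top - 1e-12
        if classes[k] == CONSERVED and not is_best:
            reasons.append("conserved_mismatch")
        if p < config.partial_match_min_frac * top - 1e-12:
            reasons.append("below_partial_floor")
        elif classes[k] == PARTLY_CONSERVED and not is_best:
            n_partial += 1
    if n_partial > 1:
        reasons.append("multiple_partial_matches")
    return (not reasons), sorted(set(reasons))


def _placement_logprob(window: str, strand: str, offset: int, pwm: PWM) -> float:
    w = pwm.width
    segment = window[offset : offset + w]
    if strand == "-":
        segment = reverse_complement(segment)
    return float(
        sum(math.log(pwm.probs[k][_BASE_INDEX[b]]) for k, b in enumerate(segment))
    )


def scan_allele_pair(
    ref_window: str,
    alt_window: str,
    pwm: PWM,
    config: Config,
    rsid: str = "",
) -> list[AlleleScanResult]:
    """Score every (strand, offset) placement of the PWM covering the SNP.

    Results are sorted by favored-allele log-probability sum (best first),
    ties broken by strand (+ first) then smaller offset.
    """
    if len(ref_window) != len(alt_window) or len(ref_window) % 2 == 0:
        raise ValueError("windows must be equal odd length")
    center = len(ref_window) // 2
    diffs = [i for i in range(len(ref_window)) if ref_window[i] != alt_window[i]]
    if diffs and diffs != [center]:
        raise ValueError("windows must differ only at the center base")
    w = pwm.width
    if w > len(ref_window):
        logger.info("PWM %s wider than window; skipped", pwm.matrix_id)
        return []

    results = []
    for strand in ("+", "-"):
        for offset in range(max(0, center - w + 1), min(len(ref_window) - w, center) + 1):
            if strand == "+":
                snp_idx = center - offset
                ref_base = ref_window[center]
                alt_base = alt_window[center]
            else:
                snp_idx = w - 1 - (center - offset)
                ref_base = ref_window[center].translate(_COMPLEMENT)
                alt_base = alt_window[center].translate(_COMPLEMENT)
            ref_p = float(pwm.probs[snp_idx][_BASE_INDEX[ref_base]])
            alt_p = float(pwm.probs[snp_idx][_BASE_INDEX[alt_base]])
            lo, hi = min(ref_p, alt_p), max(ref_p, alt_p)
            fold = math.inf if lo == 0 else hi / lo
            favored = "ref" if ref_p >= alt_p else "alt"
            ref_pass, _ = curate(ref_window, strand, offset, pwm, config)
            alt_pass, _ = curate(alt_window, strand, offset, pwm, config)
            favored_pass = ref_pass if favored == "ref" else alt_pass
            disfavored_pass = alt_pass if favored == "ref" else ref_pass
            disfavored_lower = lo < hi
            allele_specific = (
                fold > config.tfbs_fold_min
                and favored_pass
                and (not disfavored_pass or disfavored_lower)
            )
            results.append(
                AlleleScanResult(
                    rsid=rsid,
                    tf_name=pwm.tf_name,
                    strand=strand,
                    offset=offset,
                    snp_pwm_index=snp_idx,
                    ref_center_prob=ref_p,
                    alt_center_prob=alt_p,
                    fold_change=fold,
                    favored_allele=favored,
                    ref_curation_pass=ref_pass,
                    alt_curation_pass=alt_pass,
                    allele_specific=allele_specific,
                )
            )

    def sort_key(r: AlleleScanResult):
        window = ref_window if r.favored_allele == "ref" else alt_window
        score = _placement_logprob(window, r.strand, r.offset, pwm)
        return (-score, 0 if r.strand == "+" else 1, r.offset)

    results.sort(key=sort_key)
    return results


def tf_expressed(
    tf_name: str, table: ExpressionTable, focal: str, config: Config
) -> bool:
    """Expression gate: focal RPKM at or above ``tf_min_rpkm`` (inclusive)."""
    rpkm = table.rpkm(tf_name, focal)
    if rpkm is None:
        logger.info("TF %s absent from expression table; treated as silent", tf_name)
        return False
    return rpkm >= config.tf_min_rpkm


def predict_allele_specific_tfbs(
    variant: Variant,
    assembly: GenomeAssembly,
    pwms: list[PWM],
    expression: ExpressionTable,
    config: Config,
) -> list[tuple[str, str]]:
    """Expressed TFs with allele-specific predicted binding at the SNP.

    Returns deduplicated (tf_name, favored_allele) pairs in deterministic
    order.  The assembly base at the SNP must equal the ref allele.
    """
    genome_base = assembly.base_at(variant.chrom, variant.pos)
    if genome_base != variant.ref_allele:
        raise AlleleOrientationError(
            f"{variant.rsid}: assembly base {genome_base} != ref allele "
            f"{variant.ref_allele}"
        )
    ref_window = fetch_window(assembly, variant.chrom, variant.pos, config.tfbs_window)
    alt_window = apply_allele(ref_window, variant.alt_allele)
    calls: set[tuple[str, str]] = set()
    for pwm in pwms:
        for result in scan_allele_pair(ref_window, alt_window, pwm, config, variant.rsid):
            if result.allele_specific and tf_expressed(
                pwm.tf_name, expression, config.focal_cell_type, config
            ):
                calls.add((pwm.tf_name, result.favored_allele))
    return sorted(calls)


def write_prediction_table(
    results: list[AlleleScanResult], path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "rsid\ttf\tstrand\toffset\tref_center_prob\talt_center_prob\t"
            "fold_change\tfavored_allele\tref_curation_pass\talt_curation_pass\t"
            "allele_specific\n"
        )
        for r in results:
            fh.write(
                f"{r.rsid}\t{r.tf_name}\t{r.strand}\t{r.offset}\t"
                f"{r.ref_center_prob:.6g}\t{r.alt_center_prob:.6g}\t"
                f"{r.fold_change:.6g}\t{r.favored_allele}\t"
                f"{int(r.ref_curation_pass)}\t{int(r.alt_curation_pass)}\t"
                f"{int(r.allele_specific)}\n"
            )
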