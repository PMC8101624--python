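"""Allele-specific PWM scanning, curation rules, expression gating."""

import math

import numpy as np
import pandas as pd
import pytest

from enhpro.config import Config
from enhpro.model import ExpressionTable, GenomeAssembly, Variant
from enhpro.tfbs import (
    AlleleOrientationError,
    CONSERVED,
    PARTLY_CONSERVED,
    UNCONSTRAINED,
    curate,
    classify_positions,
    predict_allele_specific_tfbs,
    pwm_from_counts,
    read_transfac_pwm,
    reverse_complement,
    scan_allele_pair,
    tf_expressed,
    write_transfac,
)

CFG = Config(focal_cell_type="ostb")
BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def consensus_pwm(consensus: str, center_overrides: dict[int, list[float]] = {}):
    rows = []
    for i, base in enumerate(consensus):
        if i in center_overrides:
            rows.append(center_overrides[i])
        else:
            rows.append([97.0 if b == base else 1.0 for b in BASES])
    return pwm_from_counts("TF1", "M1", np.array(rows), CFG, pseudocount=0.0)


class TestTransfacReading:
    def test_position_classes_from_counts(self, tmp_path):
        counts = np.array(
            [[97, 1, 1, 1], [60, 30, 5, 5], [25, 25, 25, 25], [1, 1, 1, 97]],
            dtype=float,
        )
        write_transfac([("M1", "TFX", counts)], tmp_path / "m.transfac")
        (pwm,) = read_transfac_pwm(tmp_path / "m.transfac", CFG, pseudocount=0.0)
        assert pwm.tf_name == "TFX"
        assert pwm.position_class == [
            CONSERVED, PARTLY_CONSERVED, UNCONSTRAINED, CONSERVED,
        ]
        np.testing.assert_allclose(pwm.probs.sum(axis=1), 1.0)
        assert pwm.probs[0, 0] == pytest.approx(0.97)

    def test_pseudocount_keeps_probs_positive(self, tmp_path):
        counts = np.array([[100, 0, 0, 0]] * 4, dtype=float)
        write_transfac([("M1", "TFX", counts)], tmp_path / "m.transfac")
        (pwm,) = read_transfac_pwm(tmp_path / "m.transfac", CFG)  # default 0.01
        assert pwm.probs.min() > 0

    def test_round_trip_through_flat_file(self, tmp_path):
        rng = np.random.default_rng(41)
        counts = rng.integers(0, 100, size=(8, 4)).astype(float)
        write_transfac([("M7", "TFY", counts)], tmp_path / "m.transfac")
        (pwm,) = read_transfac_pwm(tmp_path / "m.transfac", CFG, pseudocount=0.0)
        np.testing.assert_allclose(
            pwm.probs, counts / counts.sum(axis=1, keepdims=True), atol=1e-12
        )


class TestFivefoldRule:
    def windows(self, center_ref="A", center_alt="G"):
        flank = "ACGTACGTAC"
        return flank + center_ref + flank, flank + center_alt + flank

    def pwm_with_center(self, a=50.0, g=5.0):
        ref_w, _ = self.windows()
        consensus = ref_w[5:16]  # 11-mer covering the center at index 5
        counts = {b: 1.0 for b in BASES}
        counts["A"], counts["G"] = a, g
        counts["C"] = 100.0 - a - g - 1.0
        return consensus_pwm(consensus, {5: [counts[b] for b in BASES]})

    def designed(self, results):
        return [r for r in results if r.strand == "+" and r.offset == 5]

    def test_identical_windows_nothing_allele_specific(self):
        ref_w, _ = self.windows()
        results = scan_allele_pair(ref_w, ref_w, self.pwm_with_center(), CFG)
        assert results and all(r.fold_change == 1.0 for r in results)
        assert not any(r.allele_specific for r in results)

    def test_tenfold_contrast_is_allele_specific(self):
        ref_w, alt_w = self.windows()
        (r,) = self.designed(scan_allele_pair(ref_w, alt_w, self.pwm_with_center(50, 5), CFG))
        assert r.fold_change == pytest.approx(10.0)
        assert r.favored_allele == "ref"
        assert r.allele_specific

    def test_contrast_just_below_five_rejected(self):
        ref_w, alt_w = self.windows()
        (r,) = self.designed(scan_allele_pair(ref_w, alt_w, self.pwm_with_center(50, 12), CFG))
        assert r.fold_change == pytest.approx(50 / 12)
        assert not r.allele_specific

    def test_exactly_fivefold_is_not_greater_than(self):
        ref_w, alt_w = self.windows()
        (r,) = self.designed(scan_allele_pair(ref_w, alt_w, self.pwm_with_center(50, 10), CFG))
        assert r.fold_change == pytest.approx(5.0)
        assert not r.allele_specific


class TestCuration:
    def test_full_consensus_passes(self):
        pwm = consensus_pwm("ACGTACGT")
        ok, reasons = curate("ACGTACGT" + "A" * 13, "+", 0, pwm, CFG)
        assert ok and reasons == []

    def test_conserved_mismatch_fails(self):
        pwm = consensus_pwm("ACGTACGT")
        ok, reasons = curate("TCGTACGT" + "A" * 13, "+", 0, pwm, CFG)
        assert not ok and "conserved_mismatch" in reasons

    def test_two_partial_matches_fail_one_passes(self):
        # positions 0 and 1 partly conserved: best base 55, partial base 30
        overrides = {
            0: [55.0, 30.0, 10.0, 5.0],  # best A, C is a partial match
            1: [55.0, 30.0, 10.0, 5.0],
        }
        pwm = consensus_pwm("AAGTACGT", overrides)
        assert pwm.position_class[0] == PARTLY_CONSERVED
        ok_one, _ = curate("CAGTACGT" + "A" * 13, "+", 0, pwm, CFG)
        assert ok_one
        ok_two, reasons = curate("CCGTACGT" + "A" * 13, "+", 0, pwm, CFG)
        assert not ok_two and "multiple_partial_matches" in reasons

    def test_below_partial_floor_fails_any_class(self):
        overrides = {0: [55.0, 30.0, 10.0, 5.0]}
        pwm = consensus_pwm("AAGTACGT", overrides)
        # T at position 0 has prob 0.05 < 0.2 * 0.55
        ok, reasons = curate("TAGTACGT" + "A" * 13, "+", 0, pwm, CFG)
        assert not ok and "below_partial_floor" in reasons

    def test_monotone_in_partial_match_floor(self):
        """Raising partial_match_min_frac never converts a fail into a pass."""
        rng = np.random.default_rng(43)
        fracs = [0.05, 0.2, 0.5, 0.9]
        for _ in range(50):
            counts = rng.integers(1, 100, size=(8, 4)).astype(float)
            pwm = pwm_from_counts("T", "M", counts, CFG, pseudocount=0.0)
            window = "".join(rng.choice(list(BASES), size=21))
            outcomes = [
                curate(window, "+", 3, pwm, CFG.replace(partial_match_min_frac=f))[0]
                for f in fracs
            ]
            # once failed at a lower floor, must stay failed at higher floors
            for a, b in zip(outcomes, outcomes[1:]):
                assert a or not b


def brute_force_scan(ref_w, alt_w, pwm, config):
    """Independent exhaustive scanner used as the oracle."""
    center = len(ref_w) // 2
    out = []
    for strand in ("+", "-"):
        for offset in range(len(ref_w) - pwm.width + 1):
            if not (offset <= center < offset + pwm.width):
                continue  # placement must cover the SNP

            def seg(window):
                s = window[offset : offset + pwm.width]
                return reverse_complement(s) if strand == "-" else s

            def cur(window):
                segment = seg(window)
                n_partial = 0
                for k, base in enumerate(segment):
                    p = pwm.probs[k][BASES.index(base)]
                    top = max(pwm.probs[k])
                    if p < config.partial_match_min_frac * top - 1e-12:
                        return False
                    if pwm.position_class[k] == CONSERVED and p < top - 1e-12:
                        return False
                    if pwm.position_class[k] == PARTLY_CONSERVED and p < top - 1e-12:
                        n_partial += 1
                return n_partial <= 1

            if strand == "+":
                k_snp = center - offset
                rb, ab = ref_w[center], alt_w[center]
            else:
                k_snp = pwm.width - 1 - (center - offset)
                rb, ab = COMP[ref_w[center]], COMP[alt_w[center]]
            rp = pwm.probs[k_snp][BASES.index(rb)]
            ap = pwm.probs[k_snp][BASES.index(ab)]
            fold = max(rp, ap) / min(rp, ap) if min(rp, ap) > 0 else math.inf
            favored = "ref" if rp >= ap else "alt"
            fav_pass = cur(ref_w) if favored == "ref" else cur(alt_w)
            specific = fold > config.tfbs_fold_min and fav_pass and rp != ap
            out.append(
                (strand, offset, k_snp, round(rp, 12), round(ap, 12),
                 favored, cur(ref_w), cur(alt_w), specific)
            )
    return out


class TestScannerAgainstBruteForce:
    def random_case(self, rng):
        window = "".join(rng.choice(list(BASES), size=21))
        ref = window[10]
        alt = rng.choice([b for b in BASES if b != ref])
        alt_w = window[:10] + alt + window[11:]
        width = int(rng.integers(4, 15))
        counts = rng.integers(0, 40, size=(width, 4)).astype(float)
        counts[rng.integers(0, width)] = [97, 1, 1, 1]  # one conserved anchor
        pwm = pwm_from_counts("T", "M", counts, CFG)
        return window, alt_w, pwm

    def test_matches_brute_force_on_200_random_pairs(self):
        rng = np.random.default_rng(47)
        for _ in range(200):
            ref_w, alt_w, pwm = self.random_case(rng)
            got = {
                (r.strand, r.offset, r.snp_pwm_index,
                 round(r.ref_center_prob, 12), round(r.alt_center_prob, 12),
                 r.favored_allele, r.ref_curation_pass, r.alt_curation_pass,
                 r.allele_specific)
                for r in scan_allele_pair(ref_w, alt_w, pwm, CFG)
            }
            assert got == set(brute_force_scan(ref_w, alt_w, pwm, CFG))

    def test_strand_symmetry(self):
        """Reverse-complementing windows and PWM preserves the fold multiset."""
        rng = np.random.default_rng(53)
        for _ in range(50):
            ref_w, alt_w, pwm = self.random_case(rng)
            a = sorted(
                round(r.fold_change, 9)
                for r in scan_allele_pair(ref_w, alt_w, pwm, CFG)
            )
            b = sorted(
                round(r.fold_change, 9)
                for r in scan_allele_pair(
                    reverse_complement(ref_w),
                    reverse_complement(alt_w),
                    pwm.reverse_complemented(),
                    CFG,
                )
            )
            assert a == b

    def test_allele_swap_flips_favored_and_keeps_fold(self):
        rng = np.random.default_rng(59)
        for _ in range(50):
            ref_w, alt_w, pwm = self.random_case(rng)
            fwd = scan_allele_pair(ref_w, alt_w, pwm, CFG)
            rev = scan_allele_pair(alt_w, ref_w, pwm, CFG)
            key = lambda r: (r.strand, r.offset)
            for a, b in zip(sorted(fwd, key=key), sorted(rev, key=key)):
                assert a.fold_change == pytest.approx(b.fold_change)
                if a.ref_center_prob != a.alt_center_prob:
                    assert a.favored_allele != b.favored_allele

    def test_results_sorted_by_favored_logprob(self):
        rng = np.random.default_rng(61)
        from enhpro.tfbs import _placement_logprob

        for _ in range(20):
            ref_w, alt_w, pwm = self.random_case(rng)
            results = scan_allele_pair(ref_w, alt_w, pwm, CFG)
            scores = [
                _placement_logprob(
                    ref_w if r.favored_allele == "ref" else alt_w,
                    r.strand, r.offset, pwm,
                )
                for r in results
            ]
            assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))


class TestExpressionGate:
    def table(self, rpkm):
        return ExpressionTable(
            pd.DataFrame({"ostb": [rpkm], "c0": [9.9]}, index=["TF1"])
        )

    def test_threshold_inclusive(self):
        assert tf_expressed("TF1", self.table(0.8), "ostb", CFG)

    def test_below_threshold(self):
        assert not tf_expressed("TF1", self.table(0.79), "ostb", CFG)

    def test_absent_tf_silent(self):
        assert not tf_expressed("TF9", self.table(5.0), "ostb", CFG)


class TestPredictAlleleSpecific:
    def setup_case(self, tf_rpkm=5.0, a=52.0, g=5.0):
        rng = np.random.default_rng(67)
        seq = "".join(rng.choice(list(BASES), size=101))
        pos = 51
        seq = seq[:50] + "A" + seq[51:]
        assembly = GenomeAssembly({"c": seq})
        variant = Variant("rsT", "c", pos, "A", "G")
        consensus = seq[pos - 6 : pos + 5]
        counts = {b: 1.0 for b in BASES}
        counts["A"], counts["G"] = a, g
        counts["C"] = 100.0 - a - g - 1.0
        rows = []
        for i, base in enumerate(consensus):
            if i == 5:
                rows.append([counts[b] for b in BASES])
            else:
                rows.append([97.0 if b == base else 1.0 for b in BASES])
        pwm = pwm_from_counts("TF1", "M1", np.array(rows), CFG)
        expr = ExpressionTable(
            pd.DataFrame({"ostb": [tf_rpkm], "c0": [1.0]}, index=["TF1"])
        )
        return variant, assembly, [pwm], expr

    def test_engineered_sixfold_yields_single_ref_call(self):
        variant, assembly, pwms, expr = self.setup_case(a=52.0, g=8.0)  # 6.5-fold
        calls = predict_allele_specific_tfbs(variant, assembly, pwms, expr, CFG)
        assert calls == [("TF1", "ref")]

    def test_silent_tf_gated_out(self):
        variant, assembly, pwms, expr = self.setup_case(tf_rpkm=0.0)
        assert predict_allele_specific_tfbs(variant, assembly, pwms, expr, CFG) == []

    def test_allele_orientation_checked(self):
        variant, assembly, pwms, expr = self.setup_case()
        bad = Variant("rsT", "c", variant.pos, "C", "G")
        with pytest.raises(AlleleOrientationError):
            predict_allele_specific_tfbs(bad, assembly, pwms, expr, CFG)
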