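"""Domain types, format readers/writers and sequence-window helpers."""

import numpy as np
import pytest

from enhpro import io
from enhpro.model import (
    GenomeAssembly,
    GenomicInterval,
    PeakTrack,
    SegmentationTrack,
    Variant,
)


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


ASSOC_TOY = (
    "rsid\tchrom\tpos\tref\talt\tpvalue\treported_genes\n"
    "rs1\tchr1\t100\tA\tG\t1e-9\tGENEA\n"
    "rs2\tchr1\t200\tC\tT\t1e-7\tGENEB\n"
    "rs3\tchr1\t300\tG\tA\t4.9e-8\tGENEA,GENEC\n"
)


class TestAssociationTable:
    @pytest.mark.parametrize(
        "threshold,expected",
        [(5e-8, ["rs1", "rs3"]), (6.6e-9, ["rs1"]), (None, ["rs1", "rs2", "rs3"])],
    )
    def test_p_threshold_is_strict_and_order_preserving(
        self, tmp_path, threshold, expected
    ):
        path = write(tmp_path, "a.tsv", ASSOC_TOY)
        variants = io.read_association_table(path, threshold)
        assert [v.rsid for v in variants] == expected
        assert all(v.source == "index" for v in variants)

    def test_reported_genes_are_split(self, tmp_path):
        path = write(tmp_path, "a.tsv", ASSOC_TOY)
        variants = io.read_association_table(path, None)
        assert variants[2].reported_genes == ["GENEA", "GENEC"]

    def test_empty_data_section(self, tmp_path):
        path = write(tmp_path, "a.tsv", ASSOC_TOY.splitlines()[0] + "\n")
        assert io.read_association_table(path, 5e-8) == []

    def test_missing_column_error_names_column(self, tmp_path):
        path = write(tmp_path, "a.tsv", "rsid\tchrom\tpos\nrs1\tchr1\t5\n")
        with pytest.raises(ValueError, match="ref"):
            io.read_association_table(path, 5e-8)

    def test_bad_pvalue_reports_line_number(self, tmp_path):
        bad = ASSOC_TOY.replace("1e-7", "oops")
        path = write(tmp_path, "a.tsv", bad)
        with pytest.raises(ValueError, match="line 3"):
            io.read_association_table(path, 5e-8)

    def test_indels_dropped(self, tmp_path):
        text = ASSOC_TOY + "rs4\tchr1\t400\tAT\tA\t1e-12\t\n"
        path = write(tmp_path, "a.tsv", text)
        assert [v.rsid for v in io.read_association_table(path, 5e-8)] == ["rs1", "rs3"]

    def test_round_trip(self, tmp_path):
        path = write(tmp_path, "a.tsv", ASSOC_TOY)
        variants = io.read_association_table(path, None)
        out = tmp_path / "b.tsv"
        io.write_association_table(variants, out)
        again = io.read_association_table(out, None)
        assert [(v.rsid, v.pos, v.ref_allele, v.reported_genes) for v in again] == [
            (v.rsid, v.pos, v.ref_allele, v.reported_genes) for v in variants
        ]


class TestVariant:
    def test_rejects_identical_alleles(self):
        with pytest.raises(ValueError):
            Variant("rs1", "chr1", 10, "A", "A")

    def test_r2_required_iff_proxy(self):
        with pytest.raises(ValueError):
            Variant("rs1", "chr1", 10, "A", "G", source="proxy")
        with pytest.raises(ValueError):
            Variant("rs1", "chr1", 10, "A", "G", source="index", r2_to_index=0.9)


class TestSegmentationBed:
    def test_mnemonic_and_bare_integer_dialects(self, tmp_path):
        path = write(tmp_path, "s.bed", "chr1\t100\t200\t9_EnhA1\nchr1\t200\t300\t15\n")
        track = io.read_segmentation_bed(path, "ostb")
        assert track.state_at_pos("chr1", 150) == 9
        assert track.state_at_pos("chr1", 250) == 15

    def test_overlap_is_an_error(self, tmp_path):
        path = write(tmp_path, "s.bed", "chr1\t100\t200\t9_EnhA1\nchr1\t150\t250\t15\n")
        with pytest.raises(ValueError, match="overlap"):
            io.read_segmentation_bed(path, "ostb")

    def test_unknown_label_reported(self, tmp_path):
        path = write(tmp_path, "s.bed", "chr1\t100\t200\tEnhX\n")
        with pytest.raises(ValueError, match="EnhX"):
            io.read_segmentation_bed(path, "ostb")

    def test_round_trip_with_mnemonic_emission(self, tmp_path):
        path = write(tmp_path, "s.bed", "chr1\t100\t200\t9\nchr2\t0\t50\t1\n")
        track = io.read_segmentation_bed(path, "ostb")
        out = tmp_path / "o.bed"
        io.write_segmentation_bed(track, out)
        text = out.read_text()
        assert "9_" in text and "1_" in text
        again = io.read_segmentation_bed(out, "ostb")
        assert sorted((iv.chrom, iv.start, iv.end, iv.label) for iv in again.intervals) == sorted(
            (iv.chrom, iv.start, iv.end, iv.label) for iv in track.intervals
        )


class TestNarrowPeak:
    LINE = "chr1\t100\t600\tpeak1\t900\t.\t5.2\t-1\t-1\t{summit}\n"

    def test_summit_parsed(self, tmp_path):
        path = write(tmp_path, "p.np", self.LINE.format(summit=250))
        track = io.read_narrowpeak(path, "ostb", "H3K27ac")
        assert track.summit_offsets == [250]

    def test_summit_minus_one_absent(self, tmp_path):
        path = write(tmp_path, "p.np", self.LINE.format(summit=-1))
        track = io.read_narrowpeak(path, "ostb", "H3K27ac")
        assert track.summit_offsets == [None]

    def test_overlapping_peaks_all_retained(self, tmp_path):
        rng = np.random.default_rng(7)
        lines = []
        for _ in range(50):
            start = int(rng.integers(0, 500))
            end = start + int(rng.integers(10, 300))
            lines.append(f"chr1\t{start}\t{end}\tp\t0\t.\t0\t-1\t-1\t-1\n")
        path = write(tmp_path, "p.np", "".join(lines))
        track = io.read_narrowpeak(path, "ostb", "DHS")
        assert len(track.intervals) == len(lines)

    def test_too_few_columns(self, tmp_path):
        path = write(tmp_path, "p.np", "chr1\t100\t600\tpeak1\t900\t.\n")
        with pytest.raises(ValueError, match="columns"):
            io.read_narrowpeak(path, "ostb", "DHS")

    def test_round_trip(self, tmp_path):
        path = write(
            tmp_path,
            "p.np",
            self.LINE.format(summit=250) + "chr2\t5\t25\tpk\t0\t.\t0\t-1\t-1\t-1\n",
        )
        track = io.read_narrowpeak(path, "ostb", "DHS")
        out = tmp_path / "o.np"
        io.write_narrowpeak(track, out)
        again = io.read_narrowpeak(out, "ostb", "DHS")
        assert [(iv.chrom, iv.start, iv.end) for iv in again.intervals] == [
            (iv.chrom, iv.start, iv.end) for iv in track.intervals
        ]
        assert again.summit_offsets == track.summit_offsets


class TestSequenceWindows:
    def test_window_exact_fit(self):
        assembly = GenomeAssembly({"c": "ACGTACGTACGTACGTACGTA"})
        assert io.fetch_window(assembly, "c", 11, 21) == "ACGTACGTACGTACGTACGTA"

    def test_window_clipped_is_error(self):
        assembly = GenomeAssembly({"c": "ACGTACGTACGTACGTACGTA"})
        with pytest.raises(ValueError):
            io.fetch_window(assembly, "c", 10, 21)

    def test_center_base_matches_direct_indexing(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        assembly = GenomeAssembly({"c": seq})
        for pos in rng.integers(11, 490, size=50):
            window = io.fetch_window(assembly, "c", int(pos), 21)
            assert window[10] == assembly.base_at("c", int(pos))

    def test_n_in_window_warns_but_returns(self):
        assembly = GenomeAssembly({"c": "A" * 10 + "N" + "A" * 10})
        with pytest.warns(UserWarning):
            window = io.fetch_window(assembly, "c", 11, 21)
        assert window[10] == "N"

    def test_apply_allele_center_only(self):
        window = "AAAAAAAAAACAAAAAAAAAA"
        out = io.apply_allele(window, "T")
        assert out[10] == "T"
        assert [i for i in range(21) if out[i] != window[i]] == [10]
        # applying ref, then alt, then ref returns the original window
        assert io.apply_allele(io.apply_allele(out, "C"), "C") == window

    def test_fasta_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        assembly = GenomeAssembly(
            {"c1": "".join(rng.choice(list("ACGT"), size=333)), "c2": "ACGTN"}
        )
        path = tmp_path / "g.fa"
        io.write_fasta(assembly, path)
        again = io.read_fasta_assembly(path)
        assert again.sequences == assembly.sequences


class TestCoordinateLaw:
    def test_point_overlap_matches_brute_force(self):
        """A variant at pos p overlaps [s,e) iff s <= p-1 < e."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            pos = int(rng.integers(1, 300))
            start = int(rng.integers(0, 290))
            end = start + int(rng.integers(1, 30))
            iv = GenomicInterval("c", start, end)
            brute = any(p == pos - 1 for p in range(start, end))
            assert iv.contains_pos(pos) == brute

    def test_segmentation_partition(self, sim):
        """No base is assigned two states in any generated segmentation."""
        for cell, path in sim.bundle.segmentation.items():
            track = io.read_segmentation_bed(path, cell)  # ctor enforces partition
            by_contig = {}
            for iv in track.intervals:
                by_contig.setdefault(iv.chrom, []).append((iv.start, iv.end))
            for spans in by_contig.values():
                spans.sort()
                assert all(b >= prev_e for (_, prev_e), (b, _) in zip(spans, spans[1:]))


class TestVcfPanel:
    def test_round_trip_phased(self, tmp_path):
        from enhpro.ld import GenotypePanel, SiteRecord

        haps = np.array([[0, 1], [1, 1], [0, 0], [1, 0]], dtype=np.int8)
        panel = GenotypePanel(
            samples=["s1", "s2"],
            loci=[SiteRecord("rs1", "chr1", 100, "A", "G"),
                  SiteRecord("rs2", "chr1", 200, "C", "T")],
            dosage=(haps[0::2] + haps[1::2]).astype(np.int8),
            phased=True,
            haplotypes=haps,
        )
        path = tmp_path / "p.vcf"
        io.write_vcf_panel(panel, path, {"chr1": 1000})
        again = io.read_vcf_panel(path)
        assert again.phased
        assert [s.rsid for s in again.loci] == ["rs1", "rs2"]
        np.testing.assert_array_equal(again.haplotypes, haps)
        np.testing.assert_array_equal(again.dosage, panel.dosage)


class TestGeneModels:
    def test_gtf_round_trip_and_tss_strand(self, tmp_path):
        from enhpro.model import GeneModel

        models = [
            GeneModel("GPLUS", "chr1", 1001, "+", GenomicInterval("chr1", 1000, 5000)),
            GeneModel("GMINUS", "chr1", 9000, "-", GenomicInterval("chr1", 6000, 9000)),
        ]
        path = tmp_path / "g.gtf"
        io.write_gene_models_gtf(models, path)
        again = {m.gene_id: m for m in io.read_gene_models_gtf(path)}
        assert again["GPLUS"].tss == 1001 and again["GPLUS"].strand == "+"
        assert again["GMINUS"].tss == 9000 and again["GMINUS"].strand == "-"
        assert again["GMINUS"].span.start == 6000 and again["GMINUS"].span.end == 9000
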