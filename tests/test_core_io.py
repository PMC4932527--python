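"""FASTA/VCF/BED round-trips, coordinate conventions, and indel
normalization against the reconstruction oracle."""

import pytest
from hypothesis import given, settings, strategies as st

from otscreen.core_io import (
    GenomeAssembly,
    MaskSet,
    VariantRecord,
    is_normalized,
    normalize_indel,
    read_bed,
    read_fasta,
    read_vcf,
    write_bed,
    write_fasta,
    write_vcf,
)

from oracles import canonical_edit, equivalent_encodings

dna = st.text(alphabet="ACGT", min_size=1)


# ---------------------------------------------------------------------------
# FASTA


class TestFasta:
    def test_multiline_records_joined_and_uppercased(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1 description text\nACGT\nacgt\n>chr2\nTTTT\n")
        g = read_fasta(p)
        assert g.sequences == {"chr1": "ACGTACGT", "chr2": "TTTT"}
        assert g.lengths == {"chr1": 8, "chr2": 4}

    def test_duplicate_header_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n>chr1\nTTTT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            read_fasta(p)

    def test_non_iupac_character_names_position(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACXT\n")
        with pytest.raises(ValueError, match="position 2"):
            read_fasta(p)

    def test_write_read_round_trip_byte_stable(self, tmp_path, small_genome):
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(small_genome, p1)
        write_fasta(read_fasta(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# VCF


class TestVcf:
    HEADER = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=10000>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )

    def _write(self, tmp_path, body):
        p = tmp_path / "x.vcf"
        p.write_text(self.HEADER + body)
        return p

    def test_deletion_parsed_directly(self, tmp_path):
        p = self._write(tmp_path, "chr1\t100\t.\tAT\tA\t.\tPASS\t.\n")
        (v,) = read_vcf(p, "s1")
        assert (v.chrom, v.pos, v.ref, v.alt) == ("chr1", 100, "AT", "A")
        assert v.vtype == "deletion"
        assert v.samples == frozenset({"s1"})

    def test_multiallelic_split_one_record_per_alt(self, tmp_path):
        p = self._write(tmp_path, "chr1\t100\t.\tA\tG,ATT\t.\tPASS\t.\n")
        recs = read_vcf(p, "s1")
        assert [(v.ref, v.alt, v.vtype) for v in recs] == [
            ("A", "G", "SNV"),
            ("A", "ATT", "insertion"),
        ]

    def test_non_pass_filter_dropped_dot_kept(self, tmp_path):
        body = (
            "chr1\t100\t.\tA\tG\t.\tLowQual\t.\n"
            "chr1\t200\t.\tA\tG\t.\t.\t.\n"
            "chr1\t300\t.\tA\tG\t.\tPASS\t.\n"
        )
        p = self._write(tmp_path, body)
        assert [v.pos for v in read_vcf(p, "s1")] == [200, 300]

    def test_keep_filters_configurable(self, tmp_path):
        p = self._write(tmp_path, "chr1\t100\t.\tA\tG\t.\tLowQual\t.\n")
        assert len(read_vcf(p, "s1", keep_filters=("PASS", ".", "LowQual"))) == 1

    def test_write_read_round_trip(self, tmp_path):
        recs = [
            VariantRecord("chr1", 100, "AT", "A"),
            VariantRecord("chr1", 50, "C", "CGG"),
        ]
        p = tmp_path / "x.vcf"
        write_vcf(recs, {"chr1": 10_000}, p)
        back = read_vcf(p, "s")
        assert [v.key for v in back] == sorted(v.key for v in recs)


# ---------------------------------------------------------------------------
# BED / masks


class TestBed:
    def test_bed_line_convention(self, tmp_path):
        p = tmp_path / "m.bed"
        write_bed([("chr1", 10, 20)], p)
        assert p.read_text() == "chr1\t10\t20\n"

    def test_round_trip_with_merge_and_order(self, tmp_path):
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed([("chr2", 5, 8), ("chr1", 30, 40), ("chr1", 10, 20)], p1)
        mask = read_bed(p1)
        write_bed(mask, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_mask_writes_empty_file(self, tmp_path):
        p = tmp_path / "m.bed"
        write_bed([], p)
        assert p.read_text() == ""

    def test_overlap_queries_half_open(self):
        mask = MaskSet({"chr1": [(100, 200), (150, 250), (400, 500)]})
        assert mask.intervals["chr1"] == [(100, 250), (400, 500)]
        assert mask.overlaps("chr1", 150, 151)
        assert not mask.overlaps("chr1", 250, 251)   # half-open end
        assert not mask.overlaps("chr1", 99, 100)    # half-open start
        assert not mask.overlaps("chrX", 0, 1000)


# ---------------------------------------------------------------------------
# Normalization


class TestNormalizeIndel:
    def test_left_aligned_to_start_of_homopolymer_run(self):
        # CAAAT: deleting either A is the same physical edit
        g = GenomeAssembly({"chr1": "GGCAAATGG"})
        late = VariantRecord("chr1", 5, "AA", "A")
        early = VariantRecord("chr1", 4, "AA", "A")
        n1, n2 = normalize_indel(late, g), normalize_indel(early, g)
        assert n1 == n2
        assert (n1.pos, n1.ref, n1.alt) == (3, "CA", "C")

    def test_affix_trimming_reduces_mnv_to_snv(self):
        g = GenomeAssembly({"chr1": "TTTTTTTTTCATTTTT"})
        v = VariantRecord("chr1", 10, "CAT", "CGT")
        n = normalize_indel(v, g)
        assert (n.pos, n.ref, n.alt) == (11, "A", "G")

    def test_snv_already_normalized_unchanged(self):
        g = GenomeAssembly({"chr1": "ACGTACGT"})
        v = VariantRecord("chr1", 3, "G", "C")
        assert normalize_indel(v, g) == v

    def test_ref_genome_disagreement_is_error(self):
        g = GenomeAssembly({"chr1": "ACGTACGT"})
        with pytest.raises(ValueError, match="disagrees"):
            normalize_indel(VariantRecord("chr1", 3, "T", "A"), g)

    def test_out_of_bounds_is_error(self):
        g = GenomeAssembly({"chr1": "ACGT"})
        with pytest.raises(ValueError, match="exceeds"):
            normalize_indel(VariantRecord("chr1", 4, "TAA", "T"), g)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_matches_reconstruction_oracle_and_idempotent(self, data):
        """Any encoding of an edit in a random <=50-bp context normalizes
        to the oracle's canonical leftmost representation, idempotently."""
        seq = data.draw(st.text(alphabet="ACGT", min_size=10, max_size=50))
        pos = data.draw(st.integers(1, len(seq) - 4))
        ref_len = data.draw(st.integers(1, min(4, len(seq) - pos + 1)))
        ref = seq[pos - 1:pos - 1 + ref_len]
        alt = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=4))
        if ref == alt:
            alt = alt + "A" if alt[-1] != "A" else alt + "C"
        g = GenomeAssembly({"c": seq})
        n = normalize_indel(VariantRecord("c", pos, ref, alt), g)
        assert (n.pos, n.ref, n.alt) == canonical_edit(seq, pos, ref, alt)
        assert normalize_indel(n, g) == n
        assert is_normalized(n, g)

    def test_all_equivalent_encodings_collapse(self):
        """Every enumerated equivalent VCF encoding of one edit in a
        repetitive context maps to the identical record."""
        seq = "GATTACAGATTACAAAAAGCGCGCGTT"
        g = GenomeAssembly({"c": seq})
        base = VariantRecord("c", 15, "AAA", "A")
        encodings = equivalent_encodings(seq, 15, "AAA", "A", limit=12)
        assert len(encodings) > 3
        targets = {
            normalize_indel(VariantRecord("c", p, r, a), g).key
            for p, r, a in encodings
        }
        assert targets == {normalize_indel(base, g).key}
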