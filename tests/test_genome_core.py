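import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crmscreen.genome_core import (
    ContactMatrix,
    FormatError,
    GenomicInterval,
    SequenceRecord,
    parse_contact_matrix,
    parse_fasta,
    parse_intervals,
    write_bed,
    write_contact_matrix,
    write_fasta,
)


class TestGenomicInterval:
    def test_half_open_length_and_midpoint(self):
        iv = GenomicInterval("chr2", 100, 200, name="peak1")
        assert len(iv) == 100
        assert iv.midpoint == 150.0

    @pytest.mark.parametrize("start,end", [(200, 100), (100, 100), (-1, 5)])
    def test_invalid_coordinates_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_overlap_requires_same_chrom(self):
        a = GenomicInterval("chr1", 0, 10)
        assert a.overlap_len(GenomicInterval("chr2", 0, 10)) == 0
        assert a.overlap_len(GenomicInterval("chr1", 9, 20)) == 1
        assert not a.overlaps(GenomicInterval("chr1", 10, 20))


class TestIntervalParsing:
    def test_bed_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr2\t100\t200\tpeak1\n")
        (iv,) = parse_intervals(p, "BED")
        assert (iv.chrom, iv.start, iv.end, iv.name) == ("chr2", 100, 200, "peak1")

    def test_gff3_converted_to_zero_based(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("##gff-version 3\nchr1\tsrc\texon\t101\t200\t.\t+\t.\tID=e1\n")
        (iv,) = parse_intervals(p, "GFF3")
        assert (iv.start, iv.end) == (100, 200)
        assert iv.feature_type == "exon"
        assert iv.name == "e1"

    def test_bedgraph_value(self, tmp_path):
        p = tmp_path / "a.bedGraph"
        p.write_text("chr1\t0\t10\t2.5\n")
        (iv,) = parse_intervals(p, "bedGraph")
        assert iv.value == 2.5

    def test_inverted_interval_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr2\t100\t200\nchr2\t200\t100\n")
        with pytest.raises(FormatError, match=":2"):
            parse_intervals(p, "BED")

    def test_malformed_line_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr2\t100\n")
        with pytest.raises(FormatError, match=":1"):
            parse_intervals(p, "BED")

    @settings(max_examples=25, derandomize=True)
    @given(
        items=st.lists(
            st.tuples(
                st.integers(0, 10**6), st.integers(1, 10**4), st.sampled_from("+-.")
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_bed_round_trip_is_identity(self, items, tmp_path_factory):
        ivs = [
            GenomicInterval("chrT", s, s + ln, strand=strand, name=f"iv{k}")
            for k, (s, ln, strand) in enumerate(items)
        ]
        p = tmp_path_factory.mktemp("rt") / "rt.bed"
        write_bed(ivs, p)
        back = parse_intervals(p, "BED")
        assert [(i.chrom, i.start, i.end, i.strand, i.name) for i in ivs] == [
            (i.chrom, i.start, i.end, i.strand, i.name) for i in back
        ]


class TestFasta:
    def test_upper_cased(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nacgt\n")
        (rec,) = parse_fasta(p)
        assert rec.seq == "ACGT"

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGT\n>a\nTTTT\n")
        with pytest.raises(FormatError, match="duplicate"):
            parse_fasta(p)

    def test_aligned_lengths_checked(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nAC-GT\n>b\nACGT\n")
        with pytest.raises(FormatError, match="unequal"):
            parse_fasta(p, aligned=True)
        parse_fasta(p)  # fine unaligned

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("")
        with pytest.raises(FormatError):
            parse_fasta(p)

    def test_round_trip(self, tmp_path):
        recs = [SequenceRecord("a", "ACGTN" * 40), SequenceRecord("b", "TTTT")]
        p = tmp_path / "rt.fa"
        write_fasta(recs, p)
        assert parse_fasta(p) == recs

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            SequenceRecord("a", "ACGU")


class TestContactMatrix:
    def _write(self, tmp_path, m, nbins, width=10000):
        mp, bp = tmp_path / "m.tsv", tmp_path / "b.bed"
        np.savetxt(mp, m, delimiter="\t")
        write_bed(
            [GenomicInterval("chr1", i * width, (i + 1) * width) for i in range(nbins)],
            bp,
        )
        return mp, bp

    def test_symmetric_parse(self, tmp_path):
        m = np.array([[1.0, 2, 3], [2, 1, 2], [3, 2, 1]])
        cm = parse_contact_matrix(*self._write(tmp_path, m, 3))
        assert cm.n_bins == 3 and cm.bin_width == 10000

    def test_bin_count_mismatch(self, tmp_path):
        m = np.eye(3)
        with pytest.raises(FormatError, match="bins"):
            parse_contact_matrix(*self._write(tmp_path, m, 2))

    def test_negative_entry(self, tmp_path):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = -1
        with pytest.raises(FormatError, match="negative"):
            parse_contact_matrix(*self._write(tmp_path, m, 3))

    def test_gross_asymmetry_rejected_small_repaired(self, tmp_path):
        m = np.array([[1.0, 5], [1, 1]])
        with pytest.raises(FormatError, match="asymmetry"):
            parse_contact_matrix(*self._write(tmp_path, m, 2))
        m2 = np.array([[1.0, 2 + 1e-9], [2, 1]])
        cm = parse_contact_matrix(*self._write(tmp_path, m2, 2))
        assert cm.matrix[0, 1] == cm.matrix[1, 0]

    def test_nonuniform_bins_rejected(self):
        bins = [GenomicInterval("c", 0, 10), GenomicInterval("c", 10, 25)]
        with pytest.raises(ValueError, match="uniform"):
            ContactMatrix(bins=bins, matrix=np.eye(2))

    def test_write_parse_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        m = rng.random((4, 4))
        m = (m + m.T) / 2
        bins = [GenomicInterval("c", i * 100, (i + 1) * 100) for i in range(4)]
        cm = ContactMatrix(bins=bins, matrix=m)
        write_contact_matrix(cm, tmp_path / "m.tsv", tmp_path / "b.bed")
        back = parse_contact_matrix(tmp_path / "m.tsv", tmp_path / "b.bed")
        np.testing.assert_allclose(back.matrix, m, rtol=1e-9)
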