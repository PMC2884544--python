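"""Domain types, FASTA/AGP/SAM round trips and coordinate conventions."""

import string

import pytest
from hypothesis import given, settings, strategies as st

from gapmend.core import Alignment, Contig, Scaffold, gaps_from_scaffolds, normalize_seq, revcomp
from gapmend.seqio import (
    FormatError,
    load_assembly,
    read_agp,
    read_fasta,
    write_agp,
    write_fasta,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


@given(dna)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_revcomp_is_involution(seq):
    assert revcomp(revcomp(seq)) == seq


def test_normalize_seq_lowercase_and_ambiguity():
    seq, changed = normalize_seq("acgtRYn")
    assert seq == "ACGTNNN"
    assert changed == 2  # R and Y; case changes not counted
    with pytest.raises(ValueError):
        normalize_seq("ACGT!")


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGT\n")
        assert read_fasta(p) == [("a", "ACGT")]

    def test_wrapped_record_concatenates(self, tmp_path):
        seq = "ACGTT" * 30  # 150 bp
        p = tmp_path / "w.fa"
        p.write_text(">w\n" + "\n".join(seq[i : i + 60] for i in range(0, 150, 60)) + "\n")
        assert read_fasta(p) == [("w", seq)]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.fa"
        p.write_text("")
        assert read_fasta(p) == []

    def test_write_exact_bytes_and_wrap_boundary(self, tmp_path):
        p = tmp_path / "o.fa"
        write_fasta([("a", "ACGT")], p)
        assert p.read_text() == ">a\nACGT\n"
        write_fasta([("b", "A" * 61)], p)
        assert p.read_text() == ">b\n" + "A" * 60 + "\nA\n"

    def test_duplicate_id_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate"):
            write_fasta([("a", "AC"), ("a", "GT")], tmp_path / "d.fa")

    def test_bad_character_names_record(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">ok\nACGT\n>bad\nAC-T\n")
        with pytest.raises(FormatError, match="record 2"):
            read_fasta(p)

    @given(
        st.lists(
            st.tuples(st.integers(0, 10 ** 6), st.text(alphabet="ACGT", min_size=1, max_size=130)),
            min_size=0,
            max_size=20,
            unique_by=lambda t: t[0],
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip(self, tmp_path_factory, records):
        recs = [(f"r{i}", seq) for i, seq in records]
        p = tmp_path_factory.mktemp("fa") / "rt.fa"
        write_fasta(recs, p)
        assert read_fasta(p) == recs


AGP_EXAMPLE = (
    "s1\t1\t30\t1\tW\tc1\t1\t30\t+\n"
    "s1\t31\t40\t2\tN\t10\tscaffold\tyes\tpaired-ends\n"
    "s1\t41\t70\t3\tW\tc2\t1\t30\t+\n"
)


class TestAgp:
    def test_direct_field_mapping(self, tmp_path):
        p = tmp_path / "a.agp"
        p.write_text(AGP_EXAMPLE)
        (sc,) = read_agp(p)
        assert sc.id == "s1"
        assert sc.contig_ids == ["c1", "c2"]
        assert sc.gap_estimates == [10]

    def test_minus_orientation_and_u_gap(self, tmp_path):
        p = tmp_path / "b.agp"
        p.write_text(
            "s1\t1\t30\t1\tW\tc1\t1\t30\t-\n"
            "s1\t31\t130\t2\tU\t100\tscaffold\tno\tna\n"
            "s1\t131\t160\t3\tW\tc2\t1\t30\t+\n"
        )
        (sc,) = read_agp(p)
        assert sc.orientations == ["-", "+"]
        assert sc.gap_estimates == [100]

    def test_two_scaffolds_grouped(self, tmp_path):
        p = tmp_path / "c.agp"
        p.write_text(AGP_EXAMPLE + "s2\t1\t30\t1\tW\tc3\t1\t30\t+\n")
        scs = read_agp(p)
        assert [s.id for s in scs] == ["s1", "s2"]
        assert scs[1].contig_ids == ["c3"]

    def test_non_monotone_coordinates_rejected(self, tmp_path):
        p = tmp_path / "bad.agp"
        p.write_text("s1\t1\t30\t1\tW\tc1\t1\t30\t+\ns1\t20\t40\t2\tN\t10\tscaffold\tyes\tna\n")
        with pytest.raises(FormatError, match="monotone"):
            read_agp(p)

    def test_assembly_round_trip_with_minus_strand(self, tmp_path):
        from gapmend.core import Assembly

        seq_c1 = "ACGTACGTACGTACGTACGTACGTACGTAC"
        fa = tmp_path / "c.fa"
        fa.write_text(f">c1\n{seq_c1}\n>c2\n{'A' * 30}\n")
        agp = tmp_path / "c.agp"
        agp.write_text(
            "s1\t1\t30\t1\tW\tc1\t1\t30\t-\n"
            "s1\t31\t40\t2\tN\t10\tscaffold\tyes\tpaired-ends\n"
            "s1\t41\t70\t3\tW\tc2\t1\t30\t+\n"
        )
        asm, gaps = load_assembly(fa, agp)
        # minus-strand contigs enter scaffold-forward
        assert asm.contigs["c1"].sequence == revcomp(seq_c1)
        assert len(gaps) == 1 and gaps[0].estimated_length == 10
        out = tmp_path / "out.agp"
        write_agp(asm, gaps, out)
        (sc,) = read_agp(out)
        assert sc.contig_ids == ["c1", "c2"] and sc.gap_estimates == [10]


class TestSam:
    def _write(self, tmp_path, body):
        p = tmp_path / "t.sam"
        p.write_text("@HD\tVN:1.6\n@SQ\tSN:c1\tLN:100\n" + body)
        return p

    def _assembly(self):
        from gapmend.core import Assembly

        asm = Assembly()
        asm.add_contig(Contig("c1", "A" * 100))
        return asm

    def test_pos_conversion(self, tmp_path):
        from gapmend.seqio import parse_sam

        p = self._write(tmp_path, "r1\t0\tc1\t1\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n")
        alns, unmapped = parse_sam(p, self._assembly())
        (a,) = alns
        assert (a.start, a.end) == (0, 10)
        assert a.is_unique and a.strand == "+"
        assert unmapped == set()

    def test_cigar_reference_span(self, tmp_path):
        from gapmend.seqio import parse_sam

        # 5M2I5M consumes 5 + 5 = 10 reference bases (I consumes none)
        p = self._write(tmp_path, "r1\t0\tc1\t4\t60\t5M2I5M\t*\t0\t0\tAAAAAAAAAAAA\t*\n")
        (a,), _ = parse_sam(p, self._assembly())
        assert (a.start, a.end) == (3, 13)

    def test_unmapped_flag(self, tmp_path):
        from gapmend.seqio import parse_sam

        p = self._write(tmp_path, "r1\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\t*\n")
        alns, unmapped = parse_sam(p, self._assembly())
        assert alns == [] and unmapped == {"r1"}

    def test_mapq_zero_not_unique(self, tmp_path):
        from gapmend.seqio import parse_sam

        p = self._write(tmp_path, "r1\t0\tc1\t1\t0\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n")
        (a,), _ = parse_sam(p, self._assembly())
        assert not a.is_unique

    def test_unknown_reference_rejected(self, tmp_path):
        from gapmend.seqio import parse_sam
        from gapmend.core import Assembly

        p = self._write(tmp_path, "r1\t0\tc1\t1\t60\t10M\t*\t0\t0\tAAAAAAAAAA\t*\n")
        asm = Assembly()
        asm.add_contig(Contig("other", "A" * 100))
        with pytest.raises(Exception, match="c1"):
            parse_sam(p, asm)


def test_gap_objects_from_scaffolds():
    sc = Scaffold("s1", ["a", "b", "c"], [50, 70])
    gaps = gaps_from_scaffolds([sc])
    assert [(g.left_contig_id, g.right_contig_id, g.estimated_length) for g in gaps] == [
        ("a", "b", 50),
        ("b", "c", 70),
    ]
    gaps[0].close()
    with pytest.raises(ValueError):
        gaps[0].close()


def test_alignment_interval_validation():
    with pytest.raises(ValueError):
        Alignment("r", "c", 5, 5, "+")
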