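"""Local-contig placement, gap closure, extension, overhang trimming and
negative-gap joins."""

import pytest

from gapmend.core import Assembly, Contig, Gap, Scaffold, revcomp
from gapmend.dbg import LocalContig
from gapmend.merge import (
    GapOutcome,
    apply_outcomes,
    place_local_contig,
    resolve_gap,
)
from gapmend.simulate import random_genome


def lc(seq, gap_id="g1", cov=10.0):
    return LocalContig(gap_id=gap_id, id="lc1", sequence=seq, mean_kmer_coverage=cov, k_used=21)


class TestPlaceLocalContig:
    def test_exact_end_overlap(self):
        flank = random_genome(200, seed=1)
        contig = flank[-30:] + random_genome(40, seed=2)  # Y,Z = two 15 bp blocks
        (pl,) = place_local_contig(contig, flank, None)
        assert pl.flank == "left" and pl.orientation == "+"
        assert pl.overlap_len == 30 and pl.identity == 1.0
        assert pl.flank_overhang == 0
        assert pl.protrusion == 40

    def test_contained_contig_no_protrusion(self):
        flank = random_genome(200, seed=3)
        contig = flank[50:120]  # inside the flank, no new sequence
        (pl,) = place_local_contig(contig, flank, None)
        assert pl.protrusion == 0 and pl.spans_flank_edge is False

    def test_flank_overhang_measured(self):
        flank = random_genome(200, seed=4)
        good = flank[:-8]  # flank's last 8 bases are junk
        contig = good[-40:] + random_genome(30, seed=5)
        (pl,) = place_local_contig(contig, flank, None)
        assert pl.flank_overhang == 8
        assert pl.protrusion == 30

    def test_reverse_orientation_detected(self):
        flank = random_genome(200, seed=6)
        contig = revcomp(flank[-30:] + random_genome(40, seed=7))
        (pl,) = place_local_contig(contig, flank, None)
        assert pl.orientation == "-" and pl.overlap_len == 30

    def test_below_thresholds_discarded(self):
        flank = random_genome(200, seed=8)
        contig = flank[-10:] + random_genome(40, seed=9)  # 10 bp < min_overlap
        assert place_local_contig(contig, flank, None) == []


def _gap():
    return Gap("g1", "s1", "L", "R", 100)


class TestResolveGap:
    def test_spanning_contig_closes(self):
        left = random_genome(300, seed=10)
        right = random_genome(300, seed=11)
        novel = random_genome(50, seed=12)
        span = left[-25:] + novel + right[:25]
        out = resolve_gap(_gap(), left, right, [lc(span)])
        assert out.action == "closed"
        assert out.inserted_sequence == novel
        assert out.closed_length == 50

    def test_one_sided_contig_extends(self):
        left = random_genome(300, seed=13)
        right = random_genome(300, seed=14)
        novel = random_genome(40, seed=15)
        out = resolve_gap(_gap(), left, right, [lc(left[-30:] + novel)])
        assert out.action == "extended_left"
        seq, a, h = out.left_ext
        assert seq[a:] == novel and h == 0

    def test_no_placement_unchanged(self):
        out = resolve_gap(_gap(), random_genome(300, seed=16), random_genome(300, seed=17),
                          [lc(random_genome(80, seed=18))])
        assert out.action == "unchanged"

    def test_negative_gap_join(self):
        """Flanks that truly overlap: join with negative closed length."""
        left = random_genome(300, seed=19)
        shared = left[-40:]
        right = shared + random_genome(260, seed=20)
        span = left[-80:] + random_genome(0, seed=1) + right[40:70]  # spans both flanks
        out = resolve_gap(_gap(), left, right, [lc(span)])
        assert out.action == "closed"
        assert out.closed_length == -40
        assert out.inserted_sequence == ""


class TestApplyOutcomes:
    def _assembly(self, left, right, est=100):
        asm = Assembly()
        asm.add_contig(Contig("L", left, "s1", 0))
        asm.add_contig(Contig("R", right, "s1", 1))
        asm.scaffolds = [Scaffold("s1", ["L", "R"], [est])]
        return asm, [Gap("s1.g1", "s1", "L", "R", est)]

    def test_closure_bookkeeping_and_byte_exact_merge(self):
        left = random_genome(400, seed=21)
        right = random_genome(400, seed=22)
        novel = random_genome(60, seed=23)
        asm, gaps = self._assembly(left, right)
        out = resolve_gap(gaps[0], left, right, [lc(left[-30:] + novel + right[:30])])
        apply_outcomes(asm, gaps, {gaps[0].gap_id: out})
        assert list(asm.contigs) == ["L"]
        assert asm.contigs["L"].sequence == left + novel + right
        assert asm.scaffolds[0].contig_ids == ["L"] and asm.scaffolds[0].gap_estimates == []
        assert gaps[0].status == "closed" and gaps[0].total_fill == novel

    def test_extension_reduces_estimated_length(self):
        left = random_genome(400, seed=24)
        right = random_genome(400, seed=25)
        novel = random_genome(40, seed=26)
        asm, gaps = self._assembly(left, right, est=1000)
        out = resolve_gap(gaps[0], left, right, [lc(left[-30:] + novel)])
        apply_outcomes(asm, gaps, {gaps[0].gap_id: out})
        assert asm.contigs["L"].sequence == left + novel
        assert gaps[0].estimated_length == 960
        assert asm.scaffolds[0].gap_estimates == [960]

    def test_no_outcomes_is_identity(self):
        left = random_genome(200, seed=27)
        right = random_genome(200, seed=28)
        asm, gaps = self._assembly(left, right)
        apply_outcomes(asm, gaps, {})
        assert asm.contigs["L"].sequence == left
        assert asm.contigs["R"].sequence == right

    def test_overhang_trim_conserves_flank_minus_trim(self):
        """Trimmed closure: flanks minus the junk appear verbatim, and the
        length audit closed_length == merged - (|L| + |R|) holds."""
        left_good = random_genome(400, seed=29)
        right = random_genome(400, seed=31)
        novel = random_genome(50, seed=32)
        # 6 junk bases at the flank end, each differing from the true fill
        junk = "".join("A" if c != "A" else "C" for c in novel[:6])
        left = left_good + junk
        asm, gaps = self._assembly(left, right)
        span = left_good[-30:] + novel + right[:30]
        out = resolve_gap(gaps[0], left, right, [lc(span)])
        assert out.action == "closed" and out.trim_left == 6
        assert out.closed_length == 50 - 6
        apply_outcomes(asm, gaps, {gaps[0].gap_id: out})
        merged = asm.contigs["L"].sequence
        assert merged == left_good + novel + right
        assert len(merged) - (len(left) + len(right)) == out.closed_length

    def test_chained_closures_in_one_scaffold(self):
        g = random_genome(1200, seed=33)
        c1, gap1, c2, gap2, c3 = g[:300], g[300:350], g[350:650], g[650:700], g[700:]
        asm = Assembly()
        for i, (cid, seq) in enumerate([("c1", c1), ("c2", c2), ("c3", c3)]):
            asm.add_contig(Contig(cid, seq, "s1", i))
        asm.scaffolds = [Scaffold("s1", ["c1", "c2", "c3"], [50, 50])]
        gaps = [Gap("s1.g1", "s1", "c1", "c2", 50), Gap("s1.g2", "s1", "c2", "c3", 50)]
        o1 = resolve_gap(gaps[0], c1, c2, [lc(c1[-25:] + gap1 + c2[:25])])
        o2 = resolve_gap(gaps[1], c2, c3, [lc(c2[-25:] + gap2 + c3[:25])])
        apply_outcomes(asm, gaps, {g_.gap_id: o for g_, o in zip(gaps, (o1, o2))})
        assert list(asm.contigs) == ["c1"]
        assert asm.contigs["c1"].sequence == g
        assert all(x.status == "closed" for x in gaps)
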