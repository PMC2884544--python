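"""Per-gap read pools: end-anchored reads plus rescued unmapped mates.

A read is *anchored* to a contig end when its unique alignment lies within
``window`` bases of that end and its strand points into the adjacent gap
(forward for a right end, reverse for a left end). The unmapped mate of an
anchored read presumably sits inside the gap and is *rescued* into the same
pool. Scaffold adjacency then unions the right-end pool of contig i with
the left-end pool of contig i+1 into one pool per intra-scaffold gap.

Pool sequences are orientation-normalized to scaffold-forward strand:
reverse-strand anchors and the mates of forward-strand anchors are reverse
complemented. Anchored reads contribute their full sequence, not the
clipped alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .core import Assembly, Contig, Gap, ReadPair, revcomp
from .mapping import PairPlacement

DEFAULT_WINDOW = 600

LEFT_ANCHOR = "left_anchor"
RIGHT_ANCHOR = "right_anchor"
RESCUED = "rescued_mate"


@dataclass
class PoolRead:
    read_id: str
    seq: str
    provenance: str  # left_anchor | right_anchor | rescued_mate


@dataclass
class GapPool:
    gap_id: str
    reads: list[PoolRead] = field(default_factory=list)

    @property
    def n_left(self) -> int:
        return sum(1 for r in self.reads if r.provenance == LEFT_ANCHOR)

    @property
    def n_right(self) -> int:
        return sum(1 for r in self.reads if r.provenance == RIGHT_ANCHOR)

    @property
    def n_rescued(self) -> int:
        return sum(1 for r in self.reads if r.provenance == RESCUED)

    def sequences(self) -> list[str]:
        return [r.seq for r in self.reads]


@dataclass
class _Anchor:
    fragment_id: str
    mate: int  # 1 or 2
    read_id: str
    mate_unmapped: bool


def find_end_anchored(
    placements: Sequence[PairPlacement],
    contigs: dict[str, Contig],
    window: int = DEFAULT_WINDOW,
    orient_filter: bool = True,
) -> dict[tuple[str, str], list[_Anchor]]:
    """Anchored reads per contig end, keyed by ``(contig_id, 'L'|'R')``.

    Right end: unique alignment ends within ``window`` of the contig's 3'
    end on the forward strand. Left end: starts within ``window`` of the 5'
    end on the reverse strand. With ``orient_filter`` off, strand is
    ignored (both strands anchor at both ends).
    """
    anchored: dict[tuple[str, str], list[_Anchor]] = {}
    for pl in placements:
        for mate, aln in ((1, pl.placement1), (2, pl.placement2)):
            if aln is None:
                continue
            clen = len(contigs[aln.contig_id])
            mate_unmapped = pl.category == "one_unique_mate_unmapped"
            anchor = _Anchor(pl.fragment_id, mate, f"{pl.fragment_id}/{mate}", mate_unmapped)
            to_right = aln.end > clen - window and (aln.strand == "+" or not orient_filter)
            to_left = aln.start < window and (aln.strand == "-" or not orient_filter)
            if to_right:
                anchored.setdefault((aln.contig_id, "R"), []).append(anchor)
            if to_left:
                anchored.setdefault((aln.contig_id, "L"), []).append(anchor)
    return anchored


def collect_pool(
    gap: Gap,
    anchored: dict[tuple[str, str], list[_Anchor]],
    pairs_by_id: dict[str, ReadPair],
) -> GapPool:
    """Union of the gap-facing end pools of both flanks plus rescued mates.

    Sequences are normalized to scaffold-forward orientation; a read enters
    a pool at most once (dedup by read id).
    """
    pool = GapPool(gap.gap_id)
    seen: set[str] = set()

    def add(read_id: str, seq: str, provenance: str) -> None:
        if read_id not in seen and seq:
            seen.add(read_id)
            pool.reads.append(PoolRead(read_id, seq, provenance))

    def mate_seq(pair: ReadPair, mate: int) -> str:
        return pair.seq1 if mate == 1 else pair.seq2

    # left flank: anchors at the left contig's right end, forward strand.
    for a in anchored.get((gap.left_contig_id, "R"), []):
        pair = pairs_by_id[a.fragment_id]
        add(a.read_id, mate_seq(pair, a.mate), LEFT_ANCHOR)
        if a.mate_unmapped:
            other = 2 if a.mate == 1 else 1
            # FR geometry: the mate reads back toward the anchor, so its
            # stored sequence is reverse complement of scaffold-forward.
            add(f"{a.fragment_id}/{other}", revcomp(mate_seq(pair, other)), RESCUED)

    # right flank: anchors at the right contig's left end, reverse strand.
    for a in anchored.get((gap.right_contig_id, "L"), []):
        pair = pairs_by_id[a.fragment_id]
        add(a.read_id, revcomp(mate_seq(pair, a.mate)), RIGHT_ANCHOR)
        if a.mate_unmapped:
            other = 2 if a.mate == 1 else 1
            add(f"{a.fragment_id}/{other}", mate_seq(pair, other), RESCUED)

    return pool


def merge_pools_by_gap(
    gaps: Sequence[Gap],
    anchored: dict[tuple[str, str], list[_Anchor]],
    pairs: Sequence[ReadPair],
) -> dict[str, GapPool]:
    """One pool per open intra-scaffold gap; scaffold-boundary ends pool nothing."""
    pairs_by_id = {p.fragment_id: p for p in pairs}
    return {
        g.gap_id: collect_pool(g, anchored, pairs_by_id)
        for g in gaps
        if g.status == "open"
    }


def write_pool_fasta(pool: GapPool, path) -> None:
    from .seqio import write_fasta

    write_fasta([(f"{r.read_id}|{r.provenance}", r.seq) for r in pool.reads], path)
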