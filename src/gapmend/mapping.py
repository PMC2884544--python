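"""Unique-placement read mapping.

The internal mapper is a seed-and-extend aligner specialised for short
reads: exact k-mer seeds vote for candidate diagonals, each candidate is
scored by ungapped extension (match +1, mismatch -1, strand-aware), and a
placement is *unique* only when the best score beats the runner-up by a
margin. This realises the "unambiguously mapped" contract; reads needing
gapped alignment are expected to arrive via SAM from an external aligner
(see :func:`placements_from_sam`), which is fully interchangeable with the
internal mapper.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from typing import Optional, Sequence

import pysam

from .core import Alignment, Assembly, Contig, ReadPair, revcomp

logger = logging.getLogger("gapmend")

DEFAULT_SEED_K = 13
DEFAULT_REPEAT_CAP = 1000
DEFAULT_MIN_IDENTITY = 0.9
DEFAULT_MIN_READ_FRACTION = 0.9
DEFAULT_UNIQUE_MARGIN = 5


@dataclass
class PairPlacement:
    """Joint placement of a read pair on the assembly.

    ``placement1``/``placement2`` hold the unique alignment of each mate, or
    None. Categories:

    - ``both_unique``: both mates place uniquely.
    - ``one_unique_mate_unmapped``: one mate unique, the other has no
      acceptable placement anywhere — the classic rescue signal that the
      mate lies inside a gap.
    - ``one_unique_mate_elsewhere``: one mate unique, the other aligns but
      ambiguously.
    - ``ambiguous``: alignments exist but none unique.
    - ``unmapped``: neither mate aligns at all.
    """

    fragment_id: str
    placement1: Optional[Alignment]
    placement2: Optional[Alignment]
    category: str


class KmerIndex:
    """Exact k-mer positions over all contigs of an assembly.

    Contigs are concatenated with ``#`` spacers so one dict serves the whole
    assembly; k-mers occurring more than ``repeat_cap`` times are masked
    (logged) to bound candidate fan-out on hyper-repetitive seeds.
    """

    def __init__(
        self,
        contigs: Sequence[Contig],
        seed_k: int = DEFAULT_SEED_K,
        repeat_cap: int = DEFAULT_REPEAT_CAP,
    ):
        self.seed_k = seed_k
        self.contig_ids: list[str] = []
        self.offsets: list[int] = []  # global start of each contig
        parts: list[str] = []
        pos = 0
        for c in contigs:
            if len(c) < seed_k:
                logger.warning("contig %s shorter than seed_k=%d; skipped", c.id, seed_k)
                continue
            self.contig_ids.append(c.id)
            self.offsets.append(pos)
            parts.append(c.sequence)
            pos += len(c) + seed_k
            parts.append("#" * seed_k)
        self.seq = "".join(parts)
        self._lens = {c.id: len(c) for c in contigs if len(c) >= seed_k}

        index: dict[str, list[int]] = {}
        k = seed_k
        seq = self.seq
        for coff, cid in zip(self.offsets, self.contig_ids):
            clen = self._lens[cid]
            for i in range(coff, coff + clen - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append(i)
        masked = [km for km, hits in index.items() if len(hits) > repeat_cap]
        for km in masked:
            del index[km]
        if masked:
            logger.info("masked %d seeds above repeat cap %d", len(masked), repeat_cap)
        self.index = index

    def locate(self, kmer: str) -> list[int]:
        return self.index.get(kmer, [])

    def contig_at(self, gpos: int) -> tuple[str, int, int]:
        """(contig_id, global_start, length) of the contig containing gpos."""
        i = bisect_right(self.offsets, gpos) - 1
        cid = self.contig_ids[i]
        return cid, self.offsets[i], self._lens[cid]


def build_index(
    contigs: Sequence[Contig] | Assembly,
    seed_k: int = DEFAULT_SEED_K,
    repeat_cap: int = DEFAULT_REPEAT_CAP,
) -> KmerIndex:
    if isinstance(contigs, Assembly):
        contigs = list(contigs.contigs.values())
    return KmerIndex(contigs, seed_k=seed_k, repeat_cap=repeat_cap)


def map_read(
    read: str,
    index: KmerIndex,
    read_id: str = "read",
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_read_fraction: float = DEFAULT_MIN_READ_FRACTION,
    unique_margin: int = DEFAULT_UNIQUE_MARGIN,
) -> tuple[list[Alignment], bool]:
    """Align one read against the index; returns (alignments, is_unique).

    Alignments are ungapped, clipped at contig boundaries, and reported when
    they cover >= ``min_read_fraction`` of the read at >= ``min_identity``.
    ``is_unique`` is True when a single candidate exists or the best score
    exceeds the runner-up by ``unique_margin``.
    """
    k = index.seed_k
    rl = len(read)
    if rl < k:
        return [], False
    seq = index.seq
    rc = revcomp(read)
    seed_offsets = (0, (rl - k) // 2, rl - k)
    offsets = index.offsets
    candidates: set[tuple[int, str, int]] = set()
    for query, strand in ((read, "+"), (rc, "-")):
        for off in seed_offsets:
            for p in index.locate(query[off : off + k]):
                # resolve the contig from the seed hit itself (always inside one)
                ci = bisect_right(offsets, p) - 1
                candidates.add((p - off, strand, ci))
    if not candidates:
        return [], False

    min_span = min_read_fraction * rl
    scored: list[tuple[int, Alignment]] = []
    for gstart, strand, ci in candidates:
        query = read if strand == "+" else rc
        cid = index.contig_ids[ci]
        coff = offsets[ci]
        clen = index._lens[cid]
        span_start = max(gstart, coff)
        span_end = min(gstart + rl, coff + clen)
        span = span_end - span_start
        if span < min_span:
            continue
        qsub = query[span_start - gstart : span_end - gstart]
        tsub = seq[span_start:span_end]
        if qsub == tsub:
            mm = 0
        else:
            mm = sum(1 for a, b in zip(qsub, tsub) if a != b)
            if (span - mm) / span < min_identity:
                continue
        score = span - 2 * mm
        scored.append(
            (
                score,
                Alignment(
                    read_id=read_id,
                    contig_id=cid,
                    start=span_start - coff,
                    end=span_end - coff,
                    strand=strand,
                    mismatches=mm,
                    score=score,
                ),
            )
        )
    if not scored:
        return [], False
    scored.sort(key=lambda t: (-t[0], t[1].contig_id, t[1].start, t[1].strand))
    is_unique = len(scored) == 1 or scored[0][0] - scored[1][0] >= unique_margin
    alns = [a for _, a in scored]
    alns[0].is_unique = is_unique
    return alns, is_unique


def _categorize(
    fragment_id: str,
    u1: Optional[Alignment],
    hit1: bool,
    u2: Optional[Alignment],
    hit2: bool,
) -> PairPlacement:
    if u1 and u2:
        cat = "both_unique"
    elif u1 or u2:
        other_hit = hit2 if u1 else hit1
        cat = "one_unique_mate_elsewhere" if other_hit else "one_unique_mate_unmapped"
    elif hit1 or hit2:
        cat = "ambiguous"
    else:
        cat = "unmapped"
    return PairPlacement(fragment_id, u1, u2, cat)


def place_pairs(
    pairs: Sequence[ReadPair],
    index: KmerIndex,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_read_fraction: float = DEFAULT_MIN_READ_FRACTION,
    unique_margin: int = DEFAULT_UNIQUE_MARGIN,
) -> list[PairPlacement]:
    """Map both mates of every pair and assign a joint category."""
    out: list[PairPlacement] = []
    kwargs = dict(
        min_identity=min_identity,
        min_read_fraction=min_read_fraction,
        unique_margin=unique_margin,
    )
    for pair in pairs:
        a1, uq1 = map_read(pair.seq1, index, read_id=pair.fragment_id + "/1", **kwargs)
        a2, uq2 = map_read(pair.seq2, index, read_id=pair.fragment_id + "/2", **kwargs)
        out.append(
            _categorize(
                pair.fragment_id,
                a1[0] if uq1 else None,
                bool(a1),
                a2[0] if uq2 else None,
                bool(a2),
            )
        )
    counts: dict[str, int] = {}
    for p in out:
        counts[p.category] = counts.get(p.category, 0) + 1
    logger.info("pair categories: %s", counts)
    return out


def placements_from_sam(path, assembly: Assembly) -> tuple[list[ReadPair], list[PairPlacement]]:
    """Rebuild read pairs and pair placements from a SAM file.

    The SAM source is interchangeable with the internal mapper: primary
    records with MAPQ > 0 count as unique, MAPQ 0 or secondary as ambiguous,
    flag 0x4 as unmapped. Mate sequences are recovered in original read
    orientation (reverse-strand SEQ fields are reverse complemented back).
    """
    seqs: dict[str, dict[int, str]] = {}
    best: dict[str, dict[int, Optional[Alignment]]] = {}
    hits: dict[str, dict[int, bool]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            qname = rec.query_name
            mate = 2 if rec.is_read2 else 1
            if qname not in seqs:
                seqs[qname] = {}
                best[qname] = {1: None, 2: None}
                hits[qname] = {1: False, 2: False}
                order.append(qname)
            if rec.query_sequence and not rec.is_secondary:
                s = rec.query_sequence
                seqs[qname][mate] = revcomp(s) if rec.is_reverse else s
            if rec.is_unmapped:
                continue
            if rec.reference_name not in assembly.contigs:
                raise ValueError(f"{path}: reference {rec.reference_name!r} not in assembly")
            hits[qname][mate] = True
            if not rec.is_secondary and rec.mapping_quality > 0:
                best[qname][mate] = Alignment(
                    read_id=f"{qname}/{mate}",
                    contig_id=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                    is_unique=True,
                )
    pairs = []
    placements = []
    for qname in order:
        s1 = seqs[qname].get(1, "")
        s2 = seqs[qname].get(2, "")
        pairs.append(ReadPair(fragment_id=qname, seq1=s1, seq2=s2))
        placements.append(
            _categorize(qname, best[qname][1], hits[qname][1], best[qname][2], hits[qname][2])
        )
    return pairs, placements
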