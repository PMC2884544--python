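"""Readers and writers for FASTA, FASTQ, AGP 2.0 and SAM.

All coordinate conversion between external 1-based inclusive conventions
(AGP, SAM) and the internal 0-based half-open convention happens here and
nowhere else. Writers are deterministic: the same objects always produce
byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO

from .core import Alignment, Assembly, Contig, Gap, ReadPair, Scaffold, normalize_seq, revcomp

logger = logging.getLogger("gapmend")


class FormatError(ValueError):
    """A malformed input file."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)`` pairs in file order.

    Sequences are uppercased; non-ACGTN IUPAC ambiguity codes collapse to N
    (count logged); any other character raises :class:`FormatError` naming
    the record.
    """
    out: list[tuple[str, str]] = []
    n_converted = 0
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise FormatError(f"{path}: record {i} has an empty header")
        try:
            seq, changed = normalize_seq(str(rec.seq))
        except ValueError as exc:
            raise FormatError(f"{path}: record {i} ({rec.id!r}): {exc}") from exc
        n_converted += changed
        out.append((rec.id, seq))
    if n_converted:
        logger.info("read_fasta(%s): %d ambiguity codes converted to N", path, n_converted)
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, wrap: int = 60) -> None:
    """Write ``(id, sequence)`` records, wrapping sequence lines at ``wrap``."""
    seen: set[str] = set()
    with open(path, "w") as fh:
        for rid, seq in records:
            if rid in seen:
                raise ValueError(f"duplicate record id {rid!r}")
            seen.add(rid)
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def _strip_mate_suffix(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Pair mates positionally: record i of file 1 with record i of file 2.

    Mate-suffixed ids (``/1``, ``/2``) are tolerated; when both names carry
    suffixes the stripped stems must agree.
    """
    recs1 = list(SeqIO.parse(str(path1), "fastq"))
    recs2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(recs1) != len(recs2):
        raise FormatError(
            f"mate files differ in record count: {len(recs1)} vs {len(recs2)}"
        )
    pairs = []
    for r1, r2 in zip(recs1, recs2):
        stem1, stem2 = _strip_mate_suffix(r1.id), _strip_mate_suffix(r2.id)
        if stem1 != stem2:
            raise FormatError(f"mate ids disagree at record {r1.id!r} / {r2.id!r}")
        s1, _ = normalize_seq(str(r1.seq))
        s2, _ = normalize_seq(str(r2.seq))
        pairs.append(ReadPair(fragment_id=stem1, seq1=s1, seq2=s2))
    return pairs


def write_fastq_pairs(pairs: Sequence[ReadPair], path1: str | Path, path2: str | Path) -> None:
    """Write mates to two FASTQ files (constant Sanger quality 'I')."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.fragment_id}/1\n{p.seq1}\n+\n{'I' * len(p.seq1)}\n")
            f2.write(f"@{p.fragment_id}/2\n{p.seq2}\n+\n{'I' * len(p.seq2)}\n")


# ---------------------------------------------------------------------------
# AGP 2.0
# ---------------------------------------------------------------------------

def read_agp(path: str | Path) -> list[Scaffold]:
    """Parse an AGP v2.0 file into Scaffold records.

    Component type W contributes a contig; N/U contribute a gap estimate
    (U's conventional length is 100). 1-based inclusive object coordinates
    are checked for monotonicity and then discarded (the layout is fully
    determined by component order and lengths).
    """
    scaffolds: list[Scaffold] = []
    cur_id: str | None = None
    cur_contigs: list[str] = []
    cur_gaps: list[int] = []
    cur_orients: list[str] = []
    last_end = 0
    pending_gap: int | None = None

    def flush() -> None:
        nonlocal cur_contigs, cur_gaps, cur_orients, pending_gap
        if cur_id is not None:
            if pending_gap is not None:
                logger.warning("AGP %s: scaffold %s ends with a gap; dropped", path, cur_id)
            scaffolds.append(Scaffold(cur_id, cur_contigs, cur_gaps, cur_orients))
        cur_contigs, cur_gaps, cur_orients = [], [], []
        pending_gap = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}:{lineno}: expected >=8 AGP columns")
            obj, obj_beg, obj_end, _part, ctype = fields[:5]
            beg, end = int(obj_beg), int(obj_end)
            if obj != cur_id:
                flush()
                cur_id = obj
                last_end = 0
            if beg != last_end + 1 or end < beg:
                raise FormatError(
                    f"{path}:{lineno}: non-monotone object coordinates "
                    f"({beg}-{end} after {last_end})"
                )
            last_end = end
            if ctype == "W":
                if cur_contigs and pending_gap is None:
                    # abutting components: AGP allows it; treat as a zero gap
                    cur_gaps.append(0)
                elif pending_gap is not None:
                    cur_gaps.append(pending_gap)
                    pending_gap = None
                comp_id, _cbeg, _cend, orient = fields[5:9]
                cur_contigs.append(comp_id)
                cur_orients.append(orient if orient in "+-" else "+")
            elif ctype in ("N", "U"):
                if pending_gap is not None:
                    raise FormatError(f"{path}:{lineno}: two consecutive gap lines")
                pending_gap = 100 if ctype == "U" else int(fields[5])
            else:
                raise FormatError(f"{path}:{lineno}: unsupported component type {ctype!r}")
    flush()
    return scaffolds


def write_agp(assembly: Assembly, gaps: Sequence[Gap], path: str | Path) -> None:
    """Write scaffolds as AGP v2.0 (W lines for contigs, N lines for gaps)."""
    open_by_pair = {(g.left_contig_id, g.right_contig_id): g for g in gaps}
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for sc in assembly.scaffolds:
            pos = 1
            part = 1
            for i, cid in enumerate(sc.contig_ids):
                contig = assembly.contigs[cid]
                clen = len(contig)
                fh.write(
                    f"{sc.id}\t{pos}\t{pos + clen - 1}\t{part}\tW\t{cid}\t1\t{clen}\t{contig.orientation}\n"
                )
                pos += clen
                part += 1
                if i < len(sc.contig_ids) - 1:
                    gap = open_by_pair.get((cid, sc.contig_ids[i + 1]))
                    glen = max(1, gap.estimated_length if gap else sc.gap_estimates[i])
                    fh.write(
                        f"{sc.id}\t{pos}\t{pos + glen - 1}\t{part}\tN\t{glen}\tscaffold\tyes\tpaired-ends\n"
                    )
                    pos += glen
                    part += 1


def load_assembly(contigs_fasta: str | Path, agp_path: str | Path) -> tuple[Assembly, list[Gap]]:
    """Assemble FASTA contigs and AGP layout into an Assembly plus open gaps.

    Contigs absent from the AGP become singleton scaffolds. '-' oriented
    contigs are reverse complemented on ingest so that all internal work is
    in scaffold-forward orientation.
    """
    from .core import gaps_from_scaffolds

    records = dict(read_fasta(contigs_fasta))
    scaffolds = read_agp(agp_path)
    asm = Assembly()
    placed: set[str] = set()
    for sc in scaffolds:
        orients = sc.orientations or ["+"] * len(sc.contig_ids)
        for idx, cid in enumerate(sc.contig_ids):
            if cid not in records:
                raise FormatError(f"AGP component {cid!r} missing from {contigs_fasta}")
            seq = records[cid]
            if orients[idx] == "-":
                seq = revcomp(seq)
            asm.add_contig(Contig(cid, seq, sc.id, idx, "+"))
            placed.add(cid)
        asm.scaffolds.append(sc)
    for cid, seq in records.items():
        if cid not in placed:
            sc = Scaffold(f"scf_{cid}", [cid], [])
            asm.add_contig(Contig(cid, seq, sc.id, 0, "+"))
            asm.scaffolds.append(sc)
    return asm, gaps_from_scaffolds(asm.scaffolds)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def parse_sam(path: str | Path, assembly: Assembly) -> tuple[list[Alignment], set[str]]:
    """Read a text SAM file into Alignments plus the set of unmapped read ids.

    POS is converted 1-based to 0-based; the reference end comes from the
    CIGAR's reference consumption. MAPQ 0 and secondary records are kept but
    flagged non-unique. Read ids are suffixed ``/1`` / ``/2`` for paired
    records so mates stay distinct.
    """
    alignments: list[Alignment] = []
    unmapped: set[str] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            rid = rec.query_name
            if rec.is_paired:
                rid += "/1" if rec.is_read1 else "/2"
            if rec.is_unmapped:
                unmapped.add(rid)
                continue
            rname = rec.reference_name
            if rname not in assembly.contigs:
                raise FormatError(f"{path}: reference {rname!r} not in assembly")
            alignments.append(
                Alignment(
                    read_id=rid,
                    contig_id=rname,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                    is_unique=not rec.is_secondary and rec.mapping_quality > 0,
                )
            )
    return alignments, unmapped


def write_sam(placements, pairs: Sequence[ReadPair], assembly: Assembly, path: str | Path) -> None:
    """Write pair placements as a text SAM file (one record per mate).

    Unplaced mates get the unmapped flag with their sequence preserved, so a
    SAM file alone carries everything the pipeline needs for mate rescue.
    """
    contig_ids = list(assembly.contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": cid, "LN": len(assembly.contigs[cid])} for cid in contig_ids],
    }
    ref_index = {cid: i for i, cid in enumerate(contig_ids)}
    by_id = {p.fragment_id: p for p in pairs}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for pl in placements:
            pair = by_id[pl.fragment_id]
            for mate, (seq, aln) in enumerate(
                [(pair.seq1, pl.placement1), (pair.seq2, pl.placement2)], start=1
            ):
                rec = pysam.AlignedSegment()
                rec.query_name = pl.fragment_id
                flag = 0x1 | (0x40 if mate == 1 else 0x80)
                if aln is None:
                    flag |= 0x4
                    rec.query_sequence = seq
                else:
                    if aln.strand == "-":
                        flag |= 0x10
                        rec.query_sequence = revcomp(seq)
                    else:
                        rec.query_sequence = seq
                    rec.reference_id = ref_index[aln.contig_id]
                    rec.reference_start = aln.start
                    rec.mapping_quality = 60 if aln.is_unique else 0
                    span = aln.end - aln.start
                    clip = len(seq) - span
                    # internal mapper is ungapped; clip any part off-contig
                    if clip <= 0:
                        rec.cigarstring = f"{span}M"
                    elif aln.start == 0:
                        cig = f"{clip}S{span}M"
                        rec.cigarstring = cig if aln.strand == "+" else f"{span}M{clip}S"
                    else:
                        cig = f"{span}M{clip}S"
                        rec.cigarstring = cig if aln.strand == "+" else f"{clip}S{span}M"
                    rec.set_tag("NM", aln.mismatches)
                rec.flag = flag
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                out.write(rec)
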