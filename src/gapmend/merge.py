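"""Placing local contigs on gap flanks; contig extension, merging and
overhang correction.

Geometry conventions, all in coordinates of the (possibly reverse
complemented) local contig C:

- the *left flank* F_L is the last ``flank_window`` bases of the gap's left
  contig; a valid left placement aligns a prefix region of C over F_L so
  that F_L's 3' end falls inside C at position ``a`` (after trimming up to
  ``max_trim`` junk flank bases — the "overhang"); C[a:] protrudes into the
  gap.
- the *right flank* F_R is the first ``flank_window`` bases of the right
  contig; a valid right placement puts F_R's 5' start at position ``b`` in
  C; C[:b] protrudes into the gap.
- one contig placing on both flanks in one orientation closes the gap:
  insert = C[a:b] when b >= a, or a negative-length join when the flanks
  themselves overlap (b < a).

Trimmed flank bases are *replaced* by C's version, so corrected sequence is
part of the inserted material and original contigs lose at most ``max_trim``
bases per end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import Assembly, Contig, Gap, revcomp
from .dbg import LocalContig

logger = logging.getLogger("gapmend")

DEFAULT_MIN_OVERLAP = 20
DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_MAX_TRIM = 100
DEFAULT_FLANK_WINDOW = 600
_SEED = 11  # exact seed length for overlap diagonal finding


@dataclass
class Placement:
    local_contig_id: str
    flank: str  # left | right
    orientation: str  # + | -
    overlap_len: int
    identity: float
    flank_overhang: int
    c_break: int  # a (left) or b (right): where the kept flank meets C
    protrusion: int  # bases of C protruding into the gap
    spans_flank_edge: bool  # placement reaches the flank's gap-facing edge


@dataclass
class GapOutcome:
    gap_id: str
    action: str  # closed|extended_left|extended_right|extended_both|overhang_corrected|unchanged
    inserted_sequence: str = ""
    closed_length: Optional[int] = None
    # closure parameters: oriented local contig and breakpoints
    span_seq: Optional[str] = None
    a: int = 0
    b: int = 0
    trim_left: int = 0
    trim_right: int = 0
    # extension parameters (seq is the oriented local contig)
    left_ext: Optional[tuple[str, int, int]] = None  # (seq, a, trim)
    right_ext: Optional[tuple[str, int, int]] = None  # (seq, b, trim)
    stats: dict = field(default_factory=dict)


def _diagonals(c_seq: str, f_seq: str) -> list[int]:
    """Candidate alignment diagonals (f_pos - c_pos) from shared exact seeds."""
    if len(f_seq) < _SEED or len(c_seq) < _SEED:
        # tiny sequences: try every diagonal
        return list(range(-len(c_seq) + 1, len(f_seq)))
    fidx: dict[str, list[int]] = {}
    for j in range(len(f_seq) - _SEED + 1):
        fidx.setdefault(f_seq[j : j + _SEED], []).append(j)
    votes: dict[int, int] = {}
    for i in range(len(c_seq) - _SEED + 1):
        for j in fidx.get(c_seq[i : i + _SEED], ()):
            d = j - i
            votes[d] = votes.get(d, 0) + 1
    return [d for d, _ in sorted(votes.items(), key=lambda t: (-t[1], t[0]))[:10]]


def _score_diagonal(
    c_seq: str,
    f_seq: str,
    d: int,
    side: str,
    min_overlap: int,
    min_identity: float,
    max_trim: int,
) -> Optional[Placement]:
    i0 = max(0, -d)
    i1 = min(len(c_seq), len(f_seq) - d)
    if i1 - i0 < 1:
        return None
    matches = [c_seq[i] == f_seq[i + d] for i in range(i0, i1)]
    n = len(matches)

    if side == "left":
        spans_edge = i1 == len(f_seq) - d  # overlap reaches F's 3' end
        h = 0
        if spans_edge:
            # trim to the maximal-scoring prefix (match +1 / mismatch -1):
            # junk flank tails score downhill even with chance matches
            best = score = 0
            p = 0
            for j in range(n):
                score += 1 if matches[j] else -1
                if score > best:
                    best, p = score, j + 1
            h = n - p if best > 0 else n
        if h > max_trim:
            return None
        m = n - h
        if m < min_overlap:
            return None
        ident = sum(matches[:m]) / m
        if ident < min_identity:
            return None
        a = (i1 - h) if spans_edge else len(c_seq)
        protrusion = len(c_seq) - a if spans_edge else 0
        return Placement("", "left", "+", m, ident, h if spans_edge else 0, a, protrusion, spans_edge)

    # right flank
    spans_edge = i0 == -d and d <= 0  # overlap covers F's 5' start
    h = 0
    if spans_edge:
        # maximal-scoring suffix: junk at the flank's 5' start is trimmed
        best = score = 0
        cut = n
        for j in range(n - 1, -1, -1):
            score += 1 if matches[j] else -1
            if score > best:
                best, cut = score, j
        h = cut if best > 0 else n
    if h > max_trim:
        return None
    m = n - h
    if m < min_overlap:
        return None
    ident = sum(matches[h:]) / m
    if ident < min_identity:
        return None
    b = (i0 + h) if spans_edge else 0
    protrusion = b if spans_edge else 0
    return Placement("", "right", "+", m, ident, h if spans_edge else 0, b, protrusion, spans_edge)


def place_local_contig(
    local_contig: LocalContig | str,
    left_flank: Optional[str],
    right_flank: Optional[str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_trim: int = DEFAULT_MAX_TRIM,
) -> list[Placement]:
    """Best placement of the local contig (either orientation) on each flank.

    Returns at most one placement per (flank, orientation); placements below
    ``min_overlap`` matched bases or ``min_identity``, or needing more than
    ``max_trim`` trimmed flank bases, are discarded.
    """
    if isinstance(local_contig, LocalContig):
        seq, lc_id = local_contig.sequence, local_contig.id
    else:
        seq, lc_id = local_contig, "local"
    out: list[Placement] = []
    for orient, c_seq in (("+", seq), ("-", revcomp(seq))):
        for side, flank in (("left", left_flank), ("right", right_flank)):
            if not flank:
                continue
            best: Optional[Placement] = None
            for d in _diagonals(c_seq, flank):
                pl = _score_diagonal(c_seq, flank, d, side, min_overlap, min_identity, max_trim)
                if pl is None:
                    continue
                key = (pl.spans_flank_edge, pl.overlap_len * pl.identity)
                if best is None or key > (best.spans_flank_edge, best.overlap_len * best.identity):
                    best = pl
            if best is not None:
                best.local_contig_id = lc_id
                best.orientation = orient
                out.append(best)
    return out


def resolve_gap(
    gap: Gap,
    left_flank: str,
    right_flank: str,
    local_contigs: Sequence[LocalContig],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_trim: int = DEFAULT_MAX_TRIM,
) -> GapOutcome:
    """Decide one gap's fate from its local contigs.

    Local contigs are tried in length x coverage order (ties: longer, then
    id). The first one placing on both flanks in a consistent orientation
    closes the gap. Failing closure, the best protrusive placement per
    flank (possibly from two different local contigs) extends the flanks;
    no mosaic of contigs is ever stitched inside the gap in one iteration.
    """
    ranked = sorted(local_contigs, key=lambda c: (-c.weight, -len(c.sequence), c.id))
    left_ext: Optional[tuple[str, Placement]] = None
    right_ext: Optional[tuple[str, Placement]] = None

    for lc in ranked:
        by_orient: dict[str, dict[str, Placement]] = {"+": {}, "-": {}}
        for pl in place_local_contig(lc, left_flank, right_flank, min_overlap, min_identity, max_trim):
            by_orient[pl.orientation][pl.flank] = pl
        # closure: both flanks, one orientation, both reaching the gap edge
        for orient in ("+", "-"):
            pls = by_orient[orient]
            if "left" in pls and "right" in pls and pls["left"].spans_flank_edge and pls["right"].spans_flank_edge:
                c_seq = lc.sequence if orient == "+" else revcomp(lc.sequence)
                a, b = pls["left"].c_break, pls["right"].c_break
                hl, hr = pls["left"].flank_overhang, pls["right"].flank_overhang
                inserted = c_seq[a:b] if b >= a else ""
                return GapOutcome(
                    gap_id=gap.gap_id,
                    action="closed",
                    inserted_sequence=inserted,
                    closed_length=(b - a) - (hl + hr),
                    span_seq=c_seq,
                    a=a,
                    b=b,
                    trim_left=hl,
                    trim_right=hr,
                    stats=_stats(pls.get("left"), pls.get("right")),
                )
        dual_conflict = (
            ("left" in by_orient["+"] and by_orient["+"]["left"].spans_flank_edge
             and "right" in by_orient["-"] and by_orient["-"]["right"].spans_flank_edge)
            or ("left" in by_orient["-"] and by_orient["-"]["left"].spans_flank_edge
                and "right" in by_orient["+"] and by_orient["+"]["right"].spans_flank_edge)
        )
        if dual_conflict:
            logger.info("gap %s: local contig %s places on both flanks with "
                        "inconsistent orientations; ignored", gap.gap_id, lc.id)
            continue
        for orient in ("+", "-"):
            pls = by_orient[orient]
            c_seq = lc.sequence if orient == "+" else revcomp(lc.sequence)
            lp = pls.get("left")
            if lp and lp.spans_flank_edge and (lp.protrusion > 0 or lp.flank_overhang > 0) and left_ext is None:
                left_ext = (c_seq, lp)
            rp = pls.get("right")
            if rp and rp.spans_flank_edge and (rp.protrusion > 0 or rp.flank_overhang > 0) and right_ext is None:
                right_ext = (c_seq, rp)

    if left_ext is None and right_ext is None:
        return GapOutcome(gap_id=gap.gap_id, action="unchanged")

    lp = left_ext[1] if left_ext else None
    rp = right_ext[1] if right_ext else None
    net_left = (lp.protrusion - lp.flank_overhang) if lp else 0
    net_right = (rp.protrusion - rp.flank_overhang) if rp else 0
    if left_ext and right_ext:
        action = "extended_both"
    elif left_ext:
        action = "extended_left" if net_left > 0 else "overhang_corrected"
    else:
        action = "extended_right" if net_right > 0 else "overhang_corrected"
    if action in ("extended_left", "extended_right", "extended_both") and net_left <= 0 and net_right <= 0:
        action = "overhang_corrected"
    return GapOutcome(
        gap_id=gap.gap_id,
        action=action,
        left_ext=(left_ext[0], lp.c_break, lp.flank_overhang) if left_ext else None,
        right_ext=(right_ext[0], rp.c_break, rp.flank_overhang) if right_ext else None,
        stats=_stats(lp, rp),
    )


def _stats(lp: Optional[Placement], rp: Optional[Placement]) -> dict:
    return {
        "overlap_left": lp.overlap_len if lp else 0,
        "overlap_right": rp.overlap_len if rp else 0,
        "identity_left": round(lp.identity, 4) if lp else "",
        "identity_right": round(rp.identity, 4) if rp else "",
        "trimmed_left": lp.flank_overhang if lp else 0,
        "trimmed_right": rp.flank_overhang if rp else 0,
    }


# ---------------------------------------------------------------------------
# applying outcomes to the assembly
# ---------------------------------------------------------------------------

def _consume_tail(gap: Gap, n: int) -> None:
    """Account for n bases trimmed off the left side of the gap."""
    take = min(n, len(gap.left_fill))
    if take:
        gap.left_fill = gap.left_fill[: len(gap.left_fill) - take]
    gap.trimmed_into_left += n - take


def _consume_head(gap: Gap, n: int) -> None:
    take = min(n, len(gap.right_fill))
    if take:
        gap.right_fill = gap.right_fill[take:]
    gap.trimmed_into_right += n - take


def apply_outcomes(
    assembly: Assembly,
    gaps: Sequence[Gap],
    outcomes: dict[str, GapOutcome],
) -> None:
    """Apply at most one outcome per gap, in scaffold order, in place.

    Each gap edits only the two contig ends facing it, so edits from
    different gaps never collide; chained closures within one scaffold are
    applied left to right against the current sequences.
    """
    gaps_by_id = {g.gap_id: g for g in gaps}
    for sc in assembly.scaffolds:
        sc_gaps = [g for g in gaps if g.scaffold_id == sc.id]
        for gap in sc_gaps:
            out = outcomes.get(gap.gap_id)
            if out is None or out.action == "unchanged":
                continue
            left = assembly.contigs[gap.left_contig_id]
            right = assembly.contigs[gap.right_contig_id]
            if out.action == "closed":
                _apply_closure(assembly, sc, gap, left, right, out, gaps)
            else:
                net = 0
                if out.left_ext is not None:
                    seq, a, h = out.left_ext
                    left.sequence = left.sequence[: len(left.sequence) - h] + seq[a:]
                    _consume_tail(gap, h)
                    gap.left_fill += seq[a:]
                    net += len(seq) - a - h
                if out.right_ext is not None:
                    seq, b, h = out.right_ext
                    right.sequence = seq[:b] + right.sequence[h:]
                    _consume_head(gap, h)
                    gap.right_fill = seq[:b] + gap.right_fill
                    net += b - h
                gap.estimated_length -= net
                i = sc.contig_ids.index(gap.left_contig_id)
                sc.gap_estimates[i] = gap.estimated_length


def _apply_closure(
    assembly: Assembly,
    sc,
    gap: Gap,
    left: Contig,
    right: Contig,
    out: GapOutcome,
    all_gaps: Sequence[Gap],
) -> None:
    c_seq, a, b = out.span_seq, out.a, out.b
    hl, hr = out.trim_left, out.trim_right
    _consume_tail(gap, hl)
    _consume_head(gap, hr)
    if b >= a:
        merged_seq = left.sequence[: len(left.sequence) - hl] + c_seq[a:b] + right.sequence[hr:]
        gap.insert = out.inserted_sequence
    else:
        overlap = a - b
        merged_seq = left.sequence[: len(left.sequence) - hl] + right.sequence[hr + overlap :]
        _consume_head(gap, overlap)
        gap.insert = ""
    # audit: net length change equals the signed closed length
    assert len(merged_seq) - (len(left.sequence) + len(right.sequence)) == out.closed_length, (
        gap.gap_id,
        len(merged_seq),
        len(left.sequence),
        len(right.sequence),
        out.closed_length,
    )
    left.sequence = merged_seq
    del assembly.contigs[right.id]
    i = sc.contig_ids.index(gap.left_contig_id)
    sc.contig_ids.pop(i + 1)
    sc.gap_estimates.pop(i)
    if sc.orientations:
        sc.orientations.pop(i + 1)
    for j, cid in enumerate(sc.contig_ids):
        assembly.contigs[cid].index_in_scaffold = j
    gap.closed_length = out.closed_length
    gap.close()
    # the neighbouring gap to the right now borders the merged contig
    for g in all_gaps:
        if g is not gap and g.left_contig_id == right.id:
            g.left_contig_id = left.id
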