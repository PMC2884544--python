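"""Truth-based benchmark scoring and misassembly screening.

``classify_gaps`` compares, for every simulated gap, the sequence the
pipeline walked into the gap (flank extensions plus the final bridging
insert) against the genome sequence the simulator omitted. "Closed
correctly" is strict: exact string equality, i.e. 100% identity over the
full length. ``coverage_check`` realigns reads to the improved assembly
and flags regions whose read depth deviates from the assembly-wide median
— a collapsed repeat shows up as unusually high depth, a spurious
insertion as unusually low.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from scipy import stats

from .core import Assembly, Gap
from .mapping import build_index, place_pairs
from .simulate import TruthGap


@dataclass
class GapEvaluation:
    gap_id: str
    truth_status: str  # closed_correct | closed_misassembled | open
    identity_to_truth: Optional[float]
    closed_length: Optional[int]
    estimated_length: int
    true_length: int


@dataclass
class BenchmarkRow:
    gap_size: int
    n_gaps: int
    n_closed_total: int
    n_closed_correct: int
    n_misassembled: int

    @property
    def fraction_correct(self) -> float:
        return self.n_closed_correct / self.n_gaps if self.n_gaps else 0.0

    @property
    def false_rate(self) -> Optional[float]:
        if self.n_closed_total == 0:
            return None
        return self.n_misassembled / self.n_closed_total


@dataclass
class BenchmarkSummary:
    rows: list[BenchmarkRow] = field(default_factory=list)

    @property
    def overall(self) -> BenchmarkRow:
        return BenchmarkRow(
            gap_size=0,
            n_gaps=sum(r.n_gaps for r in self.rows),
            n_closed_total=sum(r.n_closed_total for r in self.rows),
            n_closed_correct=sum(r.n_closed_correct for r in self.rows),
            n_misassembled=sum(r.n_misassembled for r in self.rows),
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "gap_size\tn_gaps\tn_closed_total\tn_closed_correct\t"
                "n_misassembled\tfraction_correct\tfalse_rate\n"
            )
            for r in self.rows + [self.overall]:
                fr = "NA" if r.false_rate is None else f"{r.false_rate:.4f}"
                fh.write(
                    f"{r.gap_size or 'all'}\t{r.n_gaps}\t{r.n_closed_total}\t"
                    f"{r.n_closed_correct}\t{r.n_misassembled}\t"
                    f"{r.fraction_correct:.4f}\t{fr}\n"
                )


def _global_identity(a: str, b: str) -> float:
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    total = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / total if total else 0.0


def classify_gaps(gaps: Sequence[Gap], truth: Sequence[TruthGap]) -> list[GapEvaluation]:
    """Score every truth gap against the pipeline's reconstructed fill."""
    gaps_by_id = {g.gap_id: g for g in gaps}
    missing = [t.gap_id for t in truth if t.gap_id not in gaps_by_id]
    if missing:
        raise ValueError(f"truth gap ids absent from assembly gaps: {missing[:5]}")
    out: list[GapEvaluation] = []
    for t in truth:
        g = gaps_by_id[t.gap_id]
        if g.status != "closed":
            out.append(GapEvaluation(t.gap_id, "open", None, None, g.estimated_length, t.true_length))
            continue
        fill = g.total_fill
        if fill == t.sequence and g.trimmed_into_left == 0 and g.trimmed_into_right == 0:
            status, ident = "closed_correct", 1.0
        else:
            status, ident = "closed_misassembled", _global_identity(fill, t.sequence)
        out.append(
            GapEvaluation(t.gap_id, status, ident, g.closed_length, g.estimated_length, t.true_length)
        )
    return out


def summarize(evaluations: Sequence[GapEvaluation]) -> BenchmarkSummary:
    """Per-gap-size benchmark table (fractions plus false rates)."""
    sizes = sorted({e.true_length for e in evaluations})
    summary = BenchmarkSummary()
    for size in sizes:
        evs = [e for e in evaluations if e.true_length == size]
        closed = [e for e in evs if e.truth_status.startswith("closed")]
        summary.rows.append(
            BenchmarkRow(
                gap_size=size,
                n_gaps=len(evs),
                n_closed_total=len(closed),
                n_closed_correct=sum(1 for e in evs if e.truth_status == "closed_correct"),
                n_misassembled=sum(1 for e in evs if e.truth_status == "closed_misassembled"),
            )
        )
    return summary


def gap_length_stats(
    closed_lengths: Sequence[float],
    estimated_lengths: Sequence[float],
    include_negative: bool = False,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Histogram of closed-gap lengths and Pearson correlation with the
    scaffolder's gap estimates.

    By default only positive closed lengths enter the correlation (negative
    lengths mark artificial gaps whose flanks overlapped, not real inserted
    sequence). Returns (hist_counts, bin_edges, r, p).
    """
    x = np.asarray(closed_lengths, dtype=float)
    y = np.asarray(estimated_lengths, dtype=float)
    if not include_negative:
        keep = x > 0
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need >= 3 closed gaps with estimates for a correlation")
    hist, edges = np.histogram(x, bins="auto")
    r, p = stats.pearsonr(x, y)
    return hist, edges, float(r), float(p)


def coverage_check(
    assembly: Assembly,
    pairs,
    regions: Sequence[tuple[str, int, int]],
    high: float = 2.0,
    low: float = 0.5,
    seed_k: int = 13,
) -> list[tuple[str, int, int, float, str]]:
    """Per-region median read depth versus the assembly-wide median.

    Reads are re-mapped to the improved assembly (unique placements only).
    Returns ``(contig_id, start, end, median_depth, flag)`` per region with
    flag in {"ok", "high", "low"}.
    """
    index = build_index(assembly, seed_k=seed_k)
    placements = place_pairs(pairs, index)
    depth = {cid: np.zeros(len(c) + 1, dtype=np.int32) for cid, c in assembly.contigs.items()}
    for pl in placements:
        for aln in (pl.placement1, pl.placement2):
            if aln is not None:
                depth[aln.contig_id][aln.start] += 1
                depth[aln.contig_id][aln.end] -= 1
    per_base = {cid: np.cumsum(d[:-1]) for cid, d in depth.items()}
    global_median = float(np.median(np.concatenate(list(per_base.values()))))
    out = []
    for cid, start, end in regions:
        med = float(np.median(per_base[cid][start:end])) if end > start else 0.0
        if global_median > 0 and med > high * global_median:
            flag = "high"
        elif med < low * global_median:
            flag = "low"
        else:
            flag = "ok"
        out.append((cid, start, end, med, flag))
    return out
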