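"""Pipeline orchestration: map -> pool -> assemble -> merge, iterated.

Each iteration re-maps every read pair against the *updated* assembly,
gathers per-gap pools, runs local assembly at the current k, and applies
the resulting closures/extensions. A k-mer schedule (by default
``[(41, 5), (31, 5), (21, 3)]``, clipped to k < read length) governs the
stages: within a stage, iteration continues until a pass performs no
action, then the next (smaller) k takes over. Smaller k values rescue gaps
whose pools are too shallow or too repeat-broken for the larger k.

The pipeline itself is deterministic: randomness exists only in read
simulation, never in the core loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .core import Assembly, Gap, ReadPair
from . import mapping, merge, pools
from .dbg import assemble_pool

logger = logging.getLogger("gapmend")

DEFAULT_SCHEDULE: list[tuple[int, int]] = [(41, 5), (31, 5), (21, 3)]
DEFAULT_MAX_ITERS = 20


@dataclass
class PipelineParams:
    seed_k: int = mapping.DEFAULT_SEED_K
    repeat_cap: int = mapping.DEFAULT_REPEAT_CAP
    min_identity: float = mapping.DEFAULT_MIN_IDENTITY
    min_read_fraction: float = mapping.DEFAULT_MIN_READ_FRACTION
    unique_margin: int = mapping.DEFAULT_UNIQUE_MARGIN
    window: int = pools.DEFAULT_WINDOW
    orient_filter: bool = True
    min_overlap: int = merge.DEFAULT_MIN_OVERLAP
    merge_min_identity: float = merge.DEFAULT_MIN_IDENTITY
    max_trim: int = merge.DEFAULT_MAX_TRIM
    cov_cutoff: Optional[int] = None  # None = auto per pool
    schedule: list[tuple[int, int]] = field(default_factory=lambda: list(DEFAULT_SCHEDULE))
    max_iters: int = DEFAULT_MAX_ITERS
    workdir: Optional[Path] = None  # keep per-iteration intermediates


@dataclass
class IterationReport:
    iteration: int
    k_used: int
    n_gaps_open_before: int
    n_gaps_open_after: int
    n_closed: int
    n_extended: int
    n_overhang_corrected: int
    total_inserted_bp: int
    pair_categories: dict[str, int] = field(default_factory=dict)

    @property
    def n_actions(self) -> int:
        return self.n_closed + self.n_extended + self.n_overhang_corrected


def run_iteration(
    assembly: Assembly,
    gaps: list[Gap],
    pairs: Sequence[ReadPair],
    k: int,
    params: PipelineParams,
    iteration: int = 1,
    placements: Optional[list[mapping.PairPlacement]] = None,
) -> IterationReport:
    """One full pass over all open gaps, mutating assembly and gaps.

    ``placements`` may be supplied (SAM ingest) to replace the internal
    mapper for this pass; otherwise every pair is mapped from scratch
    against the current contigs.
    """
    open_gaps = [g for g in gaps if g.status == "open"]
    n_before = len(open_gaps)
    if not open_gaps:
        return IterationReport(iteration, k, 0, 0, 0, 0, 0, 0)

    if placements is None:
        index = mapping.build_index(assembly, seed_k=params.seed_k, repeat_cap=params.repeat_cap)
        placements = mapping.place_pairs(
            pairs,
            index,
            min_identity=params.min_identity,
            min_read_fraction=params.min_read_fraction,
            unique_margin=params.unique_margin,
        )
    cats: dict[str, int] = {}
    for p in placements:
        cats[p.category] = cats.get(p.category, 0) + 1

    anchored = pools.find_end_anchored(
        placements, assembly.contigs, window=params.window, orient_filter=params.orient_filter
    )
    gap_pools = pools.merge_pools_by_gap(open_gaps, anchored, pairs)

    outcomes: dict[str, merge.GapOutcome] = {}
    empty_pool_gaps: set[str] = set()
    for gap in open_gaps:
        pool = gap_pools.get(gap.gap_id)
        if pool is None or not pool.reads:
            empty_pool_gaps.add(gap.gap_id)
            continue
        try:
            local_contigs = assemble_pool(
                pool.sequences(), k, gap_id=gap.gap_id, cov_cutoff=params.cov_cutoff
            )
        except Exception:  # per-gap assembly failures are never fatal
            logger.exception("gap %s: local assembly failed; skipped", gap.gap_id)
            continue
        if not local_contigs:
            continue
        left = assembly.contigs[gap.left_contig_id]
        right = assembly.contigs[gap.right_contig_id]
        outcomes[gap.gap_id] = merge.resolve_gap(
            gap,
            left.sequence[-params.window :],
            right.sequence[: params.window],
            local_contigs,
            min_overlap=params.min_overlap,
            min_identity=params.merge_min_identity,
            max_trim=params.max_trim,
        )
        if params.workdir is not None:
            d = Path(params.workdir) / f"iter_{iteration}"
            (d / "pools").mkdir(parents=True, exist_ok=True)
            (d / "local_contigs").mkdir(parents=True, exist_ok=True)
            pools.write_pool_fasta(pool, d / "pools" / f"{gap.gap_id}.fa")
            from .seqio import write_fasta

            write_fasta(
                [(f"{c.id} cov={c.mean_kmer_coverage:.1f}", c.sequence) for c in local_contigs],
                d / "local_contigs" / f"{gap.gap_id}.fa",
            )

    merge.apply_outcomes(assembly, gaps, outcomes)

    n_closed = sum(1 for o in outcomes.values() if o.action == "closed")
    n_ext = sum(1 for o in outcomes.values() if o.action.startswith("extended"))
    n_over = sum(1 for o in outcomes.values() if o.action == "overhang_corrected")
    total_ins = sum(len(o.inserted_sequence) for o in outcomes.values())
    report = IterationReport(
        iteration=iteration,
        k_used=k,
        n_gaps_open_before=n_before,
        n_gaps_open_after=sum(1 for g in gaps if g.status == "open"),
        n_closed=n_closed,
        n_extended=n_ext,
        n_overhang_corrected=n_over,
        total_inserted_bp=total_ins,
        pair_categories=cats,
    )
    report._empty_pool_gaps = empty_pool_gaps  # type: ignore[attr-defined]
    logger.info(
        "iter %d (k=%d): %d open -> %d; closed %d, extended %d, overhang %d",
        iteration, k, n_before, report.n_gaps_open_after, n_closed, n_ext, n_over,
    )
    return report


def run(
    assembly: Assembly,
    gaps: list[Gap],
    pairs: Sequence[ReadPair],
    params: Optional[PipelineParams] = None,
    sam_path=None,
) -> list[IterationReport]:
    """Run the full schedule to convergence, mutating assembly and gaps.

    With ``sam_path`` given, the first iteration ingests pre-computed
    alignments instead of running the internal mapper; later iterations
    (against an updated assembly) always use the internal mapper.
    """
    params = params or PipelineParams()
    read_len = min((min(len(p.seq1), len(p.seq2)) for p in pairs), default=0)
    schedule = [(k, n) for k, n in params.schedule if k < read_len]
    if not schedule and read_len:
        raise ValueError(f"no schedule k below read length {read_len}")

    reports: list[IterationReport] = []
    iteration = 0
    last_empty: set[str] = set()
    for k, stage_iters in schedule:
        for _ in range(stage_iters):
            if iteration >= params.max_iters or not any(g.status == "open" for g in gaps):
                break
            iteration += 1
            placements = None
            if sam_path is not None and iteration == 1:
                sam_pairs, placements = mapping.placements_from_sam(sam_path, assembly)
                pairs = sam_pairs
            rep = run_iteration(assembly, gaps, pairs, k, params, iteration, placements)
            reports.append(rep)
            last_empty = getattr(rep, "_empty_pool_gaps", set())
            if rep.n_actions == 0:
                break  # stage converged, advance to next k
    # gaps whose final pool held no unique anchors can never progress
    for g in gaps:
        if g.status == "open" and g.gap_id in last_empty:
            g.mark_uncloseable()
    return reports


def write_report_tsv(reports: Sequence[IterationReport], path) -> None:
    cols = [
        "iteration", "k_used", "n_gaps_open_before", "n_gaps_open_after",
        "n_closed", "n_extended", "n_overhang_corrected", "total_inserted_bp",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reports:
            fh.write("\t".join(str(getattr(r, c)) for c in cols) + "\n")


def write_outcomes_tsv(gaps: Sequence[Gap], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gap_id\tstatus\tclosed_length\testimated_length\t"
            "trimmed_into_left\ttrimmed_into_right\ttotal_fill\n"
        )
        for g in gaps:
            cl = g.closed_length if g.closed_length is not None else "NA"
            fh.write(
                f"{g.gap_id}\t{g.status}\t{cl}\t{g.estimated_length}\t"
                f"{g.trimmed_into_left}\t{g.trimmed_into_right}\t{g.total_fill or '.'}\n"
            )
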