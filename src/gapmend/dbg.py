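"""Local de Bruijn graph assembly of per-gap read pools.

The graph is double-stranded: a k-mer and its reverse complement are one
node (canonical representation, k odd so no k-mer is its own reverse
complement), and edges are (k+1)-mer adjacencies counted the same way.
Assembly extracts maximal unbranched walks; at a branch, traversal
continues only through an outgoing edge carrying at least
``MAJORITY_FRACTION`` of the branch's outgoing coverage, otherwise it stops
— preferring a truncated contig over a misjoin, which is exactly the
desired fail-closed behavior on short tandem repeats.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .core import revcomp

MAJORITY_FRACTION = 0.8
MIN_CONTIG_MARGIN = 10  # contigs shorter than k + margin are discarded


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class DeBruijnGraph:
    k: int
    nodes: Counter  # canonical k-mer -> count
    edges: Counter  # canonical (k+1)-mer -> count

    def has_node(self, kmer: str) -> bool:
        return canonical(kmer) in self.nodes

    def successors(self, kmer: str) -> list[tuple[str, int]]:
        """Oriented successors of an oriented k-mer, with edge counts."""
        out = []
        suffix = kmer[1:]
        for b in "ACGT":
            c = self.edges.get(canonical(kmer + b), 0)
            if c and canonical(suffix + b) in self.nodes:
                out.append((suffix + b, c))
        return out

    def predecessors(self, kmer: str) -> list[tuple[str, int]]:
        return [(revcomp(t), c) for t, c in self.successors(revcomp(kmer))]

    def drop_node(self, kmer: str) -> None:
        self.nodes.pop(canonical(kmer), None)


@dataclass
class LocalContig:
    gap_id: str
    id: str
    sequence: str
    mean_kmer_coverage: float
    k_used: int

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def weight(self) -> float:
        """Ranking key when several local contigs compete for one gap."""
        return len(self.sequence) * self.mean_kmer_coverage


def build_graph(reads: Iterable[str], k: int) -> DeBruijnGraph:
    """Count canonical k-mers and (k+1)-mer adjacencies over all reads.

    Reads containing N are split at the N; reads shorter than k contribute
    nothing. k must be odd.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd for a canonical double-stranded graph")
    nodes: Counter = Counter()
    edges: Counter = Counter()
    for read in reads:
        if k >= len(read):
            raise ValueError(f"k={k} must be smaller than read length {len(read)}")
        for seg in read.split("N"):
            if len(seg) < k:
                continue
            for i in range(len(seg) - k + 1):
                nodes[canonical(seg[i : i + k])] += 1
            for i in range(len(seg) - k):
                edges[canonical(seg[i : i + k + 1])] += 1
    return DeBruijnGraph(k=k, nodes=nodes, edges=edges)


def simplify(
    graph: DeBruijnGraph,
    cov_cutoff: int = 0,
    tip_len: Optional[int] = None,
) -> DeBruijnGraph:
    """Coverage-cutoff node removal followed by iterative tip clipping.

    Nodes observed fewer than ``cov_cutoff`` times are dropped. A *tip* is a
    dead-end unbranched walk shorter than ``tip_len`` bases hanging off a
    junction; tips are clipped to fixpoint. A free-standing simple path (no
    junction behind it) is never clipped — it may be the whole assembly.
    """
    if tip_len is None:
        tip_len = 2 * graph.k
    if cov_cutoff > 0:
        for km in [km for km, c in graph.nodes.items() if c < cov_cutoff]:
            del graph.nodes[km]
    changed = True
    while changed:
        changed = False
        for km in sorted(graph.nodes):
            if km not in graph.nodes:
                continue
            for oriented in (km, revcomp(km)):
                if not graph.predecessors(oriented):
                    if _clip_tip(graph, oriented, tip_len):
                        changed = True
                    break
    return graph


def _clip_tip(graph: DeBruijnGraph, start: str, tip_len: int) -> bool:
    """Walk forward from a dead end; clip the walk if it is a short tip."""
    walk = [start]
    cur = start
    while True:
        succ = graph.successors(cur)
        if len(succ) != 1:
            break
        nxt = succ[0][0]
        if len(graph.predecessors(nxt)) > 1:
            # nxt is a junction: the walk is attached to the rest of the graph
            if len(walk) + graph.k - 1 < tip_len:
                for km in walk:
                    graph.drop_node(km)
                return True
            return False
        if canonical(nxt) in {canonical(w) for w in walk}:
            return False  # cycle, not a tip
        walk.append(nxt)
        cur = nxt
    if len(succ) > 1:
        # dead-end walk terminating at a fork seen from this side
        if len(walk) + graph.k - 1 < tip_len:
            for km in walk:
                graph.drop_node(km)
            return True
    return False


def _extend(graph: DeBruijnGraph, start: str, visited: set[str]) -> list[str]:
    """Greedy right extension under the majority rule; returns appended bases."""
    bases: list[str] = []
    cur = start
    while True:
        succ = graph.successors(cur)
        if not succ:
            break
        if len(succ) == 1:
            nxt, _ = succ[0]
        else:
            total = sum(c for _, c in succ)
            succ.sort(key=lambda t: (-t[1], t[0]))
            if succ[0][1] < MAJORITY_FRACTION * total or succ[0][1] == succ[1][1]:
                break
            nxt = succ[0][0]
        if canonical(nxt) in visited:
            break
        visited.add(canonical(nxt))
        bases.append(nxt[-1])
        cur = nxt
    return bases


def assemble_pool(
    reads: Sequence[str],
    k: int,
    gap_id: str = "",
    cov_cutoff: Optional[int] = None,
    tip_len: Optional[int] = None,
) -> list[LocalContig]:
    """Assemble a read pool into local contigs.

    ``cov_cutoff=None`` selects ``max(2, mean node count // 10)`` per pool
    (low-coverage noise removal that adapts to pool depth). Output contigs
    are maximal majority-rule walks, at least ``k + 10`` bases long, sorted
    by length x coverage descending (ties: longer first, then id).
    """
    reads = [r for r in reads if len(r) > k]
    if not reads:
        return []
    graph = build_graph(reads, k)
    if not graph.nodes:
        return []
    if cov_cutoff is None:
        mean = sum(graph.nodes.values()) / len(graph.nodes)
        cov_cutoff = max(2, int(mean // 10))
    simplify(graph, cov_cutoff=cov_cutoff, tip_len=tip_len)

    visited: set[str] = set()
    contigs: list[LocalContig] = []
    n = 0
    for km in sorted(graph.nodes):
        if km in visited:
            continue
        visited.add(km)
        right = _extend(graph, km, visited)
        left = _extend(graph, revcomp(km), visited)
        seq = revcomp("".join(left)) + km + "".join(right)
        if len(seq) < k + MIN_CONTIG_MARGIN:
            continue
        counts = [graph.nodes[canonical(seq[i : i + k])] for i in range(len(seq) - k + 1)]
        n += 1
        contigs.append(
            LocalContig(
                gap_id=gap_id,
                id=f"{gap_id or 'pool'}.lc{n}",
                sequence=seq,
                mean_kmer_coverage=sum(counts) / len(counts),
                k_used=k,
            )
        )
    contigs.sort(key=lambda c: (-c.weight, -len(c.sequence), c.id))
    return contigs
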