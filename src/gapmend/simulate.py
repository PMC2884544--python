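"""Synthetic benchmark generation.

Emulates an idealized paired-end Illumina run over a finished genome: the
genome is partitioned left-to-right into fixed-length contigs separated by
fixed-length omitted stretches (the gaps to be re-closed), and error-free
read pairs of fixed fragment length are sampled uniformly from the intact
genome with truth coordinates recorded.

Defaults follow the benchmark conditions the pipeline is assessed under:
30 kb contigs, gaps of 1/2/10 kb, 76 bp reads from 300 bp fragments at
25-fold coverage. What the generator deliberately does not emulate:
sequencing errors, quality-value profiles, insert-size variance, GC bias,
chimeric fragments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Assembly, Contig, Gap, ReadPair, Scaffold, gaps_from_scaffolds, revcomp

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class TruthGap:
    """The omitted genome interval behind one simulated gap."""

    gap_id: str
    ref_start: int
    ref_end: int
    sequence: str

    @property
    def true_length(self) -> int:
        return self.ref_end - self.ref_start


def random_genome(length: int, seed: int, gc: float = 0.5) -> str:
    """A seeded i.i.d. random genome; repeat-free for practical purposes."""
    rng = np.random.default_rng(seed)
    p_at = (1.0 - gc) / 2.0
    p_gc = gc / 2.0
    draws = rng.choice(BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    return draws.tobytes().decode()


def make_gapped_assembly(
    genome: str,
    contig_len: int = 30_000,
    gap_len: int = 1_000,
    scaffold_id: str = "scaffold1",
) -> tuple[Assembly, list[Gap], list[TruthGap]]:
    """Partition a genome into alternating kept contigs and omitted gaps.

    A trailing remainder shorter than ``contig_len`` is kept as a final
    contig; a remainder that would fall inside a gap is discarded. The
    scaffold's stored gap estimates equal the true omitted length.
    """
    if contig_len < 1 or gap_len < 1:
        raise ValueError("contig_len and gap_len must be >= 1")
    if len(genome) <= contig_len:
        if len(genome) < 1:
            raise ValueError("genome shorter than one contig")
        # no room for any gap: single-contig assembly
        contigs = [Contig("contig1", genome, scaffold_id, 0)]
        asm = Assembly(contigs={c.id: c for c in contigs}, scaffolds=[Scaffold(scaffold_id, ["contig1"], [])])
        return asm, [], []

    contigs: list[Contig] = []
    truth: list[TruthGap] = []
    pos = 0
    i = 0
    while pos < len(genome):
        seg = genome[pos : pos + contig_len]
        i += 1
        contigs.append(Contig(f"contig{i}", seg, scaffold_id, i - 1))
        pos += contig_len
        if pos >= len(genome):
            break
        gap_end = pos + gap_len
        if gap_end >= len(genome):
            break  # dangling gap at the tail: discard
        truth.append(TruthGap(f"{scaffold_id}.gap{i}", pos, gap_end, genome[pos:gap_end]))
        pos = gap_end

    scaffold = Scaffold(scaffold_id, [c.id for c in contigs], [gap_len] * (len(contigs) - 1))
    asm = Assembly(contigs={c.id: c for c in contigs}, scaffolds=[scaffold])
    gaps = gaps_from_scaffolds([scaffold])
    assert [g.gap_id for g in gaps] == [t.gap_id for t in truth]
    return asm, gaps, truth


def simulate_paired_reads(
    genome: str,
    read_len: int = 76,
    fragment_len: int = 300,
    coverage: float = 25.0,
    seed: int = 1,
) -> list[ReadPair]:
    """Error-free paired reads from uniformly placed fixed-length fragments.

    Mate 1 is the fragment's first ``read_len`` bases (forward strand);
    mate 2 is the reverse complement of its last ``read_len`` bases. The
    pair count is ``ceil(len(genome) * coverage / (2 * read_len))``.
    """
    L = len(genome)
    if not (read_len <= fragment_len <= L):
        raise ValueError("need read_len <= fragment_len <= genome length")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    n_pairs = math.ceil(L * coverage / (2 * read_len))
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, L - fragment_len + 1, size=n_pairs)
    pairs: list[ReadPair] = []
    for i, s in enumerate(starts):
        s = int(s)
        m2_start = s + fragment_len - read_len
        pairs.append(
            ReadPair(
                fragment_id=f"frag{i}",
                seq1=genome[s : s + read_len],
                seq2=revcomp(genome[m2_start : m2_start + read_len]),
                truth1=("ref", s, "+"),
                truth2=("ref", m2_start, "-"),
            )
        )
    return pairs


def write_truth_tsv(truth: list[TruthGap], path) -> None:
    with open(path, "w") as fh:
        fh.write("gap_id\tref_start\tref_end\ttrue_length\tomitted_sequence\n")
        for t in truth:
            fh.write(f"{t.gap_id}\t{t.ref_start}\t{t.ref_end}\t{t.true_length}\t{t.sequence}\n")


def read_truth_tsv(path) -> list[TruthGap]:
    truth = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gap_id\t"):
            raise ValueError(f"{path}: not a truth TSV")
        for line in fh:
            gap_id, s, e, _L, seq = line.rstrip("\n").split("\t")
            truth.append(TruthGap(gap_id, int(s), int(e), seq))
    return truth
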