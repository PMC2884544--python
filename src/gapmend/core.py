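"""Domain types and coordinate conventions.

Every coordinate inside the package is 0-based half-open. Conversions to and
from the 1-based inclusive conventions of AGP and SAM happen only in
:mod:`gapmend.seqio`. Sequences are uppercase strings over ``{A,C,G,T,N}``
after ingest normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

logger = logging.getLogger("gapmend")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC nucleotide codes accepted on input; everything outside ACGT becomes N.
IUPAC = set("ACGTNRYSWKMBDHVU")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase ACGTN string (an involution)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_seq(seq: str) -> tuple[str, int]:
    """Uppercase ``seq`` and collapse non-ACGTN IUPAC codes to N.

    Returns the normalized sequence and the number of characters changed
    (case changes are not counted; ambiguity conversions are).

    Raises
    ------
    ValueError
        If a character is not an IUPAC nucleotide code.
    """
    up = seq.upper()
    bad = set(up) - IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)!r}")
    n_changed = sum(1 for c in up if c not in "ACGTN")
    if n_changed:
        out = "".join(c if c in "ACGTN" else "N" for c in up)
        return out, n_changed
    return up, 0


@dataclass
class Contig:
    """A named assembly sequence and its place in a scaffold."""

    id: str
    sequence: str
    scaffold_id: str = ""
    index_in_scaffold: int = 0
    orientation: str = "+"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.id!r} has an empty sequence")
        if self.orientation not in "+-":
            raise ValueError(f"bad orientation {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Scaffold:
    """Ordered contigs with one estimated gap length per adjacent pair."""

    id: str
    contig_ids: list[str]
    gap_estimates: list[int]
    #: per-contig orientation from the layout file; None means all '+'
    orientations: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if len(self.gap_estimates) != max(0, len(self.contig_ids) - 1):
            raise ValueError(
                f"scaffold {self.id}: {len(self.contig_ids)} contigs need "
                f"{max(0, len(self.contig_ids) - 1)} gap estimates, "
                f"got {len(self.gap_estimates)}"
            )


@dataclass
class Gap:
    """The unsequenced region between two adjacent contigs in a scaffold.

    ``left_fill``/``right_fill`` accumulate sequence walked in from either
    flank across iterations; ``insert`` is the final bridging sequence when
    the gap closes. ``total_fill`` is the full reconstructed gap sequence,
    used for truth-based evaluation.
    """

    gap_id: str
    scaffold_id: str
    left_contig_id: str
    right_contig_id: str
    estimated_length: int
    status: str = "open"  # open | closed | uncloseable

    left_fill: str = ""
    right_fill: str = ""
    insert: str = ""
    closed_length: Optional[int] = None
    trimmed_into_left: int = 0
    trimmed_into_right: int = 0

    @property
    def total_fill(self) -> str:
        return self.left_fill + self.insert + self.right_fill

    def close(self) -> None:
        if self.status != "open":
            raise ValueError(f"gap {self.gap_id} already {self.status}")
        self.status = "closed"

    def mark_uncloseable(self) -> None:
        if self.status == "open":
            self.status = "uncloseable"


@dataclass
class ReadPair:
    """Two mates from one fragment; mate 2 is the reverse complement of the
    fragment's 3' end. ``truth1``/``truth2`` are ``(ref_id, start, strand)``
    tuples recorded by the simulator."""

    fragment_id: str
    seq1: str
    seq2: str
    truth1: Optional[tuple[str, int, str]] = None
    truth2: Optional[tuple[str, int, str]] = None


@dataclass
class Alignment:
    """An ungapped (or SAM-derived) placement of a read on a contig."""

    read_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    mismatches: int = 0
    is_unique: bool = False
    score: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad alignment interval [{self.start},{self.end}) for {self.read_id}"
            )


@dataclass
class Assembly:
    """A draft assembly: contigs plus scaffold layout."""

    contigs: dict[str, Contig] = field(default_factory=dict)
    scaffolds: list[Scaffold] = field(default_factory=list)

    def add_contig(self, contig: Contig) -> None:
        if contig.id in self.contigs:
            raise ValueError(f"duplicate contig id {contig.id!r}")
        self.contigs[contig.id] = contig

    def total_bases(self) -> int:
        return sum(len(c) for c in self.contigs.values())

    def copy(self) -> "Assembly":
        return Assembly(
            contigs={
                cid: Contig(c.id, c.sequence, c.scaffold_id, c.index_in_scaffold, c.orientation)
                for cid, c in self.contigs.items()
            },
            scaffolds=[Scaffold(s.id, list(s.contig_ids), list(s.gap_estimates)) for s in self.scaffolds],
        )


def gaps_from_scaffolds(scaffolds: Iterable[Scaffold]) -> list[Gap]:
    """One open Gap per adjacent contig pair within each scaffold."""
    gaps: list[Gap] = []
    for sc in scaffolds:
        for i in range(len(sc.contig_ids) - 1):
            gaps.append(
                Gap(
                    gap_id=f"{sc.id}.gap{i + 1}",
                    scaffold_id=sc.id,
                    left_contig_id=sc.contig_ids[i],
                    right_contig_id=sc.contig_ids[i + 1],
                    estimated_length=sc.gap_estimates[i],
                )
            )
    return gaps
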