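# Methods

## Problem and model

A draft assembly is a set of contigs ordered into scaffolds, with an
estimated but unsequenced gap between each adjacent contig pair. Paired-end
reads constrain each mate's position relative to the other through the
fragment length. The pipeline treats each gap as a tiny, independent
assembly problem: the reads that can possibly span into a gap are exactly
those whose unique placement lies within an end window of a flanking
contig, oriented toward the gap, plus the unmapped mates of such reads.
Assembling only this pool makes otherwise-repetitive k-mers locally unique,
which is why a local assembly can succeed where the genome-wide assembly
terminated a contig.

Coordinates are 0-based half-open everywhere inside the package; AGP and
SAM conventions are converted at the readers/writers and nowhere else.
Ingest normalizes sequence to uppercase and collapses IUPAC ambiguity codes
to N (counted and logged) because the k-mer stages need a closed
{A,C,G,T,N} alphabet.

## Stages and tunable parameters

### Mapping (internal seed-and-extend)

* `seed_k = 13` — exact-seed length; three seed offsets per strand (start,
  middle, end) vote for candidate diagonals.
* scoring: ungapped extension, match +1 / mismatch −1, clipped at contig
  boundaries; alignments kept at ≥ 90 % identity over ≥ 90 % of the read
  (`min_identity`, `min_read_fraction`).
* `unique_margin = 5` — a read is "unambiguously mapped" iff its best score
  exceeds the runner-up by this margin (or there is a single candidate).
* `repeat_cap = 1000` — seeds occurring more often are masked (logged) to
  bound fan-out.

The mapper is deliberately ungapped: the benchmark reads are error-free,
and indel-containing real reads are expected to arrive as SAM from a gapped
aligner, which is fully interchangeable (MAPQ > 0 primary records count as
unique, MAPQ 0/secondary as ambiguous, flag 0x4 as unmapped).

### Pooling

* `window = 600` bp — a read anchors a contig end when its unique alignment
  ends within the window and points into the gap. The window should be at
  least fragment length + read length; 600 is the default for the standard
  300 bp-fragment libraries the pipeline targets.
* The orientation filter follows from fragment geometry (the mate of a
  gap-spanning anchor always reads back toward it); `--no-orient-filter`
  disables it for unusual libraries.
* Mates are rescued only when the mate has no acceptable placement
  anywhere; anchored reads whose mate maps elsewhere still contribute their
  own (full-length, not clipped) sequence.
* Pool sequences are normalized to scaffold-forward strand; a read enters a
  pool at most once.

### Local assembly

* Canonical double-stranded de Bruijn graph; k odd so no k-mer is its own
  reverse complement. Nodes are k-mers, edges (k+1)-mers, both counted over
  reads split at N.
* `cov_cutoff` — nodes observed fewer times are dropped; default
  `max(2, mean_node_count // 10)` per pool, an automated stand-in for
  manual per-dataset coverage tuning.
* tip removal — dead-end unbranched walks shorter than `2k` bases hanging
  off a junction are clipped to fixpoint; a free-standing simple path is
  never clipped (it may be the entire local contig).
* traversal — maximal walks; at a branch the walk continues only through an
  outgoing edge carrying ≥ 80 % of outgoing coverage, otherwise it stops.
  This is what makes short tandem repeats (for example a (GAA)×30 stretch,
  which is a 3-periodic cycle in the graph) fail *closed*: the walk
  truncates rather than inventing copy number.
* contigs shorter than k + 10 are discarded; output is sorted by
  length × coverage.

### Merging and extension

* flanks are the terminal `window` bases of the two contigs facing the gap.
* `min_overlap = 20` bp and `min_identity = 0.95` gate placements;
  `max_trim = 100` bp bounds how much junk flank tail ("overhang") may be
  trimmed. Trimmed bases are replaced by the local contig's version, so a
  correction composes with extension or closure.
* overhang detection uses the maximal-scoring prefix/suffix of the overlap
  (match +1 / mismatch −1) rather than a strict mismatch run, so junk tails
  containing chance matches are still trimmed.
* one local contig placing on both flanks in one orientation closes the
  gap. `closed_length` is the signed net length change of the assembly:
  the inserted bases minus trimmed bases, and negative when the flanks
  genuinely overlap (an artificial gap); the join then requires the
  spanning local contig as evidence — flank-flank overlap alone never
  joins. An audit asserts
  `closed_length == merged_length − (len_left + len_right)` at every
  closure.
* failing closure, the best placing contig per flank extends that flank;
  at most one contig acts per flank and contigs are never concatenated
  inside a gap within one iteration (multi-step walks happen across
  iterations instead).

### Iteration

* schedule: `[(41, 5), (31, 5), (21, 3)]` — five iterations at k = 41, five
  at 31, three at 21, clipped to k < read length; a stage advances early
  when an iteration performs no action; `max_iters = 20` overall.
* every iteration re-maps all reads against the updated assembly.
  Correctness over speed: stale alignments near edited ends are the main
  source of subtle errors in incremental schemes.
* the core loop is deterministic; the only randomness in the package is the
  simulator's seeded generator. Re-running on converged output is a
  fixpoint, and the open-gap count never increases.

## Synthetic benchmark

The generator emulates an idealized paired-end run over a finished genome:
the genome is partitioned left-to-right into fixed-length kept contigs
(default 30 kb) and omitted stretches (the gaps; 1/2/10 kb configurations),
and `ceil(len·coverage / (2·read_len))` error-free pairs of fixed fragment
length (default 76 bp reads, 300 bp fragments, 25×) are drawn with uniform
fragment starts from the intact genome, truth coordinates recorded. A
trailing remainder shorter than one contig is kept as a final contig; a
remainder that would fall inside a gap is discarded. Fragments are sampled
from the forward strand only (mate 2 reverse complemented), which is
informationally equivalent for an error-free simulation.

What the generator does **not** emulate: sequencing errors and quality
profiles, insert-size variance, GC/coverage bias, chimeric fragments,
strand-specific artifacts. A green benchmark therefore establishes the
correctness of the pooling/assembly/merging logic and its failure modes on
repeats — not robustness to real error profiles. For error-rich data the
intended route is an external gapped aligner via SAM, and bubble popping
(not implemented) would become relevant in the local assembler.

Evaluation is strict: a gap counts as closed correctly only when the
reconstructed fill (flank extensions plus final insert) equals the omitted
sequence exactly; anything else closed is a misassembly, with identity from
global alignment. The false rate divides misassemblies by closed gaps. The
read-depth screen re-maps reads to the improved assembly and flags regions
whose median depth exceeds 2× or falls below 0.5× the assembly-wide median
(collapsed repeats read high, spurious insertions read low).

## Numerical and design choices

* Uniqueness margin, identity/coverage thresholds, overlap/trim thresholds
  are package defaults chosen for short error-free-to-low-error reads; all
  are exposed as configuration.
* Tie-breaks are deterministic everywhere: candidate alignments sort by
  (score, contig, position, strand); local contigs by (weight, length, id);
  graph traversal starts from lexicographically sorted canonical k-mers and
  stops at equal-coverage branch ties.
* Gap fills are tracked per gap (`left_fill`, `insert`, `right_fill`) as
  edits are applied, so evaluation never has to re-locate original flank
  boundaries in merged contigs; trims are charged against fills first and
  only then against original contig sequence.
* Degenerate inputs: contigs shorter than the seed are skipped with a
  warning; pools that assemble nothing, or local contigs that place on no
  flank, leave the gap unchanged; per-gap assembly exceptions are caught
  and logged, never fatal. Gaps whose final-iteration pool held no unique
  anchors are marked uncloseable.

## Known limitations

* No bubble popping or gapped overlap alignment: high-error real data will
  close fewer gaps than an error-aware local assembler would.
* Extension length per iteration is bounded by fragment geometry
  (~fragment − read length per side), so very long gaps need many
  iterations; the default schedule caps at 13.
* No re-scaffolding: contig order and orientation are taken as given, and
  misjoined input contigs are not broken.
* The repeat screen is read-depth only; paired-distance violations are not
  yet used as evidence.
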