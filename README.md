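# gapmend

Iterative gap closing for draft genome assemblies from paired-end short
reads.

Draft assemblies built from short-read data are fragmented: scaffolds order
the contigs, but the sequence between adjacent contigs — the *gaps* — is
unknown. Much of that sequence is actually recoverable from the very reads
already in hand. Because paired-end reads come from the two ends of a DNA
fragment of known size, a read that maps uniquely just inside a contig end
with a mate that maps nowhere is strong evidence that the mate lies inside
the adjacent gap. `gapmend` exploits this: it gathers, for every gap, the
uniquely end-anchored reads from both flanks plus their rescued unmapped
mates, assembles each small pool locally with a de Bruijn graph, and uses
the resulting local contigs to extend contig ends into the gap or to merge
the two flanking contigs outright. Re-mapping against the updated assembly
and repeating lets the pipeline walk into gaps much longer than one
fragment length. It is aimed at anyone polishing a draft microbial or
eukaryotic assembly who has (or can simulate) paired-end reads.

## Method sketch

Per iteration, with read length *L*, fragment size *F*, end window *w* and
de Bruijn order *k*:

1. **Map**: every read is placed by exact *k*-mer seeding plus ungapped
   extension; a placement is *unique* iff its score (match +1, mismatch −1)
   beats the runner-up by a margin. Any SAM-producing aligner can substitute
   for the internal mapper.
2. **Pool**: a read anchors a contig end when its unique alignment lies
   within *w* bp of that end and points into the gap; unmapped mates of
   anchored reads are rescued into the same pool. The right-end pool of
   contig *i* and the left-end pool of contig *i+1* form one pool per gap.
3. **Assemble**: each pool becomes a canonical (double-stranded) de Bruijn
   graph over *k*-mers; after coverage-cutoff and tip removal, maximal
   unbranched walks are read out. At a branch, traversal continues only
   through an edge carrying ≥ 80 % of outgoing coverage — preferring a
   truncated contig over a misjoin.
4. **Merge**: local contigs are placed on the two gap flanks by banded
   overlap alignment. One contig spanning both flanks closes the gap
   (`closed_length` = inserted bases, negative when the flanks truly
   overlap); a one-sided placement extends that flank; junk flank tails
   ("overhangs", up to 100 bp) are trimmed and replaced by the local
   contig's version.

A k-mer schedule (default `41:5,31:5,21:3`, clipped below *L*) re-runs the
loop until an iteration performs no action.

## Worked example

Simulate a benchmark from any genome FASTA (here a 60 kb random sequence),
close its gaps, and score against truth:

```
$ gapmend simulate --genome ref.fa --contig-len 8000 --gap-len 500 --seed 1 --out-prefix sim
8 contigs, 7 gaps, 9869 read pairs -> sim.*

$ gapmend run --contigs sim.contigs.fa --agp sim.agp --fastq1 sim_1.fq --fastq2 sim_2.fq --out improved
7/7 gaps closed in 3 iterations -> improved.*

$ gapmend evaluate --outcomes improved.outcomes.tsv --truth sim.truth.tsv --out report
{"n_gaps": 7, "n_closed_total": 7, "n_closed_correct": 7, "fraction_correct": 1.0, "false_rate": 0.0}
```

`simulate` cuts the genome into fixed-length contigs separated by omitted
stretches (the gaps) and emits error-free pairs with truth coordinates.
`run` writes the improved FASTA/AGP plus per-gap outcomes and per-iteration
reports. `evaluate` compares every reconstructed gap fill with the omitted
sequence: `fraction_correct` counts gaps closed with **exact** (100 %
identity) fills, `false_rate` is the fraction of closed gaps whose fill
deviates from truth. Here all seven 500 bp gaps were rebuilt byte-exactly.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end benchmark from scratch: it simulates a
500 kb seeded random genome partitioned into 30 kb contigs and 1 kb gaps
with 76 bp / 300 bp-fragment pairs at 25×, runs the pipeline to
convergence, scores all gaps against truth, prints the closure summary to
stderr and writes the metrics JSON to `--out`.

## Layout

- `gapmend.core` / `gapmend.seqio` — domain types; FASTA/FASTQ/AGP/SAM IO
  (0-based half-open coordinates everywhere internally).
- `gapmend.simulate` — benchmark generator (gapped assemblies, error-free
  pairs, truth records).
- `gapmend.mapping` — k-mer index, unique-placement mapper, SAM ingest.
- `gapmend.pools` — end anchoring and mate rescue per gap.
- `gapmend.dbg` — local de Bruijn assembler.
- `gapmend.merge` — flank placement, closure, extension, overhang trimming.
- `gapmend.driver` — iteration loop and k-mer schedule.
- `gapmend.evaluate` — truth-based scoring, length statistics, read-depth
  misassembly screen.

See `docs/methods.md` for the model, parameter defaults and limitations.
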