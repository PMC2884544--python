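import logging

import pytest

from gapmend import driver, simulate as sim

logging.getLogger("gapmend").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def toy_run():
    """A full pipeline run on a small repeat-free genome, shared read-only.

    50 kb random genome, 5 kb contigs, 500 bp gaps, idealized 76 bp reads
    from 300 bp fragments at 25x; returns everything needed to interrogate
    both the inputs and the converged result.
    """
    genome = sim.random_genome(50_000, seed=7)
    asm, gaps, truth = sim.make_gapped_assembly(genome, contig_len=5_000, gap_len=500)
    pairs = sim.simulate_paired_reads(genome, read_len=76, fragment_len=300, coverage=25.0, seed=3)
    reports = driver.run(asm, gaps, pairs)
    return {
        "genome": genome,
        "assembly": asm,
        "gaps": gaps,
        "truth": truth,
        "pairs": pairs,
        "reports": reports,
    }
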