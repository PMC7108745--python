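"""Shared fixtures: one toy genome with sexed reads and a full discovery run.

The genome is desk-scale (40 kb X and Y, 30 kb autosome, 2 kb mitochondrion)
with an X-linked 12-unit target cluster (one resistant unit) and an
autosomal decoy repeat that does not carry the target site. Session scope
keeps the expensive read simulation and discovery run to a single execution.
"""

import numpy as np
import pytest

from xshred import simulate as sim
from xshred.pipeline import run_discovery


@pytest.fixture(scope="session")
def genome():
    spec = sim.GenomeSpec(
        x_length=40_000,
        autosome_lengths=(30_000,),
        y_length=40_000,
        mito_length=2_000,
        clusters=(
            sim.RepeatClusterSpec(chrom="X", start=5_000, unit_count=12, resistant_unit=11),
            sim.RepeatClusterSpec(
                chrom="2", start=8_000, unit_count=8, unit_length=200, carries_target=False
            ),
        ),
        seed=7,
    )
    return sim.build_genome(spec)


@pytest.fixture(scope="session")
def read_spec():
    return sim.ReadSimSpec(
        depth=30.0, long_read_count=150, long_read_min=2_000, long_read_max=8_000
    )


@pytest.fixture(scope="session")
def sexed_reads(genome, read_spec):
    male = sim.simulate_short_reads(genome, "male", read_spec, seed=11)
    female = sim.simulate_short_reads(genome, "female", read_spec, seed=12)
    return male, female


@pytest.fixture(scope="session")
def long_reads(genome, read_spec):
    return sim.simulate_long_reads(genome, read_spec, seed=13)


@pytest.fixture(scope="session")
def discovery(genome, sexed_reads, long_reads):
    male, female = sexed_reads
    reads, _truth = long_reads
    return run_discovery(
        male, female, reads, genome.sequences["MT"], assembly=genome.to_fasta_records()
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
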