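import pytest

from alignbench import (
    GenomicRegion,
    QualityScenario,
    generate_synthetic_genome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def unique_genome():
    """100-kb repeat-free genome: every window is effectively unique."""
    genome, annot = generate_synthetic_genome(
        n_chroms=1, chrom_length=100_000, repeat_units=[], seed=7
    )
    return genome, annot


@pytest.fixture(scope="session")
def repeat_genome():
    """100-kb genome with a 500-bp unit planted at exactly two loci."""
    genome, annot = generate_synthetic_genome(
        n_chroms=1, chrom_length=100_000, repeat_units=[(500, 2, 0.0)], seed=3
    )
    return genome, annot


@pytest.fixture(scope="session")
def unique_regions(unique_genome):
    genome, _ = unique_genome
    return [
        GenomicRegion("chr1", start, start + 2000, name=f"region{i}")
        for i, start in enumerate(range(0, 100_000, 5000))
    ]


@pytest.fixture(scope="session")
def repeat_unit_regions(repeat_genome):
    """Regions that are exactly the planted repeat copies (reads drawn from
    them lie wholly inside a 2-copy exact repeat)."""
    _, annot = repeat_genome
    return [GenomicRegion(c, s, e) for c, s, e in annot.intervals]


@pytest.fixture(scope="session")
def mm1_high_reads(unique_genome, unique_regions):
    genome, _ = unique_genome
    return simulate_reads(
        genome,
        unique_regions,
        QualityScenario.make(1, "high"),
        n_reads=300,
        seed=5,
    )
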