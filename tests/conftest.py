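import pytest

from xenolocus import simulate as sim


@pytest.fixture(scope="session")
def constructs():
    return sim.default_constructs()


@pytest.fixture(scope="session")
def small_host():
    """Two small scaffolds with a handful of multi-exon genes and repeats."""
    records, models, repeats = sim.make_host_genome(
        2, [60_000, 40_000], genes_per_scaffold=3, seed=101
    )
    return records, models, repeats


@pytest.fixture(scope="session")
def small_genome(small_host):
    records, _models, _repeats = small_host
    return {r.id: r.seq for r in records}


@pytest.fixture(scope="session")
def insertion_scenario(small_genome, small_host, constructs):
    """A homozygous forward insertion with a 28-base flanking deletion plus
    the simulated read set over the combined reference."""
    records, models, _ = small_host
    event = sim.InsertionEvent("scf01", 30_000, deleted=28, zygosity="hom")
    haps, event = sim.apply_insertion(small_genome, constructs[0], event, models)
    refs = {r.id: len(r.seq) for r in records}
    refs.update({c.name: len(c.seq) for c in constructs})
    reads = sim.simulate_genomic_pairs(
        haps, refs, sim.ReadSimConfig(depth=30, seed=7), emit_fastq=False
    )
    return event, reads
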