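import pytest

import lariatkit as lk


@pytest.fixture(scope="session")
def toy():
    """Small genome with plus/minus-strand multi-intron genes."""
    genome, introns, genes = lk.make_genome(12, intron_len_range=(300, 500), seed=3)
    return genome, introns, genes


@pytest.fixture(scope="session")
def toy_index(toy):
    genome, _, _ = toy
    return lk.build_index(genome, 12)


@pytest.fixture(scope="session")
def toy_reads(toy):
    """Noise-free reads of all four classes with ground truth."""
    genome, introns, genes = toy
    counts = {
        "lariat": {i.intron_id: 4 for i in introns},
        "intron_circle": {i.intron_id: 1 for i in introns},
        "linear_mRNA": lk.uniform_counts([g.gene_id for g in genes], 24),
        "pre_mRNA": lk.uniform_counts([g.gene_id for g in genes], 12),
    }
    reads, truth = lk.simulate_reads(
        genome, introns, counts, read_len=60, seed=11, genes=genes, min_block=20
    )
    return reads, truth
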