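import pytest

from circat import align, simulate

SEED = 7


@pytest.fixture(scope="session")
def toy_truth():
    """2 x 50 kb toy genome with the 30-circle default design planted."""
    genome, ann = simulate.make_genome(seed=SEED)
    return simulate.plant_circles(genome, ann, simulate.default_design(), seed=SEED)


@pytest.fixture(scope="session")
def toy_index(toy_truth):
    return align.GenomeIndex(toy_truth.genome)


@pytest.fixture(scope="session")
def toy_reads(toy_truth):
    return simulate.simulate_reads(toy_truth, seed=SEED, n_linear_pairs=2000)["S1"]


@pytest.fixture(scope="session")
def toy_alignments(toy_truth, toy_index, toy_reads):
    pairs, _ = toy_reads
    alns, _ = align.detect_pairs(pairs, toy_truth.genome, index=toy_index)
    return alns
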