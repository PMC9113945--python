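import numpy as np
import pytest

from cpgprofiler import GeneRecord, SimulationConfig, WindowGrid, gen_sequences


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_grid():
    """A compact 10-window grid (200 bp flank, 40-bp windows) for unit tests."""
    return WindowGrid(flank=200, window=40)


@pytest.fixture(scope="session")
def small_sim():
    """A small three-archetype synthetic study shared across tests."""
    config = SimulationConfig(n_genes=(60, 60, 60), seed=7)
    genome, genes, truth = gen_sequences(config)
    return config, genome, genes, truth


def random_genome(rng, n_chrom=2, length=20_000):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        f"chr{i + 1}": bases[rng.integers(0, 4, size=length)].tobytes().decode()
        for i in range(n_chrom)
    }


def random_genes(rng, genome, n, grid):
    genes = []
    for i in range(n):
        chrom = list(genome)[rng.integers(len(genome))]
        tss = int(rng.integers(grid.flank, len(genome[chrom]) - grid.flank))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(f"r{i:03d}", chrom, tss, strand))
    return genes


@pytest.fixture(scope="session")
def random_locus_set(rng, small_grid):
    """100 random loci on random sequence, mixed strands."""
    genome = random_genome(rng)
    genes = random_genes(rng, genome, 100, small_grid)
    return genome, genes
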