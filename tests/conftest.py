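import numpy as np
import pytest

import hickar as hk
from hickar.edits import DerivativeKaryotype
from hickar.genome import Chromosome, GenomeModel


@pytest.fixture(scope="session")
def toy_genome():
    return hk.toy_chicken()


@pytest.fixture(scope="session")
def two_chrom_genome():
    return GenomeModel((Chromosome("A", 40_000_000), Chromosome("B", 30_000_000)))


@pytest.fixture(scope="session")
def identity_map_toy(toy_genome):
    """Default simulator output for the unedited toy genome."""
    return hk.simulate_map(
        toy_genome, hk.SimulationParams(bin_size=500_000, total_contacts=5e6, seed=0)
    )


@pytest.fixture(scope="session")
def insertion_map(toy_genome):
    """Toy map with one 30 Mb unbalanced insertion chr2 -> chr3:50 Mb."""
    e = hk.KaryotypeEdit(
        "translocation", "chr2", 100_000_000, 130_000_000,
        acceptor_chrom="chr3", insertion=50_000_000, mode="moved",
    )
    kt = hk.apply_edits(toy_genome, [e])
    m = hk.simulate_map(
        kt, hk.SimulationParams(bin_size=250_000, total_contacts=3e7, seed=2)
    )
    return m


@pytest.fixture(scope="session")
def small_map_pair(two_chrom_genome):
    """Two independent simulations of the same small identity genome."""
    p1 = hk.SimulationParams(bin_size=100_000, total_contacts=2e7, seed=21)
    p2 = hk.SimulationParams(bin_size=100_000, total_contacts=2e7, seed=22)
    kt = DerivativeKaryotype.identity(two_chrom_genome)
    return hk.simulate_map(kt, p1), hk.simulate_map(kt, p2)
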