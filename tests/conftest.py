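import numpy as np
import pytest

from gsalloc import (
    CVConfig,
    GenotypeMatrix,
    PhenotypeVector,
    SimConfig,
    simulate_population,
)


@pytest.fixture(scope="session")
def germplasm_pop():
    """Moderate structured panel with an additive trait (h2 = 0.6)."""
    cfg = SimConfig(
        archetype="GERMPLASM", n_genotypes=150, n_markers=300, n_qtl=15,
        h2=0.6, n_subpop=2, fst=0.1, seed=11,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def ld_block_pop():
    """Panel with strong block LD (few founder haplotypes, long blocks)."""
    cfg = SimConfig(
        archetype="GERMPLASM", n_genotypes=120, n_markers=50, n_chromosomes=2,
        n_qtl=5, h2=0.8, n_founder_haplotypes=4, block_mean_cM=60.0, seed=7,
    )
    G, _, _ = simulate_population(cfg)
    return G


@pytest.fixture
def tiny_G():
    """4 genotypes x 3 markers, handwritten dosages, no missing data."""
    return GenotypeMatrix(
        genotype_ids=["g1", "g2", "g3", "g4"],
        marker_ids=["m1", "m2", "m3"],
        dosage=np.array(
            [[0.0, 1.0, 2.0], [1.0, 1.0, 1.0], [2.0, 0.0, 0.0], [0.0, 2.0, 1.0]]
        ),
    )


@pytest.fixture
def fast_cv():
    return CVConfig(k=3, n_repetitions=1, seed=5)
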