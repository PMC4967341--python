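import numpy as np
import pytest

import methnome as mn


@pytest.fixture(scope="session")
def small_genome():
    """50 kb toy genome with its cytosine catalog."""
    params = mn.SimulationParams(genome_length=50_000, rng_seed=42)
    genome, catalog = mn.simulate_genome(params)
    return genome, catalog


@pytest.fixture(scope="session")
def dmr_dataset():
    """300 kb genome with 20 planted DMRs (delta 0.4, 6-12 CpGs, 30x, 2 vs 2)."""
    params = mn.SimulationParams(
        genome_length=300_000,
        n_dmrs=20,
        dmr_delta=(0.4,),
        dmr_cpg_range=(6, 12),
        coverage=30,
        donor_effect=0.0,
        rng_seed=7,
    )
    genome, catalog = mn.simulate_genome(params)
    table, truth = mn.simulate_methylomes(genome, catalog, params)
    return genome, table, truth


@pytest.fixture(scope="session")
def nome_dataset():
    """1 Mb NOMe-seq dataset: 10 planted NDRs per cell type, p 0.5/0.05, 20x."""
    params = mn.SimulationParams(
        genome_length=1_000_000,
        n_ndrs=(10, 10),
        ndr_p_open=0.5,
        ndr_p_closed=0.05,
        nome_coverage=20,
        rng_seed=11,
    )
    genome, catalog = mn.simulate_genome(params)
    table, truth = mn.simulate_nome(genome, catalog, params)
    return table, truth


def rng_for(name: str) -> np.random.Generator:
    """Stable per-test RNG derived from the test name."""
    return np.random.default_rng(abs(hash(name)) % (2**31))
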