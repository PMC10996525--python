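import numpy as np
import pytest

from tecompartment.compartmentalization import (
    call_compartmentalized,
    flank_profiles,
    resolve_repeat_overlaps,
)
from tecompartment.synthetic_data import SimulationConfig, simulate_species


@pytest.fixture(scope="session")
def small_config():
    """A compact species: fast to simulate, still >= 10 genes per percentile call."""
    return SimulationConfig(
        seed=42,
        n_chroms=2,
        chrom_length=13_000_000,
        n_genes=200,
        n_families=60,
        n_te_variants=800,
        n_snvs=600,
        n_sites_per_family=100,
    )


@pytest.fixture(scope="session")
def small_species(small_config):
    return simulate_species(small_config)


@pytest.fixture(scope="session")
def small_profiles(small_species):
    chroms, genes, repeats, _ = small_species
    return flank_profiles(genes, resolve_repeat_overlaps(repeats), chroms)


@pytest.fixture(scope="session")
def small_calls(small_profiles):
    return call_compartmentalized(small_profiles, "ALL", 90, "smallsim")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
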