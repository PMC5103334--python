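import pytest

from mirnome.synthdata import (
    SimConfig,
    simulate_genomes,
    simulate_mirnome,
    simulate_mrna_counts,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Desk-scale study: 4 species x 3 libraries, 8 conserved families."""
    return SimConfig(
        seed=11,
        n_conserved_families=8,
        n_specific_per_species=4,
        nb_mean_range=(20.0, 100.0),
    )


@pytest.fixture(scope="session")
def mirnome_bundle(small_config):
    return simulate_mirnome(small_config)


@pytest.fixture(scope="session")
def specific_precursors(small_config, mirnome_bundle):
    return {
        sp: {
            pid: seq
            for pid, seq in mirnome_bundle.precursors[sp].items()
            if pid.startswith("spec_")
        }
        for sp in small_config.species
    }


@pytest.fixture(scope="session")
def genome_bundle(small_config, mirnome_bundle, specific_precursors):
    return simulate_genomes(
        small_config, mirnome_bundle.shared_precursors, specific_precursors
    )


@pytest.fixture(scope="session")
def mrna_bundle():
    return simulate_mrna_counts(SimConfig(seed=23, n_genes=300, de_fraction=0.1))
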