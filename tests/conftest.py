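import pytest

from rrhp import (
    LibraryConfig,
    detectable_sites,
    digest,
    make_genome,
    make_profile,
    size_select,
)


@pytest.fixture(scope="session")
def toy_genome():
    """Two 20 kb contigs with at least 50 planted CCGG sites each."""
    return make_genome(n_contigs=2, contig_length=20_000, target_site_count=50, seed=101)


@pytest.fixture(scope="session")
def toy_catalog(toy_genome):
    return size_select(digest(toy_genome), 40, 430)


@pytest.fixture(scope="session")
def toy_sites(toy_catalog):
    return detectable_sites(toy_catalog)


@pytest.fixture(scope="session")
def toy_profile(toy_sites):
    return make_profile(toy_sites, hmc_beta_params=(2, 5), zero_hmc_fraction=0.2, seed=202)


@pytest.fixture()
def base_config():
    return LibraryConfig(n_molecules_per_fragment=40, seed=303)
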