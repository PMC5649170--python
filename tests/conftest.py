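import pytest

from tnpquant.simulate import (SimConfig, Taxon, generate_community,
                               generate_reference_db)


def small_sim_config(**overrides) -> SimConfig:
    """A reduced community for fast unit tests: 3 taxa, 2 stations, 12 samples."""
    defaults = dict(
        seed=0,
        stations=["GS665", "GS694"],
        marine_stations=["GS694"],
        taxa=[
            Taxon("Synechococcus_BS", "Cyanobacteria", "Cyanophyceae",
                  "Chroococcales", "Synechococcus", 0.5),
            Taxon("Pelagibacter_BS", "Proteobacteria", "Alphaproteobacteria",
                  "Pelagibacterales", "Pelagibacter", 0.3),
            Taxon("Flavobacterium_BS", "Bacteroidetes", "Flavobacteriia",
                  "Flavobacteriales", "Flavobacterium", 0.2),
        ],
        n_contigs_per_taxon=4,
        contig_length_range=(6000, 9000),
        n_ref_families=3,
        refs_per_family=2,
        ref_aa_length_range=(200, 300),
        tnp_copies_per_taxon=2,
        reads_per_sample=2000,
        n_single_copy_markers=10,
        marker_length=600,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_config():
    return small_sim_config()


@pytest.fixture(scope="session")
def small_refs(small_config):
    refs, families = generate_reference_db(small_config)
    return refs, families


@pytest.fixture(scope="session")
def small_community(small_config, small_refs):
    refs, _ = small_refs
    return generate_community(small_config, refs)
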