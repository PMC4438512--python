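import pytest

from taxonog import (
    GenomeProfile,
    Lineage,
    ReferenceTaxonomy,
    SimConfig,
    build_db,
    simulate,
)


def profile(genome_id, nogs, gene_count=None):
    """Shorthand: a profile whose gene count defaults to its NOG count."""
    nogs = frozenset(nogs)
    return GenomeProfile(
        genome_id=genome_id,
        nogs=nogs,
        gene_count=gene_count if gene_count is not None else len(nogs),
        assigned_fraction=1.0 if nogs else 0.0,
    )


@pytest.fixture(scope="session")
def tiny_cfg():
    """A small but full-depth taxonomy: 3 phyla, 24 species, 48 genomes."""
    return SimConfig(
        children_per_rank=(3, 2, 2, 2, 1, 1),
        genomes_per_species=2,
        pool_size_per_node=6,
        core_pool_size=40,
        genes_per_genome=500,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_cfg):
    return simulate(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_db(tiny_world):
    ref, _ = tiny_world
    return build_db(ref)


@pytest.fixture
def three_phylum_ref():
    """The hand-computed worked example: three genomes across two phyla."""
    profiles = [
        profile("G1", {"n1", "n2", "n3"}),
        profile("G2", {"n2", "n4"}),
        profile("G3", {"n3", "n5"}),
    ]
    lineage_of = {
        "G1": Lineage.from_labels("A"),
        "G2": Lineage.from_labels("A"),
        "G3": Lineage.from_labels("B"),
    }
    return ReferenceTaxonomy(profiles=profiles, lineage_of=lineage_of)
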