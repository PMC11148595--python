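import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_taxonomy(tmp_path_factory):
    """Toy dual-kingdom taxonomy: 5 viral families, 5 bacterial genera (63 nodes)."""
    from virannot.simulate import synth_taxonomy

    return synth_taxonomy(5, 5, seed=7,
                          out_dir=tmp_path_factory.mktemp("taxdump"))


@pytest.fixture(scope="session")
def tree(fixture_taxonomy):
    return fixture_taxonomy.tree


@pytest.fixture(scope="session")
def mock_community():
    """Small seeded community shared by read-level tests."""
    from virannot.simulate import (
        MockCommunitySpec, synth_community, synth_taxonomy,
    )
    import tempfile

    tax = synth_taxonomy(4, 2, seed=7, out_dir=tempfile.mkdtemp())
    spec = MockCommunitySpec(
        viral_genomes=[(f"virus{i+1}", 3000, tax.viral_species[i], "dsDNA")
                       for i in range(4)],
        bacterial_genomes=[(f"bact{i+1}", 6000, tax.bacterial_species[i])
                           for i in range(2)],
        reads_per_genome=50, read_length=150, substitution_rate=0.01, seed=11,
    )
    from virannot.simulate import synth_community
    return tax, spec, synth_community(spec)
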