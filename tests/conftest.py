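import pytest

from capskit import enzyme_by_name, load_enzyme_table, published_fixtures


@pytest.fixture(scope="session")
def enzyme_library():
    return load_enzyme_table()


@pytest.fixture(scope="session")
def enzymes(enzyme_library):
    return {e.name: e for e in enzyme_library}


@pytest.fixture(scope="session")
def panel():
    """The four published-geometry synthetic fixtures (five assays)."""
    return published_fixtures(seed=0)


@pytest.fixture(scope="session")
def table3_counts():
    """Genotype counts reconstructed from the four-region survey table."""
    from capskit import GenotypeCounts

    return [
        GenotypeCounts("Argolida", 0, 1, 10),
        GenotypeCounts("Chania", 2, 34, 6),
        GenotypeCounts("Heraklion", 0, 8, 4),
        GenotypeCounts("Messinia", 0, 7, 0),
    ]
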