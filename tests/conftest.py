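import pytest
from importlib import resources

from kirtyper.allele_catalog import Allele, SubtypeGroup, load_frequency_table
from kirtyper.insilico_pcr import load_panel
from kirtyper.population_stats import group_frequencies
from kirtyper.synthetic_fixtures import GROUP_SNPS, make_allele_cds, make_template

TYPEABLE = (SubtypeGroup.NULL, SubtypeGroup.LOW1, SubtypeGroup.HIGH1,
            SubtypeGroup.HIGH2, SubtypeGroup.LOW2, SubtypeGroup.S1)


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def table1():
    with resources.as_file(resources.files("kirtyper.data")
                           .joinpath("table1_frequencies.tsv")) as p:
        return load_frequency_table(p)


@pytest.fixture(scope="session")
def group_freqs(table1):
    """Normalized group frequencies over the high-frequency alleles."""
    return group_frequencies(table1, min_percent=1.0).normalized().frequencies


@pytest.fixture(scope="session")
def templates():
    return {g: make_template(g) for g in TYPEABLE}


@pytest.fixture(scope="session")
def reference_alleles():
    return [Allele(name=make_template(g).allele_name, cds=make_allele_cds(g),
                   group=g) for g in TYPEABLE]
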