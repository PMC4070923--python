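import pytest
from hypothesis import settings

from mitocomp.codes import genetic_code

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from mitocomp.datasets import load_bminax_gene_table, load_class_stats


@pytest.fixture(scope="session")
def code5():
    return genetic_code(5)


@pytest.fixture(scope="session")
def bminax():
    """(features, genome_length) of the bundled B. minax annotation table."""
    return load_bminax_gene_table()


@pytest.fixture(scope="session")
def class_stats():
    return load_class_stats()
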