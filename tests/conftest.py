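import pytest

from amplimit.community import mock_community
from amplimit.io import genus_tree
from amplimit.simulate import simulate_library


@pytest.fixture(scope="session")
def spec():
    """The twelve-taxon mock community with default copy numbers."""
    return mock_community()


@pytest.fixture(scope="session")
def unit_cn_spec():
    """Same community with every 16S copy number forced to 1 (no bias)."""
    base = mock_community()
    return mock_community(
        copy_numbers={t.taxon_id: 1 for t in base.taxa}
    )


@pytest.fixture(scope="session")
def small_library(spec):
    """A 5,000-read simulated library, copy-number bias off."""
    return simulate_library(spec, 5000, seed=11, copy_number_bias=False)


@pytest.fixture(scope="session")
def tree(spec):
    """Genus-level Newick tree over the mock taxa."""
    return genus_tree(spec)
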