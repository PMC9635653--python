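import pytest

from nacfam.simulate import FamilyConfig, generate_family, generate_tree


@pytest.fixture(scope="session")
def small_family():
    """A compact synthetic family shared by read-only tests."""
    return generate_family(FamilyConfig(seed=7, n_anchor_orthologs=24, decoy_count=20))


@pytest.fixture(scope="session")
def small_tree(small_family):
    return generate_tree(small_family.truth, noise=0.0, seed=7)
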