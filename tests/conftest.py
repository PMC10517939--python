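import numpy as np
import pytest

from igtandem.fixtures import SandwichRecipe, make_ideal_sandwich, make_ideal_sheet


@pytest.fixture(scope="session")
def ig_sandwich():
    """Ideal 12-strand sandwich (6 strands of 7 residues per sheet)."""
    return make_ideal_sandwich(SandwichRecipe(6, 7, 10.0, 30.0))


@pytest.fixture(scope="session")
def small_sandwich():
    """Compact 6-strand sandwich (3 per sheet), untwisted."""
    return make_ideal_sandwich(SandwichRecipe(3, 7, 10.0, 0.0))


@pytest.fixture(scope="session")
def two_strand_sheet():
    return make_ideal_sheet(2, 5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
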