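import numpy as np
import pytest

from cdfragmap.synthetic import make_basis, make_protein, make_reference_set


@pytest.fixture(scope="session")
def basis():
    return make_basis(0)


@pytest.fixture(scope="session")
def clean_refs(basis):
    """Noise-free reference set sharing the session basis."""
    return make_reference_set(31, basis, noise_sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def default_refs(basis):
    """Reference set at the default (small) library noise."""
    return make_reference_set(31, basis, seed=0)


@pytest.fixture(scope="session")
def small_protein(basis):
    """A reduced-scale synthetic protein for fast structural tests."""
    return make_protein(n_residues=120, n_helices=6, n_strands=3,
                        n_fragments=4, noise_sigma=0.05,
                        non_native_fragment=2, basis=basis, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
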