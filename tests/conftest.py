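import numpy as np
import pytest

from oxsar import chemistry as chem
from oxsar import synthetic_data as sd


@pytest.fixture(scope="session")
def small_library():
    """A 300-compound synthetic library shared across tests (fixed seed)."""
    return sd.generate_library(sd.SyntheticLibrarySpec(n_compounds=300, seed=7))


@pytest.fixture(scope="session")
def small_fps(small_library):
    return chem.fingerprint_matrix(small_library["smiles"], chem.FCFP4_1024)


@pytest.fixture(scope="session")
def small_fps_model(small_library):
    return chem.fingerprint_matrix(small_library["smiles"], chem.FCFP6_2048)


@pytest.fixture(scope="session")
def toy_separable():
    """Linearly separable 2-feature toy problem (40 points)."""
    rng = np.random.default_rng(0)
    X0 = rng.normal(loc=[-2.0, -2.0], scale=0.4, size=(20, 2))
    X1 = rng.normal(loc=[2.0, 2.0], scale=0.4, size=(20, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * 20 + [1] * 20)
    return X, y
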