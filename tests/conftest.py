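import numpy as np
import pytest

from nucdock.fixtures import DuplexSpec, build_aform_duplex, duplex_partners


@pytest.fixture(scope="session")
def duplex_spec():
    return DuplexSpec("GGGGCCCC")


@pytest.fixture(scope="session")
def duplex(duplex_spec):
    return build_aform_duplex(duplex_spec)


@pytest.fixture(scope="session")
def partners(duplex_spec):
    """(receptor, ligand) = chains A and B of the 8-bp fixture duplex."""
    return duplex_partners(duplex_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR-based)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
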