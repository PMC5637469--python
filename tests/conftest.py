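import numpy as np
import pytest

from delselect.library import TINY_ARCHITECTURE, LibraryArchitecture


@pytest.fixture(scope="session")
def arch() -> LibraryArchitecture:
    """Default 18+12+18 architecture with the EcoRV-bearing spike."""
    return LibraryArchitecture()


@pytest.fixture(scope="session")
def tiny_arch() -> LibraryArchitecture:
    """Miniature 6+2+6 architecture covering a 16-barcode space."""
    return TINY_ARCHITECTURE


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250925)
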