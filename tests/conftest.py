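import numpy as np
import pytest

import puckerfit as pf


@pytest.fixture(scope="session")
def test_set():
    """The 24 synthetic fluoro/hydroxy furanose templates."""
    return pf.build_test_set()


@pytest.fixture(scope="session")
def by_name(test_set):
    return {t.name: t for t in test_set}


@pytest.fixture(scope="session")
def params():
    """GAFF-like starting parameters."""
    return pf.default_parameters()


@pytest.fixture(scope="session")
def tpl_fluoro(test_set):
    """Mono-fluoro template (no rotatable exocyclic torsions)."""
    return test_set[0]


@pytest.fixture(scope="session")
def tpl_mixed(test_set):
    """2'-F / 3'-OH template: carries all vicinal F/OH dihedral classes."""
    return test_set[8]


@pytest.fixture(scope="session")
def scan_mixed(tpl_mixed):
    """Standard 18-degree scan of the mixed template (20 frames)."""
    return pf.scan_pseudorotation(tpl_mixed, pf.ScanSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
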