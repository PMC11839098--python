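import numpy as np
import pytest

from condensaxs import chains


@pytest.fixture(scope="session")
def library():
    return chains.load_suite_library()


@pytest.fixture(scope="session")
def small_pool(library):
    """A small clash-screened pool of 30-mers shared across tests."""
    return chains.sample_pool("U" * 30, chains.SuiteWeights.uniform(34), library,
                              n_conformers=4, seed=12)


@pytest.fixture(scope="session")
def aform_chain(library):
    """30-mer built from one A-form-like suite repeated 29 times."""
    return chains.build_chain("A" * 30, ["1a"] * 29, library)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
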