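import numpy as np
import pytest
from hypothesis import settings

import heteroseek as hs

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundled_ref():
    return hs.load_bundled_reference()


@pytest.fixture(scope="session")
def bundled_map():
    return hs.load_bundled_gene_map()


@pytest.fixture(scope="session")
def small_ref():
    """A 2,000 bp random circular reference for fast unit tests."""
    return hs.make_reference(2000, seed=42, name="toy_mt")


def make_read(rid, sequence, q=35):
    return hs.Read(id=rid, sequence=sequence, qualities=np.full(len(sequence), q, dtype=np.int16))


@pytest.fixture
def read_factory():
    return make_read
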