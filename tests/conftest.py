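import numpy as np
import pytest

from loopwalk.descriptors import DescriptorTable


@pytest.fixture(scope="session")
def table() -> DescriptorTable:
    """The packaged 13-descriptor table (session-wide; it is immutable)."""
    return DescriptorTable.paper_set()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
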