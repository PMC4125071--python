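import pytest

from synmem.patterns import generate_prototypes


@pytest.fixture(scope="session")
def small_patterns():
    """A small Bernoulli pattern set shared by read-only tests."""
    return generate_prototypes(200, 20, f=0.1, seed=11)
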