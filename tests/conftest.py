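import pytest

from coccohv.iontheory import load_solutions


@pytest.fixture(scope="session")
def solutions():
    return load_solutions()
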