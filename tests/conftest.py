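import pytest

from mapkflow import build_n1, build_n2


@pytest.fixture(scope="session")
def n1():
    return build_n1()


@pytest.fixture(scope="session")
def n2():
    return build_n2()
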