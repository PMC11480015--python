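import pytest

from kvclamp.channels import SolutionSpec, load_preset


@pytest.fixture(scope="session")
def wt():
    return load_preset("wt")


@pytest.fixture(scope="session")
def e675k():
    return load_preset("e675k")


@pytest.fixture(scope="session")
def m1i():
    return load_preset("m1i")


@pytest.fixture(scope="session")
def solution_2mm():
    return SolutionSpec(kex=2.0)
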