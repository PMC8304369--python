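import pytest

from tapkit.demo import demo_library, demo_rules


@pytest.fixture(scope="session")
def library():
    return demo_library()


@pytest.fixture(scope="session")
def rules_v3():
    return demo_rules("v3")


@pytest.fixture(scope="session")
def rules_v2():
    return demo_rules("v2")
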