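import pytest

from ctmotif.core import CTNetwork


@pytest.fixture
def tiny_net() -> CTNetwork:
    """{(c1,t1), (c1,t2), (c2,t1)} — the hand-counted degree fixture."""
    return CTNetwork.from_edges([("c1", "t1"), ("c1", "t2"), ("c2", "t1")])


@pytest.fixture
def star_net() -> CTNetwork:
    """c1 connected to t1..t5."""
    return CTNetwork.from_edges([("c1", f"t{i}") for i in range(1, 6)])
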