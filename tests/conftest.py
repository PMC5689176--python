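import math

import pytest
from hypothesis import settings

from anchornet.netio import PDI, PPI, Edge, InteractionNetwork
from anchornet.reconstruct import RootedInstance

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def diamond_net():
    """a-x-t (costs 1, 1) versus a-y-t (costs 3, 3)."""
    e1 = math.exp(-1.0)
    e3 = math.exp(-3.0)
    return InteractionNetwork(
        [
            Edge("a", "x", e1),
            Edge("t", "x", e1),
            Edge("a", "y", e3),
            Edge("t", "y", e3),
        ]
    )


@pytest.fixture
def diamond_inst(diamond_net):
    return RootedInstance.build(diamond_net, {"a"}, {"t"}, alpha=0.25)


@pytest.fixture
def mixed_net():
    """Small mixed PPI/PDI network used across modules."""
    return InteractionNetwork(
        [
            Edge("A", "B", 0.9, PPI),
            Edge("B", "C", 0.8, PPI),
            Edge("C", "D", 0.7, PPI),
            Edge("B", "E", 0.6, PDI),
            Edge("E", "F", 0.5, PPI),
            Edge("A", "D", 0.4, PPI),
        ]
    )
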