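import pytest
from hypothesis import HealthCheck, settings

from pdgene.network import InteractionNetwork

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def five_node_net():
    """Edges {A-B, B-C, C-D, D-E, A-E, B-E}."""
    net = InteractionNetwork()
    for a, b in [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("A", "E"), ("B", "E")]:
        net.add_edge(a, b, 0.9)
    return net
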