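import pytest

from ctln.digraph import base_graph, enumerate_oriented_nosink
from ctln.network import CTLNParams


@pytest.fixture(scope="session")
def std():
    return CTLNParams.standard()


@pytest.fixture(scope="session")
def fig3_graph():
    """3-cycle feeding a sink: edges 12, 23, 31, 34 (the T base graph)."""
    return base_graph("T")


@pytest.fixture(scope="session")
def census_graphs_n5():
    """All 152 oriented no-sink graphs on 5 vertices, one per iso class."""
    return enumerate_oriented_nosink(5)


@pytest.fixture(scope="session")
def nosink_graphs_upto4():
    """The 8 oriented no-sink graphs on n <= 4 vertices."""
    out = []
    for n in (1, 2, 3, 4):
        out.extend(enumerate_oriented_nosink(n))
    return [G for G in out if not G.sinks()]
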