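import networkx as nx
import pytest

from hubnet.prioritize import NodeStats

# Degree / betweenness rows of the five published hub genes.
TABLE1_STATS = [
    NodeStats("IL6", 77, 0.10995103),
    NodeStats("VEGFA", 61, 0.09511043),
    NodeStats("IL1B", 61, 0.05885691),
    NodeStats("TNF", 62, 0.05394098),
    NodeStats("PTGS2", 49, 0.05242533),
]

# Published retention-frequency table: level -> (per-hub frequencies,
# accuracy, number of test networks).
TABLE2_ROWS = {
    1: ((21, 21, 21, 21, 20), 0.945, 22),
    2: ((20, 20, 20, 19, 20), 0.792, 25),
    3: ((20, 23, 18, 17, 9), 0.696, 25),
    4: ((20, 23, 18, 19, 4), 0.672, 25),
}


@pytest.fixture
def table1_stats():
    return list(TABLE1_STATS)


@pytest.fixture
def path3():
    return nx.path_graph(["A", "B", "C"])


@pytest.fixture
def star5():
    g = nx.star_graph(4)
    return nx.relabel_nodes(g, {0: "H", 1: "L1", 2: "L2", 3: "L3", 4: "L4"})
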