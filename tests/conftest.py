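import numpy as np
import pytest

from erfusion.graph import ERGraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_graph():
    """A small two-entity graph with a binary main relation and a drug-drug
    self-relation, used by model/trainer unit tests."""
    g = ERGraph()
    g.add_entity("drug", 12, embedding_dim=4, module_depth=2, module_width=5)
    g.add_entity("protein", 9, embedding_dim=3, module_depth=3, module_width=6)
    cells = np.array([[0, 0], [1, 2], [3, 5], [7, 8], [11, 0], [2, 2]])
    vals = np.array([1.0, 0, 1, 0, 1, 1])
    g.add_relation("dti", "drug", "protein", cells, vals, task="binary", main=True)
    sc = np.array([[0, 1], [2, 3], [4, 5], [1, 0]])
    g.add_relation("dsim", "drug", "drug", sc, np.array([0.2, 0.8, 0.5, 0.1]),
                   task="regression", loss_id="mse", weight=0.7)
    return g
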