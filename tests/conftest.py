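import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from lncnet.synthetic import GeneratorConfig, generate_all


@pytest.fixture(scope="session")
def default_bundle():
    """One fully generated study at the default conditions."""
    return generate_all(GeneratorConfig(seed=17))


@pytest.fixture(scope="session")
def small_config():
    """A down-scaled study used where full size adds nothing."""
    return GeneratorConfig(n_coding=300, n_lnc=60, frac_de=0.2,
                           module_count=3, module_size=6, seed=5)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_all(small_config)


@pytest.fixture()
def bridged_cliques():
    """Two 6-cliques joined by a single bridge edge."""
    graph = nx.union(nx.complete_graph([f"a{i}" for i in range(6)]),
                     nx.complete_graph([f"b{i}" for i in range(6)]))
    graph.add_edge("a0", "b0")
    return graph
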