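import itertools

import networkx as nx
import numpy as np
import pytest

from cmnet.corpus import Corpus, EdgeBag, Vocabulary
from cmnet.io import GenomicInterval, Interaction


@pytest.fixture
def diamond_graph():
    """A-C-B and A-D-B: two shortest paths between A and B."""
    g = nx.Graph()
    g.add_edges_from([("A", "C"), ("C", "B"), ("A", "D"), ("D", "B")])
    return g


@pytest.fixture
def small_interaction():
    return Interaction(
        "L1", GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 5000, 5100)
    )


def make_corpus(bag_tokens, vocab_size):
    """Corpus from a list of {token: count} dicts over a synthetic vocabulary."""
    from cmnet.simulate import make_pair_vocabulary

    vocab = make_pair_vocabulary(vocab_size)
    bags = [EdgeBag(f"I{i + 1}", dict(c)) for i, c in enumerate(bag_tokens)]
    return Corpus(vocabulary=vocab, bags=bags)


@pytest.fixture
def module_reference():
    """Four 5-cliques with a few random bridges; used by permutation tests."""
    rng = np.random.default_rng(0)
    graph = nx.Graph()
    modules = [[f"M{m}N{i}" for i in range(5)] for m in range(4)]
    for module in modules:
        graph.add_edges_from(itertools.combinations(module, 2))
    nodes = [n for module in modules for n in module]
    for _ in range(8):
        a, b = rng.choice(len(nodes), 2, replace=False)
        if nodes[a] != nodes[b]:
            graph.add_edge(nodes[a], nodes[b])
    return graph, modules
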