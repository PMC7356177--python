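"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by a method unrelated to the
implementation it checks: exhaustive subset search for k-cores, the
literal step-up definition for Benjamini-Hochberg, and complete
enumeration of draws for the hypergeometric tail.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import networkx as nx
import numpy as np


def k_core_exhaustive(graph: nx.Graph, k: int) -> set:
    """The k-core as the union of every node subset whose induced
    subgraph has minimum degree >= k (bitmask search, n <= ~16)."""
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    adjacency = [0] * len(nodes)
    for a, b in graph.edges:
        adjacency[index[a]] |= 1 << index[b]
        adjacency[index[b]] |= 1 << index[a]
    union = 0
    for subset in range(1, 1 << len(nodes)):
        bits = subset
        valid = True
        while bits:
            i = (bits & -bits).bit_length() - 1
            if (adjacency[i] & subset).bit_count() < k:
                valid = False
                break
            bits &= bits - 1
        if valid:
            union |= subset
    return {nodes[i] for i in range(len(nodes)) if union >> i & 1}


def bh_step_up(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values straight from the step-up definition:
    after sorting, q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(
            min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hypergeom_tail_enumeration(n_universe: int, n_set: int, n_query: int,
                               k_min: int) -> float:
    """P[overlap >= k_min] by counting every possible draw of
    ``n_query`` items from a universe with ``n_set`` marked items."""
    universe = range(n_universe)
    marked = set(range(n_set))
    hits = sum(
        1 for draw in combinations(universe, n_query)
        if len(marked.intersection(draw)) >= k_min)
    return hits / comb(n_universe, n_query)
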