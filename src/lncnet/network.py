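"""DEG interaction network and MCODE-style dense-module detection.

The module detector follows the molecular-complex-detection scheme:

1. *Vertex weighting.* Each node is weighted by ``k * density`` of the
   highest (largest-``k`` non-empty) k-core of its closed neighborhood,
   where density of a graph with ``n`` nodes and ``m`` edges is
   ``2m / (n (n - 1))`` (0 when ``n < 2``).
2. *Seeded growth.* The highest-weight unclaimed node seeds a candidate;
   neighbors join (transitively, to a fixpoint) when their weight strictly
   exceeds ``seed_weight * (1 - node_score_cutoff)`` AND they are linked to
   the current candidate by at least two edges (the coherence check; the
   very first addition to a single-node candidate is exempt). The coherence
   check keeps a single bridge edge from fusing two dense regions that a
   pure weight threshold cannot separate. Every grown node is claimed, so
   modules are pairwise node-disjoint.
3. *Post-processing.* With ``haircut`` the candidate is reduced to its
   2-core; candidates lacking a non-empty ``k_core_filter``-core are
   discarded. ``score = density * size``; labels M1, M2, ... follow
   descending score with deterministic tie-breaks (larger size, then
   lexicographically smallest member).

All tie-breaks are deterministic, so detection is reproducible and
independent of node insertion order.
"""

from __future__ import annotations

import networkx as nx

from .data import GeneModule
from .errors import ParameterError


def induce_deg_network(network: nx.Graph, degs: set[str]) -> nx.Graph:
    """Subgraph induced on the DEGs present in the network."""
    return network.subgraph(set(network.nodes) & set(degs)).copy()


def count_connected(network: nx.Graph) -> int:
    """Number of nodes with degree >= 1."""
    return sum(1 for _, d in network.degree() if d >= 1)


def graph_density(n_nodes: int, n_edges: int) -> float:
    """Edge density 2m / (n (n - 1)); defined as 0 when n < 2."""
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def k_core(network: nx.Graph, k: int) -> nx.Graph:
    """Maximal subgraph in which every node has degree >= k, by peeling.

    Iteratively removes nodes of degree < k until none remain; the result
    is the unique maximal such subgraph (possibly empty).
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    degree = dict(network.degree())
    stack = [n for n, d in degree.items() if d < k]
    removed = set(stack)
    while stack:
        node = stack.pop()
        for nb in network[node]:
            if nb not in removed:
                degree[nb] -= 1
                if degree[nb] < k:
                    removed.add(nb)
                    stack.append(nb)
    return network.subgraph(set(network.nodes) - removed).copy()


def _highest_core(network: nx.Graph) -> tuple[int, nx.Graph]:
    """(k, core) for the largest k with a non-empty k-core; (0, G) if G
    has no edges."""
    if network.number_of_edges() == 0:
        return 0, network
    k, core = 1, k_core(network, 1)
    while True:
        nxt = k_core(core, k + 1)
        if nxt.number_of_nodes() == 0:
            return k, core
        k, core = k + 1, nxt


def vertex_weights(network: nx.Graph) -> dict[str, float]:
    """MCODE vertex weights: highest-core ``k`` x that core's density,
    computed on each node's closed neighborhood."""
    weights: dict[str, float] = {}
    for v in network.nodes:
        closed = set(network[v]) | {v}
        nbhd = network.subgraph(closed)
        k, core = _highest_core(nbhd)
        weights[v] = k * graph_density(core.number_of_nodes(),
                                       core.number_of_edges())
    return weights


def _grow_candidate(network: nx.Graph, weights: dict[str, float], seed: str,
                    threshold: float, used: set[str]) -> set[str]:
    candidate = {seed}
    changed = True
    while changed:
        changed = False
        frontier = sorted(
            {nb for node in candidate for nb in network[node]}
            - candidate - used)
        for u in frontier:
            if weights[u] <= threshold:
                continue
            links = sum(1 for nb in network[u] if nb in candidate)
            if len(candidate) == 1 or links >= 2:
                candidate.add(u)
                changed = True
    return candidate


def find_modules(network: nx.Graph, k_core_filter: int = 4,
                 node_score_cutoff: float = 0.2, haircut: bool = True,
                 fluff: bool = False, fluff_density: float = 0.1
                 ) -> list[GeneModule]:
    """Detect dense, node-disjoint gene modules.

    Parameters
    ----------
    k_core_filter
        Each reported module must contain a non-empty k-core at this k
        (default 4, the usual setting for PPI complexes).
    node_score_cutoff
        Fractional weight tolerance for growth: neighbors join when their
        weight exceeds ``seed_weight * (1 - cutoff)``.
    haircut
        Reduce each candidate to its 2-core, so every member keeps
        within-module degree >= 2.
    fluff
        Optionally append peripheral neighbors whose closed-neighborhood
        density exceeds ``fluff_density``; off by default because fluffed
        nodes may be shared, breaking module disjointness.
    """
    if not 0 <= node_score_cutoff < 1:
        raise ParameterError(
            f"node_score_cutoff must be in [0, 1), got {node_score_cutoff}")
    if k_core_filter < 1:
        raise ParameterError(f"k_core_filter must be >= 1, got {k_core_filter}")
    weights = vertex_weights(network)
    used: set[str] = set()
    kept: list[tuple[str, frozenset[str]]] = []
    for seed in sorted(network.nodes, key=lambda n: (-weights[n], n)):
        if seed in used or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        candidate = _grow_candidate(network, weights, seed, threshold, used)
        used |= candidate
        members = set(candidate)
        if haircut:
            members = set(k_core(network.subgraph(members), 2).nodes)
        if len(members) < 2:
            continue
        if k_core(network.subgraph(members), k_core_filter).number_of_nodes() == 0:
            continue
        kept.append((seed, frozenset(members)))

    if fluff:
        fluffed = []
        core_nodes = {n for _, m in kept for n in m}
        for seed, members in kept:
            extra = set()
            neighbors = {nb for n in members for nb in network[n]}
            for u in sorted(neighbors - members - core_nodes):
                closed = set(network[u]) | {u}
                sub = network.subgraph(closed)
                if graph_density(sub.number_of_nodes(),
                                 sub.number_of_edges()) > fluff_density:
                    extra.add(u)
            fluffed.append((seed, frozenset(members | extra)))
        kept = fluffed

    modules = []
    for seed, members in kept:
        sub = network.subgraph(members)
        density = graph_density(sub.number_of_nodes(), sub.number_of_edges())
        modules.append((seed, members, density, density * len(members)))
    modules.sort(key=lambda t: (-t[3], -len(t[1]), min(t[1])))
    return [
        GeneModule(label=f"M{i}", members=members, seed_gene=seed,
                   density=density, score=score)
        for i, (seed, members, density, score) in enumerate(modules, start=1)
    ]
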