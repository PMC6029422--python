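"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own algorithms:
equivalence classes are found by brute-force enumeration of edge
orientations, confusion matrices by explicit loops over node pairs.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pytest

from copcida.graph_core import (
    DIRECTED,
    MixedGraph,
    TieredVariableSet,
    UNDIRECTED,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_vars(n: int, tier=None, outcome=None) -> TieredVariableSet:
    names = [f"x{i}" for i in range(n)]
    tiers = None if tier is None else {f"x{i}": t for i, t in enumerate(tier)}
    return TieredVariableSet.from_names(names, tier=tiers, outcome=outcome)


def random_dag(rng, n_nodes: int, edge_prob: float = 0.35) -> MixedGraph:
    """Random DAG over a random topological order of n nodes."""
    variables = make_vars(n_nodes)
    order = list(variables.names)
    rng.shuffle(order)
    g = MixedGraph(variables)
    for i, j in combinations(range(n_nodes), 2):
        if rng.random() < edge_prob:
            g.add_directed(order[i], order[j])
    return g


def _is_acyclic(nodes, directed_edges) -> bool:
    # Kahn's algorithm on plain edge tuples
    out = {v: set() for v in nodes}
    indeg = {v: 0 for v in nodes}
    for a, b in directed_edges:
        if b not in out[a]:
            out[a].add(b)
            indeg[b] += 1
    queue = [v for v in nodes if indeg[v] == 0]
    seen = 0
    while queue:
        v = queue.pop()
        seen += 1
        for w in out[v]:
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
    return seen == len(nodes)


def _v_structures_of(nodes, directed_edges, adjacency) -> frozenset:
    pa = {v: set() for v in nodes}
    for a, b in directed_edges:
        pa[b].add(a)
    out = set()
    for b in nodes:
        for a, c in combinations(sorted(pa[b]), 2):
            if frozenset((a, c)) not in adjacency:
                out.add((a, b, c))
    return frozenset(out)


def enumerate_equivalent_dags(dag: MixedGraph) -> list[frozenset]:
    """All DAGs sharing ``dag``'s skeleton and v-structures, each returned
    as a frozenset of directed (tail, head) pairs.  Brute force: orient
    every skeleton edge both ways and filter."""
    nodes = list(dag.variables.names)
    skel = [tuple(sorted(p)) for p in dag.adjacency_pairs()]
    skel.sort()
    adjacency = {frozenset(p) for p in skel}
    target = _v_structures_of(
        nodes, [(a, b) for a, b, m in dag.edges() if m == DIRECTED], adjacency
    )
    out = []
    for choice in product((0, 1), repeat=len(skel)):
        edges = [
            (a, b) if c == 0 else (b, a) for (a, b), c in zip(skel, choice)
        ]
        if not _is_acyclic(nodes, edges):
            continue
        if _v_structures_of(nodes, edges, adjacency) != target:
            continue
        out.append(frozenset(edges))
    return out


def cpdag_by_enumeration(dag: MixedGraph) -> MixedGraph:
    """Oracle CPDAG: edge directed iff every equivalent DAG agrees."""
    members = enumerate_equivalent_dags(dag)
    out = MixedGraph(dag.variables)
    for pair in dag.adjacency_pairs():
        a, b = sorted(pair)
        fwd = all((a, b) in m for m in members)
        bwd = all((b, a) in m for m in members)
        if fwd:
            out.add_directed(a, b)
        elif bwd:
            out.add_directed(b, a)
        else:
            out.add_undirected(a, b)
    return out


def enumerate_cpdag_extensions(cpdag: MixedGraph) -> list[frozenset]:
    """All consistent DAG extensions of a CPDAG: orient the undirected
    edges every way, keep orientations that are acyclic and add no new
    v-structure."""
    nodes = list(cpdag.variables.names)
    directed = [(a, b) for a, b, m in cpdag.edges() if m == DIRECTED]
    undirected = [(a, b) for a, b, m in cpdag.edges() if m == UNDIRECTED]
    adjacency = cpdag.adjacency_pairs()
    target = _v_structures_of(nodes, directed, adjacency)
    out = []
    for choice in product((0, 1), repeat=len(undirected)):
        extra = [
            (a, b) if c == 0 else (b, a) for (a, b), c in zip(undirected, choice)
        ]
        edges = directed + extra
        if not _is_acyclic(nodes, edges):
            continue
        if _v_structures_of(nodes, edges, adjacency) != target:
            continue
        out.append(frozenset(edges))
    return out


def relabel_graph(g: MixedGraph, mapping: dict[str, str]) -> MixedGraph:
    variables = g.variables
    new_vars = TieredVariableSet(
        names=tuple(mapping[v] for v in variables.names),
        tier={mapping[v]: variables.tier[v] for v in variables.names},
        role={mapping[v]: variables.role[v] for v in variables.names},
    )
    out = MixedGraph(new_vars)
    for a, b, mark in g.edges():
        if mark == DIRECTED:
            out.add_directed(mapping[a], mapping[b])
        else:
            out.add_undirected(mapping[a], mapping[b])
    return out
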