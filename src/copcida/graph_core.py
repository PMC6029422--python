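"""Graph data model for tiered causal structure learning.

Provides the mixed (partially directed) graph container used throughout the
package, Markov-equivalence operations (DAG -> CPDAG, Meek orientation
rules), structure-comparison metrics (sensitivity/specificity over
adjacencies, structural Hamming distance) and edge aggregation across
resampled CPDAGs.

Variables live in a :class:`TieredVariableSet`: each variable carries a
non-negative integer *tier* (the visit index of a repeated measurement) and
a role, either ``covariate`` or ``outcome``.  The binary outcome, when
present, must occupy a tier strictly above every covariate: it is measured
after all exposures.
"""

from __future__ import annotations

import csv
import logging
import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

logger = logging.getLogger(__name__)

DIRECTED = "directed"
UNDIRECTED = "undirected"

COVARIATE = "covariate"
OUTCOME = "outcome"


class GraphError(ValueError):
    """Invalid graph input (cycles, node mismatches, malformed edges)."""


@dataclass(frozen=True)
class TieredVariableSet:
    """Ordered variable names with visit tiers and covariate/outcome roles.

    Parameters
    ----------
    names
        Unique variable identifiers, in a fixed (column) order.
    tier
        Map name -> non-negative integer visit index.  Variables measured
        at the same visit share a tier; the outcome sits strictly above
        all covariate tiers.
    role
        Map name -> ``"covariate"`` or ``"outcome"``.  At most one outcome.
    """

    names: tuple[str, ...]
    tier: Mapping[str, int]
    role: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("variable names must be unique")
        missing = [v for v in self.names if v not in self.tier or v not in self.role]
        if missing:
            raise ValueError(f"variables without tier/role: {missing}")
        bad_tier = [v for v in self.names if int(self.tier[v]) < 0]
        if bad_tier:
            raise ValueError(f"negative tiers for: {bad_tier}")
        outcomes = [v for v in self.names if self.role[v] == OUTCOME]
        if len(outcomes) > 1:
            raise ValueError(f"at most one outcome variable allowed, got {outcomes}")
        if outcomes:
            y = outcomes[0]
            cov_tiers = [self.tier[v] for v in self.names if v != y]
            if cov_tiers and self.tier[y] <= max(cov_tiers):
                raise ValueError(
                    "outcome tier must be strictly greater than every covariate tier"
                )

    @classmethod
    def from_names(
        cls,
        names: Sequence[str],
        tier: Mapping[str, int] | None = None,
        outcome: str | None = None,
    ) -> "TieredVariableSet":
        """Build a variable set; with no tier map all covariates share tier 0.

        If ``outcome`` is given without an explicit tier it is placed one
        tier above the maximal covariate tier.
        """
        names = tuple(names)
        tiers = dict(tier) if tier is not None else {v: 0 for v in names}
        roles = {v: COVARIATE for v in names}
        if outcome is not None:
            if outcome not in names:
                raise ValueError(f"outcome {outcome!r} not among variable names")
            roles[outcome] = OUTCOME
            cov_tiers = [tiers.get(v, 0) for v in names if v != outcome]
            if outcome not in tiers or (
                cov_tiers and tiers[outcome] <= max(cov_tiers)
            ):
                tiers[outcome] = (max(cov_tiers) if cov_tiers else 0) + 1
        for v in names:
            tiers.setdefault(v, 0)
        return cls(names=names, tier=tiers, role=roles)

    @property
    def outcome(self) -> str | None:
        for v in self.names:
            if self.role[v] == OUTCOME:
                return v
        return None

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(v for v in self.names if self.role[v] == COVARIATE)

    @property
    def tiers(self) -> tuple[int, ...]:
        return tuple(sorted({self.tier[v] for v in self.names}))

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)


class MixedGraph:
    """Partially directed graph: at most one edge, directed or undirected,
    per unordered pair; no self loops.

    The same container serves as initial graph, skeleton, PDAG, CPDAG and
    DAG at different stages of the pipeline.
    """

    def __init__(self, variables: TieredVariableSet):
        self.variables = variables
        self._parents: dict[str, set[str]] = {v: set() for v in variables}
        self._children: dict[str, set[str]] = {v: set() for v in variables}
        self._undirected: dict[str, set[str]] = {v: set() for v in variables}

    # -- construction -------------------------------------------------
    @classmethod
    def complete_undirected(cls, variables: TieredVariableSet) -> "MixedGraph":
        g = cls(variables)
        for a, b in combinations(variables.names, 2):
            g.add_undirected(a, b)
        return g

    @classmethod
    def from_edges(
        cls,
        variables: TieredVariableSet,
        directed: Iterable[tuple[str, str]] = (),
        undirected: Iterable[tuple[str, str]] = (),
    ) -> "MixedGraph":
        g = cls(variables)
        for a, b in directed:
            g.add_directed(a, b)
        for a, b in undirected:
            g.add_undirected(a, b)
        return g

    def copy(self) -> "MixedGraph":
        g = MixedGraph(self.variables)
        for v in self.variables:
            g._parents[v] = set(self._parents[v])
            g._children[v] = set(self._children[v])
            g._undirected[v] = set(self._undirected[v])
        return g

    # -- mutation ------------------------------------------------------
    def _check_pair(self, a: str, b: str) -> None:
        if a == b:
            raise GraphError(f"self loop at {a!r}")
        if a not in self._parents or b not in self._parents:
            raise GraphError(f"unknown variable in edge ({a!r}, {b!r})")

    def add_directed(self, a: str, b: str) -> None:
        """Add a -> b, replacing any existing edge on the pair."""
        self._check_pair(a, b)
        self.remove_edge(a, b)
        self._children[a].add(b)
        self._parents[b].add(a)

    def add_undirected(self, a: str, b: str) -> None:
        """Add a - b, replacing any existing edge on the pair."""
        self._check_pair(a, b)
        self.remove_edge(a, b)
        self._undirected[a].add(b)
        self._undirected[b].add(a)

    def remove_edge(self, a: str, b: str) -> None:
        self._check_pair(a, b)
        self._children[a].discard(b)
        self._children[b].discard(a)
        self._parents[a].discard(b)
        self._parents[b].discard(a)
        self._undirected[a].discard(b)
        self._undirected[b].discard(a)

    def orient(self, a: str, b: str) -> None:
        """Turn the undirected edge a - b into a -> b."""
        if b not in self._undirected.get(a, ()):
            raise GraphError(f"no undirected edge between {a!r} and {b!r}")
        self._undirected[a].discard(b)
        self._undirected[b].discard(a)
        self._children[a].add(b)
        self._parents[b].add(a)

    # -- queries -------------------------------------------------------
    def mark(self, a: str, b: str) -> str | None:
        """Edge mark on the ordered pair: 'directed' if a -> b, 'undirected'
        if a - b, None if b -> a or no edge."""
        if b in self._children[a]:
            return DIRECTED
        if b in self._undirected[a]:
            return UNDIRECTED
        return None

    def is_adjacent(self, a: str, b: str) -> bool:
        return (
            b in self._children[a]
            or b in self._parents[a]
            or b in self._undirected[a]
        )

    def has_directed(self, a: str, b: str) -> bool:
        return b in self._children[a]

    def has_undirected(self, a: str, b: str) -> bool:
        return b in self._undirected[a]

    def parents(self, v: str) -> set[str]:
        return set(self._parents[v])

    def children(self, v: str) -> set[str]:
        return set(self._children[v])

    def undirected_neighbors(self, v: str) -> set[str]:
        return set(self._undirected[v])

    def adjacent(self, v: str) -> set[str]:
        return self._parents[v] | self._children[v] | self._undirected[v]

    def edges(self) -> list[tuple[str, str, str]]:
        """Deterministic edge list: directed as (tail, head, 'directed'),
        undirected as (min, max, 'undirected')."""
        out: list[tuple[str, str, str]] = []
        for a in self.variables:
            for b in sorted(self._children[a]):
                out.append((a, b, DIRECTED))
            for b in sorted(self._undirected[a]):
                if a < b:
                    out.append((a, b, UNDIRECTED))
        out.sort()
        return out

    def adjacency_pairs(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b, _ in self.edges()}

    @property
    def n_edges(self) -> int:
        return len(self.edges())

    def is_fully_directed(self) -> bool:
        return all(not nbrs for nbrs in self._undirected.values())

    def directed_part_is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.directed_view())

    def directed_view(self) -> nx.DiGraph:
        """networkx DiGraph over the directed edges only (all nodes kept)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.variables.names)
        for a in self.variables:
            for b in self._children[a]:
                g.add_edge(a, b)
        return g

    def has_directed_path(self, a: str, b: str) -> bool:
        """Is b reachable from a following directed edges only?"""
        seen = {a}
        stack = [a]
        while stack:
            u = stack.pop()
            if u == b:
                return True
            for w in self._children[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MixedGraph):
            return NotImplemented
        return (
            self.variables.names == other.variables.names
            and self.edges() == other.edges()
        )

    def __repr__(self) -> str:
        return f"MixedGraph({len(self.variables)} nodes, {self.n_edges} edges)"


@dataclass
class WeightedDAG:
    """Fully directed acyclic MixedGraph with real edge weights.

    When the node set is tiered every edge must respect tiers
    (tail tier <= head tier)."""

    graph: MixedGraph
    weight: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.graph.is_fully_directed():
            raise GraphError("WeightedDAG requires only directed edges")
        if not self.graph.directed_part_is_acyclic():
            raise GraphError("WeightedDAG must be acyclic")
        tier = self.graph.variables.tier
        for a, b, _ in self.graph.edges():
            if tier[a] > tier[b]:
                raise GraphError(f"edge {a}->{b} violates tier order")
            if (a, b) not in self.weight:
                raise GraphError(f"edge {a}->{b} has no weight")

    def topological_order(self) -> list[str]:
        order = list(nx.lexicographical_topological_sort(self.graph.directed_view()))
        return order


@dataclass(frozen=True)
class StructureMetrics:
    """Adjacency-level confusion summary of an estimated graph vs truth.

    Sensitivity and specificity are computed over unordered node pairs:
    a pair counts as positive when the two nodes are adjacent (any mark).
    """

    sensitivity: float
    specificity: float
    shd: int
    n_directed: int
    n_undirected: int
    n_nonchronological: int
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0


def _require_same_nodes(a: MixedGraph, b: MixedGraph) -> None:
    if set(a.variables.names) != set(b.variables.names):
        raise GraphError("graphs have different node sets")


# ---------------------------------------------------------------------------
# Markov equivalence operations
# ---------------------------------------------------------------------------

def find_v_structures(dag: MixedGraph) -> list[tuple[str, str, str]]:
    """Unshielded colliders a -> b <- c (a, c non-adjacent), a < c."""
    out = []
    for b in dag.variables:
        pas = sorted(dag.parents(b))
        for a, c in combinations(pas, 2):
            if not dag.is_adjacent(a, c):
                out.append((a, b, c))
    return out


def meek_closure(
    pdag: MixedGraph, fixed: set[tuple[str, str]] | None = None
) -> MixedGraph:
    """Apply Meek's orientation rules R1-R3 to a fixpoint.

    R1: a -> b, b - c, a and c non-adjacent        =>  b -> c
    R2: a -> c -> b, a - b                          =>  a -> b
    R3: a - c -> b, a - d -> b, c,d non-adjacent,
        a - b                                       =>  a -> b

    ``fixed`` edges are background knowledge (e.g. chronologically
    pre-directed edges); an orientation that would reverse one, or create
    a directed cycle, is skipped with a warning — finite-sample constraint
    sets can be mutually inconsistent and must not crash the run.
    """
    g = pdag.copy()
    fixed = set(fixed or ())

    def try_orient(a: str, b: str, rule: str) -> bool:
        if not g.has_undirected(a, b):
            return False
        if (b, a) in fixed:
            warnings.warn(
                f"Meek {rule}: orienting {a}->{b} would reverse a background "
                "edge; skipped",
                stacklevel=3,
            )
            return False
        if g.has_directed_path(b, a):
            warnings.warn(
                f"Meek {rule}: orienting {a}->{b} would create a directed "
                "cycle; skipped",
                stacklevel=3,
            )
            return False
        g.orient(a, b)
        return True

    changed = True
    while changed:
        changed = False
        for b in g.variables:
            # R1: some parent a of b, undirected b - c, a/c non-adjacent
            for a in sorted(g.parents(b)):
                for c in sorted(g.undirected_neighbors(b)):
                    if c != a and not g.is_adjacent(a, c):
                        changed |= try_orient(b, c, "R1")
        for a in g.variables:
            for b in sorted(g.undirected_neighbors(a)):
                # R2: directed chain a -> c -> b
                if any(c in g.parents(b) for c in g.children(a)):
                    changed |= try_orient(a, b, "R2")
        for a in g.variables:
            for b in sorted(g.undirected_neighbors(a)):
                # R3: a - c -> b and a - d -> b with c, d non-adjacent
                mids = sorted(g.undirected_neighbors(a) & g.parents(b))
                done = False
                for c, d in combinations(mids, 2):
                    if not g.is_adjacent(c, d):
                        changed |= try_orient(a, b, "R3")
                        done = True
                        break
                if done:
                    continue
    return g


def dag_to_cpdag(dag: MixedGraph) -> MixedGraph:
    """Completed partially directed acyclic graph of ``dag``'s equivalence
    class: same skeleton, v-structures kept, compelled edges directed,
    reversible edges undirected.
    """
    if not dag.is_fully_directed():
        raise GraphError("dag_to_cpdag expects a fully directed graph")
    if not dag.directed_part_is_acyclic():
        raise GraphError("input graph is cyclic")
    skel = MixedGraph(dag.variables)
    for a, b, _ in dag.edges():
        skel.add_undirected(a, b)
    for a, b, c in find_v_structures(dag):
        for tail in (a, c):
            if skel.has_undirected(tail, b):
                skel.orient(tail, b)
    return meek_closure(skel)


# ---------------------------------------------------------------------------
# Structure comparison
# ---------------------------------------------------------------------------

def shd(estimated: MixedGraph, truth: MixedGraph, variant: str = "paper") -> int:
    """Structural Hamming distance.

    variant='paper': +1 per extra adjacency and +1 per missing adjacency;
    orientation is ignored (wrong connections plus missed edges).
    variant='full': additionally +1 per shared adjacency whose mark differs
    (directed vs undirected, or opposite direction).
    """
    _require_same_nodes(estimated, truth)
    if variant not in ("paper", "full"):
        raise ValueError(f"unknown SHD variant {variant!r}")
    est_adj = estimated.adjacency_pairs()
    tru_adj = truth.adjacency_pairs()
    d = len(est_adj ^ tru_adj)
    if variant == "full":
        for pair in est_adj & tru_adj:
            a, b = sorted(pair)
            if estimated.mark(a, b) != truth.mark(a, b):
                d += 1
    return d


def classify_edges(
    g: MixedGraph, tiers: TieredVariableSet | None = None
) -> tuple[int, int, int]:
    """Count (directed, undirected, non-chronological) edges.

    An edge is non-chronological when it is directed from a strictly later
    tier to a strictly earlier one, or undirected between two distinct
    tiers (a cross-tier edge should have been chronologically directed).
    """
    tier = (tiers or g.variables).tier
    n_dir = n_undir = n_nonchron = 0
    for a, b, mark in g.edges():
        if mark == DIRECTED:
            n_dir += 1
            if tier[a] > tier[b]:
                n_nonchron += 1
        else:
            n_undir += 1
            if tier[a] != tier[b]:
                n_nonchron += 1
    return n_dir, n_undir, n_nonchron


def structure_metrics(
    estimated: MixedGraph,
    truth: MixedGraph,
    tiers: TieredVariableSet | None = None,
) -> StructureMetrics:
    """Adjacency confusion counts of ``estimated`` against ``truth`` plus
    edge-class counts of the estimated graph."""
    _require_same_nodes(estimated, truth)
    est_adj = estimated.adjacency_pairs()
    tru_adj = truth.adjacency_pairs()
    n = len(estimated.variables)
    n_pairs = n * (n - 1) // 2
    tp = len(est_adj & tru_adj)
    fp = len(est_adj - tru_adj)
    fn = len(tru_adj - est_adj)
    tn = n_pairs - tp - fp - fn
    se = tp / (tp + fn) if (tp + fn) else 1.0
    sp = tn / (tn + fp) if (tn + fp) else 1.0
    n_dir, n_undir, n_nonchron = classify_edges(estimated, tiers)
    return StructureMetrics(
        sensitivity=se,
        specificity=sp,
        shd=shd(estimated, truth, "paper"),
        n_directed=n_dir,
        n_undirected=n_undir,
        n_nonchronological=n_nonchron,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


# ---------------------------------------------------------------------------
# Aggregation over resampled CPDAGs
# ---------------------------------------------------------------------------

@dataclass
class AggregatedGraph:
    """Summary graph over resampling runs: retained edges with their
    adjacency frequency (drives edge thickness when drawn)."""

    graph: MixedGraph
    freq: dict[frozenset[str], float]


def aggregate_cpdags(
    graphs: Sequence[MixedGraph], min_freq: float = 0.20
) -> AggregatedGraph:
    """Aggregate CPDAGs from resampled runs into one summary graph.

    An unordered pair is retained iff its adjacency frequency across runs
    is >= ``min_freq``.  A retained edge is drawn directed a -> b when the
    a -> b count strictly exceeds the b -> a count plus the undirected
    count; symmetric for b -> a; otherwise it stays undirected.
    """
    if not graphs:
        raise ValueError("no graphs to aggregate")
    if not (0 < min_freq <= 1):
        raise ValueError("min_freq must be in (0, 1]")
    base = graphs[0].variables
    for g in graphs[1:]:
        if set(g.variables.names) != set(base.names):
            raise GraphError("all graphs must share the node set")
    nruns = len(graphs)
    dir_counts: dict[tuple[str, str], int] = {}
    undir_counts: dict[frozenset[str], int] = {}
    for g in graphs:
        for a, b, mark in g.edges():
            if mark == DIRECTED:
                dir_counts[(a, b)] = dir_counts.get((a, b), 0) + 1
            else:
                key = frozenset((a, b))
                undir_counts[key] = undir_counts.get(key, 0) + 1
    out = MixedGraph(base)
    freqs: dict[frozenset[str], float] = {}
    pairs = {frozenset(k) for k in dir_counts} | set(undir_counts)
    for pair in sorted(pairs, key=sorted):
        a, b = sorted(pair)
        fwd = dir_counts.get((a, b), 0)
        bwd = dir_counts.get((b, a), 0)
        und = undir_counts.get(pair, 0)
        freq = (fwd + bwd + und) / nruns
        if freq < min_freq:
            continue
        if fwd > bwd + und:
            out.add_directed(a, b)
        elif bwd > fwd + und:
            out.add_directed(b, a)
        else:
            out.add_undirected(a, b)
        freqs[pair] = freq
    return AggregatedGraph(graph=out, freq=freqs)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _edge_rows(g: MixedGraph, freq: dict[frozenset[str], float] | None):
    for a, b, mark in g.edges():
        f = 1.0 if freq is None else freq.get(frozenset((a, b)), 1.0)
        yield a, b, mark, f


def write_dot(
    g: MixedGraph,
    path,
    freq: dict[frozenset[str], float] | None = None,
) -> None:
    """Graphviz DOT output; edge penwidth scales with adjacency frequency."""
    lines = ["digraph G {"]
    for v in g.variables:
        lines.append(f'  "{v}";')
    for a, b, mark, f in _edge_rows(g, freq):
        attrs = f'mark="{mark}", freq="{f:.4f}", penwidth="{1 + 4 * f:.2f}"'
        if mark == UNDIRECTED:
            attrs += ', dir="none"'
        lines.append(f'  "{a}" -> "{b}" [{attrs}];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_graphml(
    g: MixedGraph,
    path,
    freq: dict[frozenset[str], float] | None = None,
) -> None:
    gx = nx.DiGraph()
    for v in g.variables:
        gx.add_node(v, tier=int(g.variables.tier[v]), role=g.variables.role[v])
    for a, b, mark, f in _edge_rows(g, freq):
        gx.add_edge(a, b, mark=mark, freq=float(f))
    nx.write_graphml(gx, path)


def write_edge_csv(
    g: MixedGraph,
    path,
    freq: dict[frozenset[str], float] | None = None,
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["from", "to", "mark", "freq"])
        for a, b, mark, f in _edge_rows(g, freq):
            w.writerow([a, b, mark, f"{f:.6g}"])
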