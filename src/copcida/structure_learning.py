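"""PC-stable and chronologically ordered PC-stable (COPC-stable).

PC-stable learns a CPDAG from data in three phases: level-wise skeleton
estimation with conditional-independence tests (order-independent because
adjacency sets are frozen at the start of each conditioning-set-size
level), v-structure orientation from the recorded separating sets, and
Meek-rule closure.

COPC-stable adds chronological background knowledge for repeated
measurements: the initial graph is complete but with every cross-tier edge
pre-directed from the earlier visit to the later one (and every edge into
the binary outcome directed covariate -> outcome), candidate separating
sets for a pair measured at times t and t* exclude all variables measured
strictly after max(t, t*), surviving cross-tier edges keep their
chronological direction, and orientation phases never reverse a
tier-directed edge.  The resulting CPDAG can therefore contain no
non-chronologically ordered edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .ci_test import GaussianCITester, LogisticOutcomeCITester
from .graph_core import (
    DIRECTED,
    GraphError,
    MixedGraph,
    TieredVariableSet,
    classify_edges,
    meek_closure,
)

logger = logging.getLogger(__name__)


class SepsetStore(dict):
    """Map from unordered pair frozenset({a, b}) to the separating set that
    removed the edge.  A pair is absent iff its edge survived."""

    def record(self, a: str, b: str, S) -> None:
        S = frozenset(S)
        if a in S or b in S:
            raise ValueError("separating set must not contain the pair itself")
        self[frozenset((a, b))] = S

    def sepset(self, a: str, b: str) -> frozenset | None:
        return self.get(frozenset((a, b)))


@dataclass
class LearnConfig:
    """Tuning parameters of the structure-learning step.

    alpha
        Two-sided significance cut-off of the CI tests; smaller alpha
        yields sparser graphs.  The application default is 0.02.
    max_cond_size
        Cap on conditioning-set size (None = unbounded; the Gaussian test
        itself caps it at n - 4 for positive degrees of freedom).
    stable
        Freeze adjacency sets per level (order independence).  The plain
        order-dependent variant is kept for comparison only.
    tiered
        Use chronological background knowledge (COPC).
    outcome_test
        'gaussian' treats the 0/1 endpoint as numeric in the Fisher-z test;
        'logistic-lrt' uses a logistic likelihood-ratio test for pairs
        involving the outcome.
    """

    alpha: float = 0.02
    max_cond_size: int | None = None
    stable: bool = True
    tiered: bool = False
    outcome_test: str = "gaussian"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.outcome_test not in ("gaussian", "logistic-lrt"):
            raise ValueError(f"unknown outcome_test {self.outcome_test!r}")


@dataclass
class LearnDetails:
    """Diagnostics of one structure-learning run."""

    sepsets: SepsetStore
    n_ci_tests: int
    max_level: int
    edges_removed_per_level: list[int] = field(default_factory=list)


def _make_tester(data, variables: TieredVariableSet, cfg: LearnConfig):
    data = np.asarray(data, dtype=float)
    if cfg.outcome_test == "logistic-lrt" and variables.outcome is not None:
        return LogisticOutcomeCITester(
            data, variables.names, cfg.alpha, variables.outcome
        )
    return GaussianCITester(data, variables.names, cfg.alpha)


def pc_stable_skeleton(
    data,
    cfg: LearnConfig,
    variables: TieredVariableSet | None = None,
    initial: MixedGraph | None = None,
    ci_tester=None,
) -> tuple[MixedGraph, SepsetStore, LearnDetails]:
    """Level-wise skeleton phase shared by PC-stable and COPC-stable.

    At level L the candidate separating sets for an edge (a, b) are the
    size-L subsets of the adjacency sets frozen at the start of the level,
    enumerated in lexicographic order of the sorted adjacency list; the
    first separating set found removes the edge and is recorded.  With
    ``cfg.tiered`` candidate variables measured strictly after
    max(tier(a), tier(b)) are excluded — the future cannot separate the
    past.

    Pre-directed edges in ``initial`` (chronological background) are
    ordinary adjacencies for the search; removal deletes them like any
    other edge, survival keeps their direction.
    """
    if variables is None:
        if ci_tester is not None:
            variables = TieredVariableSet.from_names(ci_tester.names)
        else:
            raise ValueError("variables required when no tester is given")
    tester = ci_tester if ci_tester is not None else _make_tester(data, variables, cfg)
    g = initial.copy() if initial is not None else MixedGraph.complete_undirected(variables)
    tier = variables.tier
    sepsets = SepsetStore()
    details = LearnDetails(sepsets=sepsets, n_ci_tests=0, max_level=0)

    cap = cfg.max_cond_size
    t_cap = getattr(tester, "max_cond_size", None)
    if t_cap is not None:
        cap = t_cap if cap is None else min(cap, t_cap)

    level = 0
    while True:
        if cap is not None and level > cap:
            break
        # freeze adjacency sets (PC-stable order independence)
        frozen = {v: sorted(g.adjacent(v)) for v in variables}
        if not any(len(frozen[v]) - 1 >= level for v in variables):
            break
        removed_here = 0
        if not cfg.stable:
            frozen = None  # order-dependent variant: live adjacency sets
        for a, b, _mark in g.edges():
            if not g.is_adjacent(a, b):
                continue  # removed earlier this level
            max_t = max(tier[a], tier[b])
            separated = False
            for x, y in ((a, b), (b, a)):
                adj = frozen[x] if frozen is not None else sorted(g.adjacent(x))
                cand = [
                    v
                    for v in adj
                    if v != y and (not cfg.tiered or tier[v] <= max_t)
                ]
                if len(cand) < level:
                    continue
                for S in combinations(cand, level):
                    res = tester.test(a, b, S)
                    if res.independent:
                        g.remove_edge(a, b)
                        sepsets.record(a, b, S)
                        separated = True
                        removed_here += 1
                        break
                if separated:
                    break
        details.edges_removed_per_level.append(removed_here)
        details.max_level = level
        logger.info("skeleton level %d: removed %d edges", level, removed_here)
        level += 1
    details.n_ci_tests = tester.n_tests
    return g, sepsets, details


def orient_v_structures(
    skeleton: MixedGraph, sepsets: SepsetStore
) -> MixedGraph:
    """Orient unshielded triples a * - * b * - * c with b outside sepset(a, c)
    as a -> b <- c.

    Orientation proposals are collected for the whole graph and applied in
    one batch, only onto currently undirected edges — pre-directed
    (background) edges are never reversed, and a pair proposed in both
    directions is left undirected with a logged conflict.
    """
    g = skeleton.copy()
    proposals: set[tuple[str, str]] = set()
    for b in g.variables:
        nbrs = sorted(g.adjacent(b))
        for a, c in combinations(nbrs, 2):
            if g.is_adjacent(a, c):
                continue
            S = sepsets.sepset(a, c)
            if S is None or b in S:
                continue
            proposals.add((a, b))
            proposals.add((c, b))
    for a, b in sorted(proposals):
        if (b, a) in proposals:
            if a < b:
                logger.debug(
                    "conflicting v-structure orientations on %s - %s; "
                    "left undirected",
                    a,
                    b,
                )
            continue
        if g.has_undirected(a, b):
            g.orient(a, b)
        elif g.has_directed(b, a):
            logger.debug(
                "v-structure wants %s -> %s against a pre-directed edge; kept",
                a,
                b,
            )
    return g


def pc_stable(
    data,
    cfg: LearnConfig | None = None,
    variables: TieredVariableSet | None = None,
    ci_tester=None,
    full_output: bool = False,
):
    """Order-independent PC: skeleton, v-structures, Meek closure.

    Returns the estimated CPDAG (a :class:`MixedGraph`); with
    ``full_output`` also the separating sets and run diagnostics.
    """
    cfg = cfg or LearnConfig()
    if cfg.tiered:
        raise ValueError("use copc_stable for tiered learning")
    skel, sepsets, details = pc_stable_skeleton(
        data, cfg, variables=variables, ci_tester=ci_tester
    )
    pdag = orient_v_structures(skel, sepsets)
    cpdag = meek_closure(pdag)
    if not cpdag.directed_part_is_acyclic():  # pragma: no cover - guarded by meek
        raise GraphError("output CPDAG has a directed cycle")
    if full_output:
        return cpdag, sepsets, details
    return cpdag


def copc_initial_graph(variables: TieredVariableSet) -> MixedGraph:
    """Complete initial graph with chronological a priori information.

    Cross-tier edges are directed from the earlier to the later visit
    (hence all edges into the outcome point at it); within-tier edges stay
    undirected.  With a single tier this is the plain complete undirected
    graph.
    """
    g = MixedGraph(variables)
    tier = variables.tier
    for a, b in combinations(variables.names, 2):
        if tier[a] < tier[b]:
            g.add_directed(a, b)
        elif tier[a] > tier[b]:
            g.add_directed(b, a)
        else:
            g.add_undirected(a, b)
    return g


def copc_stable(
    data,
    variables: TieredVariableSet,
    cfg: LearnConfig | None = None,
    ci_tester=None,
    full_output: bool = False,
):
    """Chronologically ordered PC-stable.

    Starts from :func:`copc_initial_graph`, restricts separating-set
    candidates to variables measured no later than the pair under test,
    keeps the chronological direction of surviving cross-tier edges
    (a partially directed skeleton), orients v-structures only on
    within-tier undirected edges, and closes with Meek rules holding the
    tier-directed edges fixed.  The output contains, by construction, zero
    non-chronologically ordered edges.
    """
    cfg = cfg or LearnConfig(tiered=True)
    if not cfg.tiered:
        cfg = LearnConfig(
            alpha=cfg.alpha,
            max_cond_size=cfg.max_cond_size,
            stable=cfg.stable,
            tiered=True,
            outcome_test=cfg.outcome_test,
        )
    initial = copc_initial_graph(variables)
    skel, sepsets, details = pc_stable_skeleton(
        data, cfg, variables=variables, initial=initial, ci_tester=ci_tester
    )
    fixed = {(a, b) for a, b, mark in skel.edges() if mark == DIRECTED}
    pdag = orient_v_structures(skel, sepsets)
    cpdag = meek_closure(pdag, fixed=fixed)
    _, _, n_nonchron = classify_edges(cpdag, variables)
    if n_nonchron:  # pragma: no cover - structural guarantee
        raise GraphError(
            f"COPC output has {n_nonchron} non-chronological edges (bug)"
        )
    if full_output:
        return cpdag, sepsets, details
    return cpdag
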