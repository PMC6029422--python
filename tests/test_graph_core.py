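"""Graph model, Markov-equivalence operations and structure metrics."""

import numpy as np
import pytest

from copcida.graph_core import (
    GraphError,
    MixedGraph,
    TieredVariableSet,
    aggregate_cpdags,
    classify_edges,
    dag_to_cpdag,
    meek_closure,
    shd,
    structure_metrics,
    write_dot,
    write_edge_csv,
    write_graphml,
)

from conftest import (
    cpdag_by_enumeration,
    enumerate_cpdag_extensions,
    make_vars,
    random_dag,
    relabel_graph,
)


class TestTieredVariableSet:
    def test_invariants(self):
        with pytest.raises(ValueError, match="unique"):
            TieredVariableSet.from_names(["a", "a"])
        v = TieredVariableSet.from_names(["a", "b", "y"], outcome="y")
        assert v.outcome == "y"
        assert v.tier["y"] == 1  # strictly above the covariates
        with pytest.raises(ValueError, match="strictly greater"):
            TieredVariableSet(
                names=("a", "y"),
                tier={"a": 2, "y": 1},
                role={"a": "covariate", "y": "outcome"},
            )
        with pytest.raises(ValueError, match="one outcome"):
            TieredVariableSet(
                names=("a", "b"),
                tier={"a": 0, "b": 1},
                role={"a": "outcome", "b": "outcome"},
            )

    def test_mixed_graph_edge_exclusivity(self):
        g = MixedGraph(make_vars(3))
        g.add_undirected("x0", "x1")
        g.add_directed("x0", "x1")  # replaces
        assert g.mark("x0", "x1") == "directed"
        assert g.mark("x1", "x0") is None
        with pytest.raises(GraphError):
            g.add_directed("x0", "x0")


class TestDagToCpdag:
    def test_chain_becomes_undirected(self):
        # the three Markov-equivalent chains/forks collapse to x0 - x1 - x2
        g = MixedGraph.from_edges(
            make_vars(3), directed=[("x0", "x1"), ("x1", "x2")]
        )
        cp = dag_to_cpdag(g)
        assert cp.edges() == [
            ("x0", "x1", "undirected"),
            ("x1", "x2", "undirected"),
        ]

    def test_collider_is_invariant(self):
        g = MixedGraph.from_edges(
            make_vars(3), directed=[("x0", "x1"), ("x2", "x1")]
        )
        cp = dag_to_cpdag(g)
        assert cp.mark("x0", "x1") == "directed"
        assert cp.mark("x2", "x1") == "directed"

    def test_cyclic_input_rejected(self):
        g = MixedGraph.from_edges(
            make_vars(2), directed=[("x0", "x1")]
        )
        g._children["x1"].add("x0")  # force a cycle
        g._parents["x0"].add("x1")
        with pytest.raises(GraphError):
            dag_to_cpdag(g)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_enumeration_oracle(self, seed):
        """CPDAG equals the brute-force enumeration over all DAGs with the
        same skeleton and v-structures (6-node random DAGs)."""
        rng = np.random.default_rng(1000 + seed)
        dag = random_dag(rng, 6, edge_prob=0.4)
        assert dag_to_cpdag(dag) == cpdag_by_enumeration(dag)

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_through_extensions(self, seed):
        """Every consistent extension of the CPDAG maps back to it."""
        rng = np.random.default_rng(2000 + seed)
        dag = random_dag(rng, 5, edge_prob=0.45)
        cp = dag_to_cpdag(dag)
        for member in enumerate_cpdag_extensions(cp):
            g = MixedGraph.from_edges(dag.variables, directed=sorted(member))
            assert dag_to_cpdag(g) == cp


class TestMeekClosure:
    def test_r1(self):
        g = MixedGraph.from_edges(
            make_vars(3), directed=[("x0", "x1")], undirected=[("x1", "x2")]
        )
        out = meek_closure(g)
        assert out.mark("x1", "x2") == "directed"

    def test_r2(self):
        g = MixedGraph.from_edges(
            make_vars(3),
            directed=[("x0", "x2"), ("x2", "x1")],
            undirected=[("x0", "x1")],
        )
        out = meek_closure(g)
        assert out.mark("x0", "x1") == "directed"

    def test_r3(self):
        g = MixedGraph.from_edges(
            make_vars(4),
            directed=[("x2", "x1"), ("x3", "x1")],
            undirected=[("x0", "x1"), ("x0", "x2"), ("x0", "x3")],
        )
        out = meek_closure(g)
        assert out.mark("x0", "x1") == "directed"

    def test_fixpoint_on_directed_graph(self):
        g = MixedGraph.from_edges(
            make_vars(3), directed=[("x0", "x1"), ("x1", "x2")]
        )
        assert meek_closure(g) == g

    def test_fixed_edges_never_reversed(self):
        # R1 would orient x1 -> x2 but the reverse is background knowledge
        g = MixedGraph.from_edges(
            make_vars(3), directed=[("x0", "x1")], undirected=[("x1", "x2")]
        )
        with pytest.warns(UserWarning, match="background"):
            out = meek_closure(g, fixed={("x2", "x1")})
        assert out.mark("x1", "x2") == "undirected"

    @pytest.mark.parametrize("seed", range(10))
    def test_label_permutation_equivariance(self, seed):
        rng = np.random.default_rng(3000 + seed)
        dag = random_dag(rng, 6, edge_prob=0.4)
        cp = dag_to_cpdag(dag)
        names = list(dag.variables.names)
        perm = list(names)
        rng.shuffle(perm)
        mapping = dict(zip(names, perm))
        assert relabel_graph(cp, mapping) == dag_to_cpdag(
            relabel_graph(dag, mapping)
        )


class TestShd:
    def test_identical_graphs(self):
        v = make_vars(4)
        g = MixedGraph.from_edges(v, directed=[("x0", "x1")])
        assert shd(g, g) == 0

    def test_extra_plus_missing(self):
        v = make_vars(4)
        truth = MixedGraph.from_edges(v, undirected=[("x0", "x1")])
        est = MixedGraph.from_edges(v, undirected=[("x2", "x3")])
        assert shd(est, truth) == 2

    def test_empty_vs_complete(self):
        v = make_vars(4)
        assert shd(MixedGraph(v), MixedGraph.complete_undirected(v)) == 6

    def test_paper_variant_ignores_orientation_full_counts_it(self):
        v = make_vars(2)
        est = MixedGraph.from_edges(v, directed=[("x0", "x1")])
        truth = MixedGraph.from_edges(v, undirected=[("x0", "x1")])
        assert shd(est, truth, "paper") == 0
        assert shd(est, truth, "full") == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(4000 + seed)
        a = dag_to_cpdag(random_dag(rng, 6, 0.4))
        b = dag_to_cpdag(random_dag(rng, 6, 0.4))
        assert shd(a, b) == shd(b, a)


class TestClassifyAndMetrics:
    def test_classify_edges(self):
        v = make_vars(4, tier=[1, 1, 2, 2])
        g = MixedGraph.from_edges(
            v, directed=[("x2", "x0")], undirected=[("x0", "x1")]
        )
        assert classify_edges(g) == (1, 1, 1)  # later -> earlier is wrong
        g2 = MixedGraph.from_edges(v, undirected=[("x0", "x1")])
        assert classify_edges(g2) == (0, 1, 0)  # within-tier undirected ok
        g3 = MixedGraph.from_edges(v, undirected=[("x0", "x2")])
        assert classify_edges(g3) == (0, 1, 1)  # cross-tier undirected wrong

    def test_metrics_extremes(self):
        v = make_vars(4)
        truth = MixedGraph.from_edges(v, undirected=[("x0", "x1"), ("x1", "x2")])
        m = structure_metrics(truth, truth)
        assert m.sensitivity == 1.0 and m.specificity == 1.0 and m.shd == 0
        m0 = structure_metrics(MixedGraph(v), truth)
        assert m0.sensitivity == 0.0 and m0.specificity == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_confusion_matches_bruteforce(self, seed):
        from itertools import combinations

        rng = np.random.default_rng(5000 + seed)
        est = dag_to_cpdag(random_dag(rng, 8, 0.3))
        truth = dag_to_cpdag(random_dag(rng, 8, 0.3))
        m = structure_metrics(est, truth)
        tp = fp = tn = fn = 0
        for a, b in combinations(est.variables.names, 2):
            e, t = est.is_adjacent(a, b), truth.is_adjacent(a, b)
            tp += e and t
            fp += e and not t
            fn += t and not e
            tn += not e and not t
        assert (m.tp, m.fp, m.tn, m.fn) == (tp, fp, tn, fn)
        if tp + fn:
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert m.specificity == pytest.approx(tn / (tn + fp))


class TestAggregation:
    def _graphs(self, marks):
        v = make_vars(2)
        out = []
        for m in marks:
            g = MixedGraph(v)
            if m == ">":
                g.add_directed("x0", "x1")
            elif m == "<":
                g.add_directed("x1", "x0")
            elif m == "-":
                g.add_undirected("x0", "x1")
            out.append(g)
        return out

    def test_threshold_boundary(self):
        # present in exactly 20% of 300 graphs -> retained at min_freq 0.20
        graphs = self._graphs([">"] * 60 + [""] * 240)
        agg = aggregate_cpdags(graphs, min_freq=0.20)
        assert agg.freq[frozenset(("x0", "x1"))] == pytest.approx(0.20)
        agg59 = aggregate_cpdags(self._graphs([">"] * 59 + [""] * 241), 0.20)
        assert not agg59.freq

    def test_single_graph_identity(self):
        graphs = self._graphs(["-"])
        agg = aggregate_cpdags(graphs, min_freq=0.5)
        assert agg.graph == graphs[0]
        assert list(agg.freq.values()) == [1.0]

    def test_direction_call(self):
        # direction wins only when it beats reverse + undirected together
        agg = aggregate_cpdags(self._graphs([">", ">", "-", "-"]), 0.2)
        assert agg.graph.mark("x0", "x1") == "undirected"  # 2 vs 2: tie
        agg2 = aggregate_cpdags(self._graphs([">", "<"]), 0.2)
        assert agg2.graph.mark("x0", "x1") == "undirected"
        agg3 = aggregate_cpdags(self._graphs([">", ">", ">", "<"]), 0.2)
        assert agg3.graph.mark("x0", "x1") == "directed"  # 3 > 1
        agg4 = aggregate_cpdags(self._graphs(["<", "<", ">"]), 0.2)
        assert agg4.graph.mark("x1", "x0") == "directed"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cpdags([], 0.2)


class TestWriters:
    def test_formats(self, tmp_path):
        v = make_vars(3, tier=[1, 1, 2])
        g = MixedGraph.from_edges(
            v, directed=[("x0", "x2")], undirected=[("x0", "x1")]
        )
        freq = {frozenset(("x0", "x2")): 0.5, frozenset(("x0", "x1")): 1.0}
        dot = tmp_path / "g.dot"
        write_dot(g, dot, freq=freq)
        text = dot.read_text()
        assert 'mark="directed"' in text and 'freq="0.5000"' in text
        assert "penwidth" in text
        write_graphml(g, tmp_path / "g.graphml", freq=freq)
        assert (tmp_path / "g.graphml").stat().st_size > 0
        csvp = tmp_path / "g.csv"
        write_edge_csv(g, csvp, freq=freq)
        lines = csvp.read_text().strip().splitlines()
        assert lines[0] == "from,to,mark,freq"
        assert len(lines) == 3
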