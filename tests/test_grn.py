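import numpy as np
import pandas as pd
import pytest

from bulkcraft.grn import (
    MAX_HOPS,
    MAX_NETWORKS,
    Network,
    compare_networks,
    extract_neighbourhood,
    infer_grn,
)
from bulkcraft.matrixio import ExpressionMatrix, MatrixIOError

from oracles import set_algebra_subset_counts


def _toy_matrix(seed=5, n_samples=50):
    """y is an exact copy of x1; x2..x10 are independent noise."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((10, n_samples))
    data = pd.DataFrame(
        np.vstack([x, x[0]]), index=[f"x{i + 1}" for i in range(10)] + ["y"],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix((data + 10).clip(lower=0), state="normalised")


def _star(weights: dict[str, float]) -> Network:
    net = Network()
    net.add_node("hub")
    for leaf, w in weights.items():
        net.add_node(leaf)
        net.add_edge(leaf, "hub", weight=w)
    return net


class TestInference:
    def test_true_driver_dominates_decoys(self):
        m = _toy_matrix()
        net = infer_grn(m, targets=["y"], regulators=[f"x{i + 1}" for i in range(10)],
                        n_trees=100, seed=3)
        w = sorted(((u, d["weight"]) for u, _, d in net.g.in_edges("y", data=True)),
                   key=lambda kv: -kv[1])
        assert w[0][0] == "x1"
        assert w[0][1] >= 5 * w[1][1]

    def test_deterministic_under_regulator_order_permutation(self):
        m = _toy_matrix(seed=8)
        regs = [f"x{i + 1}" for i in range(10)]
        n1 = infer_grn(m, targets=["y"], regulators=regs, n_trees=50, seed=7)
        n2 = infer_grn(m, targets=["y"], regulators=list(reversed(regs)), n_trees=50, seed=7)
        t1, t2 = n1.edges_table(), n2.edges_table()
        pd.testing.assert_frame_equal(t1, t2)

    def test_single_regulator_takes_all_importance(self):
        m = _toy_matrix(seed=9)
        net = infer_grn(m, targets=["y"], regulators=["x1"], n_trees=50, seed=1)
        # y standardised to unit (population) variance: total variance
        # reduction approaches 1 and lands on the only regulator
        assert net.g.has_edge("x1", "y")
        assert net.edge_weight("x1", "y") > 0.5

    def test_constant_target_rejected_by_name(self):
        df = pd.DataFrame({"s1": [1.0, 5.0, 5.0], "s2": [2.0, 5.0, 6.0],
                           "s3": [3.0, 5.0, 7.0]}, index=["a", "flat", "c"])
        m = ExpressionMatrix(df, state="normalised")
        with pytest.raises(MatrixIOError, match="flat"):
            infer_grn(m, targets=["flat"], regulators=["a", "c"], n_trees=10, seed=0)

    def test_minimum_sample_count_enforced(self, tiny_matrix):
        with pytest.raises(MatrixIOError, match="3 samples"):
            infer_grn(tiny_matrix, n_trees=10, seed=0)

    def test_weights_nonnegative_and_bounded(self):
        m = _toy_matrix(seed=10)
        net = infer_grn(m, n_trees=50, seed=2)
        for t in net.nodes:
            weights = [d["weight"] for _, _, d in net.g.in_edges(t, data=True)]
            assert all(w >= 0 for w in weights)
            total = sum(weights)
            if total > 0:
                # normalised by total importance, per-target mass sums to 1
                assert sum(w / total for w in weights) == pytest.approx(1.0)

    def test_self_loops_forbidden(self):
        net = Network()
        net.add_node("a")
        with pytest.raises(MatrixIOError):
            net.add_edge("a", "a", weight=1.0)


class TestNeighbourhood:
    def test_star_top_n_keeps_heaviest_spokes(self):
        weights = {f"leaf{i:02d}": float(i) for i in range(1, 13)}
        net = _star(weights)
        sub = extract_neighbourhood(net, ["hub"], top_n=7, max_hops=1)
        kept = {u for u, _ in sub.edge_set()}
        assert kept == {f"leaf{i:02d}" for i in range(6, 13)}

    def test_tie_break_is_lexicographic(self):
        net = _star({"b": 1.0, "a": 1.0, "c": 1.0})
        sub = extract_neighbourhood(net, ["hub"], top_n=2, max_hops=1)
        assert {u for u, _ in sub.edge_set()} == {"a", "b"}

    def test_isolated_focus_keeps_only_focus(self):
        net = Network()
        net.add_node("lonely")
        net.add_node("other")
        sub = extract_neighbourhood(net, ["lonely"], top_n=3, max_hops=1)
        assert sub.nodes == ["lonely"]
        assert not sub.edge_set()

    def test_hop_bound_on_chain(self):
        net = Network()
        chain = ["a", "b", "c", "d", "e"]
        for n in chain:
            net.add_node(n)
        for u, v in zip(chain, chain[1:]):
            net.add_edge(u, v, weight=1.0)
        sub = extract_neighbourhood(net, ["a"], top_n=5, max_hops=3)
        assert "e" not in sub.nodes
        assert "d" in sub.nodes

    def test_output_is_subgraph_and_idempotent(self):
        rng = np.random.default_rng(15)
        net = Network()
        nodes = [f"n{i}" for i in range(20)]
        for n in nodes:
            net.add_node(n)
        for _ in range(60):
            u, v = rng.choice(nodes, size=2, replace=False)
            if not net.g.has_edge(u, v):
                net.add_edge(u, v, weight=float(rng.random()))
        sub = extract_neighbourhood(net, ["n0", "n1"], top_n=3, max_hops=2)
        assert sub.edge_set() <= net.edge_set()
        again = extract_neighbourhood(sub, ["n0", "n1"], top_n=3, max_hops=2)
        assert again.edge_set() == sub.edge_set()

    @pytest.mark.parametrize("hops", [0, 4])
    def test_hop_limit_enforced(self, hops):
        net = _star({"a": 1.0})
        with pytest.raises(MatrixIOError, match="max_hops"):
            extract_neighbourhood(net, ["hub"], top_n=1, max_hops=hops)

    def test_top_n_validated(self):
        net = _star({"a": 1.0})
        with pytest.raises(MatrixIOError, match="top_n"):
            extract_neighbourhood(net, ["hub"], top_n=0)

    def test_unknown_focus_rejected(self):
        net = _star({"a": 1.0})
        with pytest.raises(MatrixIOError, match="ghost"):
            extract_neighbourhood(net, ["ghost"])


def _net_from_edges(edges) -> Network:
    net = Network()
    for u, v in edges:
        net.add_node(u)
        net.add_node(v)
        net.add_edge(u, v, weight=1.0)
    return net


class TestComparison:
    def test_identical_networks_share_everything(self):
        edges = [("a", "b"), ("b", "c")]
        comp = compare_networks([_net_from_edges(edges), _net_from_edges(edges)])
        assert comp.subset_counts == {(0, 1): 2}
        assert comp.shared_edges == sorted(edges)

    def test_disjoint_networks_have_only_singletons(self):
        comp = compare_networks([_net_from_edges([("a", "b")]),
                                 _net_from_edges([("c", "d")])])
        assert comp.subset_counts == {(0,): 1, (1,): 1}
        assert comp.shared_edges == []

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_counts_match_set_algebra(self, k):
        rng = np.random.default_rng(40 + k)
        nodes = [f"n{i}" for i in range(12)]
        nets, sets = [], []
        for _ in range(k):
            edges = set()
            while len(edges) < 15:
                u, v = rng.choice(nodes, size=2, replace=False)
                edges.add((u, v))
            nets.append(_net_from_edges(edges))
            sets.append(edges)
        comp = compare_networks(nets)
        assert comp.subset_counts == set_algebra_subset_counts(sets)
        assert comp.union_size == len(set().union(*sets))

    @pytest.mark.parametrize("k", [1, 5])
    def test_network_count_limit(self, k):
        nets = [_net_from_edges([("a", "b")]) for _ in range(k)]
        with pytest.raises(MatrixIOError, match=str(MAX_NETWORKS)):
            compare_networks(nets)

    def test_annotation_edges_excluded(self):
        n1 = _net_from_edges([("a", "b")])
        n1.add_node("peak1")
        n1.add_edge("peak1", "b", weight=0.0, kind="annotation")
        n2 = _net_from_edges([("a", "b")])
        comp = compare_networks([n1, n2])
        assert comp.subset_counts == {(0, 1): 1}
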