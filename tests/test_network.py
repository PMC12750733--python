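import networkx as nx
import numpy as np
import pandas as pd
import pytest

from duinet import synthetic
from duinet.network import (
    compare_groups,
    components,
    edge_enrichment,
    load_interactome,
    node_metrics,
    stress_centrality,
)

from oracles import stress_by_path_enumeration


class TestStress:
    def test_path_graph(self):
        g = nx.path_graph(["A", "B", "C"])
        s = stress_centrality(g)
        assert s == {"A": 0.0, "B": 1.0, "C": 0.0}
        m = node_metrics(g)
        assert m.loc["B", "degree"] == 2

    def test_star_graph(self):
        g = nx.star_graph(5)  # center 0, leaves 1..5
        s = stress_centrality(g)
        assert s[0] == 10.0  # C(5,2) pairs route through the center
        m = node_metrics(g)
        assert m.loc[1, "neighborhood_connectivity"] == 5.0

    def test_complete_graph_and_leaves_have_zero_stress(self):
        s = stress_centrality(nx.complete_graph(6))
        assert all(v == 0.0 for v in s.values())

    def test_matches_path_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(1e6)))
            mine = stress_centrality(g)
            ref = stress_by_path_enumeration(g)
            assert mine == ref


class TestComponents:
    def test_edgeless_set_all_isolated(self):
        g = nx.empty_graph(["A", "B", "C"])
        comps, isolated = components(g)
        assert comps == [] and isolated == {"A", "B", "C"}

    def test_path_plus_isolated(self):
        g = nx.path_graph(["A", "B", "C"])
        g.add_node("D")
        comps, isolated = components(g)
        assert comps == [{"A", "B", "C"}] and isolated == {"D"}

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(40, 0.04, seed=11)
        comps, isolated = components(g)
        # independent flood fill
        seen, ref = set(), []
        for start in g.nodes:
            if start in seen:
                continue
            stack, comp = [start], set()
            while stack:
                v = stack.pop()
                if v in comp:
                    continue
                comp.add(v)
                stack.extend(g.neighbors(v))
            seen |= comp
            if len(comp) > 1:
                ref.append(comp)
        ref.sort(key=lambda c: (-len(c), sorted(c)[0]))
        assert comps == ref


class TestEdgeEnrichment:
    def test_full_node_set_is_boundary(self):
        g, _ = synthetic.simulate_interactome(30, 0.2, [], [], 0.2, seed=1)
        out = edge_enrichment(g, set(g.nodes), n_resample=49, seed=2)
        assert out["observed"] == g.number_of_edges()
        assert out["p"] == 1.0

    def test_planted_module_detected(self):
        nodes_a = [f"n{i + 1:04d}" for i in range(10)]
        nodes_b = [f"n{i + 11:04d}" for i in range(10)]
        g, _ = synthetic.simulate_interactome(
            150, 0.02, nodes_a, nodes_b, 0.4, seed=3
        )
        out = edge_enrichment(
            g, set(nodes_a) | set(nodes_b), n_resample=499, seed=4
        )
        assert out["p"] < 0.01
        assert out["observed"] > out["expected"]

    def test_tiny_set_warns(self):
        g, _ = synthetic.simulate_interactome(10, 0.3, [], [], 0.3, seed=5)
        with pytest.warns(UserWarning):
            out = edge_enrichment(g, {sorted(g.nodes)[0]}, n_resample=9, seed=6)
        assert out["p"] == 1.0


class TestCompareGroups:
    def test_shift_detected(self, rng):
        g = nx.path_graph(range(40))
        metrics = node_metrics(g)
        labels = {v: ("CE" if v < 20 else "DE") for v in g.nodes}
        metrics["degree"] = np.where(
            [labels[v] == "CE" for v in metrics.index],
            metrics["degree"] + 10,
            metrics["degree"],
        )
        out = compare_groups(metrics[["degree"]], labels)
        w = out[out["test"] == "wilcoxon"].iloc[0]
        assert w["p"] < 0.01
        assert w["higher_group"] == "CE"

    def test_identical_distributions_near_one(self):
        metrics = pd.DataFrame(
            {"degree": [1, 2, 3, 4, 5, 1, 2, 3, 4, 5]},
            index=[f"v{i}" for i in range(10)],
        )
        labels = {f"v{i}": ("CE" if i < 5 else "DE") for i in range(10)}
        out = compare_groups(metrics, labels)
        assert (out["p"] > 0.5).all()

    def test_single_shared_value_ties_handled(self):
        metrics = pd.DataFrame(
            {"stress": [3.0] * 8}, index=[f"v{i}" for i in range(8)]
        )
        labels = {f"v{i}": ("CE" if i < 4 else "DE") for i in range(8)}
        out = compare_groups(metrics, labels, tests=("wilcoxon",))
        assert np.isfinite(out["p"]).all()


class TestLoad:
    def test_score_threshold_boundary(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text(
            "node_a\tnode_b\tscore\n"
            "a\tb\t0.400\n"
            "a\tc\t0.3999\n"
            "b\tb\t0.9\n"
        )
        g = load_interactome(p)
        assert g.has_edge("a", "b")      # at threshold: kept
        assert not g.has_edge("a", "c")  # below: dropped
        assert not g.has_edge("b", "b")  # self loop dropped
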