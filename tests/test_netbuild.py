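import numpy as np
import networkx as nx
import pandas as pd
import pytest

import ccmbn.netbuild as netbuild
from ccmbn.eccm import ECCMProfile
from ccmbn.netbuild import (CausalEdge, CausalNetwork, add_expert_edges,
                            apply_surrogate_filter, build_target_network,
                            pairwise_ccm_network, refine_with_eccm, to_dag)
from ccmbn.series import MultivariateSeries
from ccmbn.simulate import SimConfig, simulate_four_species

DIRECT = {("Y1", "Y2"), ("Y2", "Y3"), ("Y3", "Y4")}


def net_from(edge_triples, target="T"):
    nodes = sorted({n for e in edge_triples for n in e[:2]})
    edges = [CausalEdge(a, b, s) for a, b, s in edge_triples]
    return CausalNetwork(nodes, edges, target)


class TestCausalEdge:
    def test_self_edge_rejected(self):
        with pytest.raises(ValueError):
            CausalEdge("A", "A", 0.5)


class TestBuildTargetNetwork:
    def test_four_species_direct_chain_recovered(self, four_species):
        net = build_target_network(four_species, "Y4")
        assert DIRECT <= net.edge_pairs()
        for e in net.edges:
            assert e.mean_skill >= 0.01
            assert e.n_converged_windows >= 10

    def test_constant_input_gives_empty_network(self):
        frame = pd.DataFrame({"a": np.ones(300), "b": np.ones(300),
                              "t": np.ones(300)})
        series = MultivariateSeries(frame)
        with pytest.warns(UserWarning, match="screening set empty"):
            net = build_target_network(series, "t")
        assert net.edges == []

    def test_missing_target_rejected(self, four_species):
        with pytest.raises(KeyError):
            build_target_network(four_species, "Y9")

    def test_candidate_pair_bound(self, four_species):
        net = build_target_network(four_species, "Y4")
        k = len(net.nodes)
        assert len(net.edges) <= k * (k - 1)


class TestRefineWithEccm:
    def fake_profiles(self, mapping):
        def fake(x, y, params, frame, max_library, max_shift):
            return mapping.pop(0)
        return fake

    def make_profile(self, cls, lag_xy=-2, lag_yx=-1):
        shifts = np.arange(-5, 6)
        prof = ECCMProfile(shifts, np.full(11, 0.2), np.full(11, 0.2),
                           lag_xy, lag_yx, min(lag_xy, 0), min(lag_yx, 0))
        prof.classification = cls
        return prof

    def test_false_and_common_force_dropped(self, monkeypatch, four_species):
        net = net_from([("Y1", "Y2", 0.5), ("Y2", "Y3", 0.4)], target="Y4")
        profs = [self.make_profile("false_interaction"),
                 self.make_profile("synchrony_common_force")]
        monkeypatch.setattr(netbuild, "eccm_scan", self.fake_profiles(profs))
        out = refine_with_eccm(net, four_species)
        assert out.edges == []

    def test_bidirectional_keeps_both_with_lags(self, monkeypatch, four_species):
        net = net_from([("Y1", "Y2", 0.5), ("Y2", "Y1", 0.4)], target="Y4")
        profs = [self.make_profile("bidirectional", lag_xy=-3, lag_yx=-1)]
        monkeypatch.setattr(netbuild, "eccm_scan", self.fake_profiles(profs))
        out = refine_with_eccm(net, four_species)
        assert out.edge_pairs() == {("Y1", "Y2"), ("Y2", "Y1")}
        lags = {(e.source, e.target): e.lag_steps for e in out.edges}
        assert lags == {("Y1", "Y2"): -3, ("Y2", "Y1"): -1}

    def test_enslavement_keeps_dominant_direction(self, monkeypatch,
                                                  four_species):
        net = net_from([("Y1", "Y2", 0.5), ("Y2", "Y1", 0.4)], target="Y4")
        profs = [self.make_profile("synchrony_enslaved_xy", lag_xy=-4,
                                   lag_yx=6)]
        monkeypatch.setattr(netbuild, "eccm_scan", self.fake_profiles(profs))
        out = refine_with_eccm(net, four_species)
        assert out.edge_pairs() == {("Y1", "Y2")}

    def test_empty_network_passthrough(self, four_species):
        net = CausalNetwork(["Y4"], [], "Y4")
        assert refine_with_eccm(net, four_species).edges == []


class TestSurrogateFilter:
    def test_failing_edges_removed_and_passing_marked(self, monkeypatch,
                                                      four_species):
        net = net_from([("Y1", "Y2", 0.5), ("Y3", "Y1", 0.4)], target="Y4")
        results = {("Y1", "Y2"): (0.9, 0.2, True),
                   ("Y3", "Y1"): (0.1, 0.3, False)}

        def fake(cause, effect, params, **kw):
            key = [k for k in results
                   if np.array_equal(four_species.column(k[0]), cause)][0]
            return results[key]
        monkeypatch.setattr(netbuild, "surrogate_significance", fake)
        out = apply_surrogate_filter(net, four_species, n_surrogates=100)
        assert out.edge_pairs() == {("Y1", "Y2")}
        assert out.edges[0].significant is True

    def test_expert_edges_exempt(self, monkeypatch, four_species):
        edge = CausalEdge("Y1", "Y4", float("nan"), provenance="expert")
        net = CausalNetwork(["Y1", "Y4"], [edge], "Y4")
        monkeypatch.setattr(netbuild, "surrogate_significance",
                            lambda *a, **k: (0.0, 1.0, False))
        out = apply_surrogate_filter(net, four_species)
        assert out.edge_pairs() == {("Y1", "Y4")}

    def test_true_edges_survive_default_quantile(self, four_species):
        net = net_from([("Y1", "Y2", 0.8)], target="Y4")
        out = apply_surrogate_filter(net, four_species, n_surrogates=200,
                                     seed=0)
        assert out.edge_pairs() == {("Y1", "Y2")}


class TestToDag:
    def test_cycle_through_target_truncated_after_target(self):
        net = net_from([("A", "B", 0.5), ("B", "C", 0.4), ("C", "A", 0.3)],
                       target="B")
        dag = to_dag(net)
        assert dag.edge_pairs() == {("A", "B"), ("C", "A")}

    def test_acyclic_input_only_sink_pruned(self):
        net = net_from([("A", "T", 0.5), ("A", "D", 0.4)], target="T")
        dag = to_dag(net)
        # D is a non-target sink and must go
        assert dag.edge_pairs() == {("A", "T")}
        assert "D" not in dag.nodes

    def test_random_networks_acyclic_idempotent_target_safe(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            k = int(rng.integers(4, 9))
            names = [f"N{i}" for i in range(k)]
            triples = [(a, b, float(rng.random()))
                       for a in names for b in names
                       if a != b and rng.random() < 0.3]
            if not triples:
                continue
            net = net_from(triples, target="N0")
            dag = to_dag(net)
            g = dag.to_graph()
            assert nx.is_directed_acyclic_graph(g)
            again = to_dag(dag)
            assert again.edge_pairs() == dag.edge_pairs()
            target_in = {(a, b) for a, b, _ in triples if b == "N0"}
            assert target_in <= dag.edge_pairs()

    def test_confounder_cycle_loses_weakest_in_edge(self):
        # A has two out-edges (a confounder); the cycle edge entering it
        # (C->A, skill 0.5) is removed, then B and C collapse as sinks
        net = net_from([("A", "B", 0.9), ("B", "C", 0.1), ("C", "A", 0.5),
                        ("A", "T", 0.8)], target="T")
        dag = to_dag(net)
        assert dag.edge_pairs() == {("A", "T")}
        assert nx.is_directed_acyclic_graph(dag.to_graph())

    def test_target_cycle_keeps_upstream_chain(self):
        net = net_from([("A", "B", 0.9), ("B", "C", 0.1), ("C", "A", 0.5)],
                       target="C")
        dag = to_dag(net)
        # the cycle is truncated after the target: C's out-edge goes
        assert dag.edge_pairs() == {("A", "B"), ("B", "C")}


class TestExpertEdges:
    def base_dag(self):
        return to_dag(net_from([("A", "T", 0.5)], target="T"))

    def test_append_with_lag(self):
        dag = add_expert_edges(self.base_dag(), [("P", "T", -2)])
        edge = dag.edge("P", "T")
        assert edge.provenance == "expert" and edge.lag_steps == -2

    def test_cycle_creating_edge_rejected(self):
        dag = add_expert_edges(self.base_dag(), [("T", "B", 0)])
        with pytest.raises(ValueError, match="cycle"):
            add_expert_edges(dag, [("B", "A", 0)])  # closes A->T->B->A

    def test_duplicate_not_added(self):
        dag = self.base_dag()
        out = add_expert_edges(dag, [("A", "T", 0)])
        assert len(out.edges) == len(dag.edges)


class TestSerialization:
    def test_json_round_trip(self, tmp_path, four_species):
        net = net_from([("Y1", "Y2", 0.5), ("Y2", "Y3", 0.25)], target="Y4")
        path = tmp_path / "net.json"
        net.to_json(path)
        back = CausalNetwork.from_json(path)
        assert back.edge_pairs() == net.edge_pairs()
        assert back.target == net.target

    def test_dot_and_adjacency_exports(self):
        net = net_from([("A", "B", 0.5)], target="B")
        dot = net.to_dot()
        assert '"A" -> "B"' in dot
        adj = net.adjacency_frame()
        assert adj.loc["A", "B"] == 1 and adj.loc["B", "A"] == 0
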