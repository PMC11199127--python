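import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from ccmbn.bn import (AlignedTable, BayesNet, check_state_support, evaluate,
                      fit_cpds, infer, learn_structure_hillclimb, shift_align)
from ccmbn.netbuild import CausalEdge, CausalNetwork
from ccmbn.preprocess import DiscreteTable


def brute_force_posterior(bn, evidence, query):
    """Joint-enumeration oracle for exact inference."""
    card = bn.cardinalities
    hidden = [v for v in card if v != query and v not in evidence]
    post = np.zeros(card[query])
    for qv in range(card[query]):
        for combo in itertools.product(*[range(card[h]) for h in hidden]):
            assign = dict(evidence, **dict(zip(hidden, combo)))
            assign[query] = qv
            p = 1.0
            for node, (parents, tab) in bn.cpds.items():
                p *= tab[(assign[node], *[assign[par] for par in parents])]
            post[qv] += p
    return post / post.sum()


def random_bayesnet(n_nodes, seed, target=None, max_parents=3):
    """Random DAG over n_nodes with random CPTs (cards 2 or 3)."""
    rng = np.random.default_rng(seed)
    names = [f"V{i}" for i in range(n_nodes)]
    target = target or names[-1]
    edges = []
    for j in range(1, n_nodes):
        parents = rng.choice(j, size=min(j, int(rng.integers(0, max_parents + 1))),
                             replace=False)
        edges += [CausalEdge(names[p], names[j], 0.5) for p in parents]
    dag = CausalNetwork(names, edges, target)
    cards = {n: (2 if n == target else int(rng.integers(2, 4))) for n in names}
    g = dag.to_graph()
    cpds = {}
    for n in names:
        parents = sorted(g.predecessors(n))
        shape = (cards[n], *[cards[p] for p in parents])
        tab = rng.random(shape) + 0.1
        cpds[n] = (parents, tab / tab.sum(axis=0, keepdims=True))
    return BayesNet(dag, cards, cpds, target)


def sample_rows(bn, n, seed):
    """Ancestral sampling from a BayesNet."""
    rng = np.random.default_rng(seed)
    import networkx as nx

    order = list(nx.topological_sort(bn.dag.to_graph()))
    data = {}
    for node in order:
        parents, tab = bn.cpds[node]
        vals = np.empty(n, dtype=int)
        for i in range(n):
            col = tab[(slice(None), *[data[p][i] for p in parents])] \
                if parents else tab
            vals[i] = rng.choice(len(col), p=col)
        data[node] = vals
    return pd.DataFrame(data)


def chain_bayesnet(seed):
    """Binary 5-node chain with CPT entries in [0.2, 0.8], so every parent
    configuration keeps enough sampling support for parameter recovery."""
    rng = np.random.default_rng(seed)
    names = [f"V{i}" for i in range(5)]
    edges = [CausalEdge(names[i], names[i + 1], 0.5) for i in range(4)]
    dag = CausalNetwork(names, edges, names[-1])
    cards = {n: 2 for n in names}
    cpds = {}
    for i, n in enumerate(names):
        if i == 0:
            p1 = rng.uniform(0.3, 0.7)
            cpds[n] = ([], np.array([1 - p1, p1]))
        else:
            p1 = rng.uniform(0.2, 0.8, size=2)
            cpds[n] = ([names[i - 1]], np.vstack([1 - p1, p1]))
    return BayesNet(dag, cards, cpds, names[-1])


class TestShiftAlign:
    def make_table(self, n=40):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"A": rng.integers(0, 3, n),
                              "B": rng.integers(0, 3, n),
                              "T": rng.integers(0, 2, n)})
        return DiscreteTable(frame, {}, "T", {"A": 3, "B": 3, "T": 2})

    def test_zero_lags_identity(self):
        table = self.make_table()
        dag = CausalNetwork(["A", "T"],
                            [CausalEdge("A", "T", 0.5, lag_steps=0)], "T")
        out = shift_align(table, dag)
        assert len(out.frame) == 40
        assert (out.frame["A"].to_numpy()
                == table.frame["A"].to_numpy()).all()

    def test_single_cause_advanced(self):
        table = self.make_table()
        dag = CausalNetwork(["A", "T"],
                            [CausalEdge("A", "T", 0.5, lag_steps=-2)], "T")
        out = shift_align(table, dag)
        assert len(out.frame) == 38
        assert (out.frame["A"].to_numpy()
                == table.frame["A"].to_numpy()[:38]).all()
        assert (out.frame["T"].to_numpy()
                == table.frame["T"].to_numpy()[2:]).all()

    def test_max_shift_rule_two_causes(self):
        table = self.make_table()
        dag = CausalNetwork(
            ["A", "B", "T"],
            [CausalEdge("A", "T", 0.5, lag_steps=-1),
             CausalEdge("B", "T", 0.4, lag_steps=-3)], "T")
        out = shift_align(table, dag)
        assert len(out.frame) == 37
        assert out.shifts == {"T": 0, "A": 1, "B": 3}

    def test_upstream_shift_accumulates(self):
        table = self.make_table()
        dag = CausalNetwork(
            ["A", "B", "T"],
            [CausalEdge("A", "B", 0.5, lag_steps=-2),
             CausalEdge("B", "T", 0.4, lag_steps=-1)], "T")
        out = shift_align(table, dag)
        assert out.shifts == {"T": 0, "B": 1, "A": 3}

    def test_positive_lag_rejected(self):
        table = self.make_table()
        dag = CausalNetwork(["A", "T"],
                            [CausalEdge("A", "T", 0.5, lag_steps=2)], "T")
        with pytest.raises(ValueError):
            shift_align(table, dag)

    def test_excessive_shift_rejected(self):
        table = self.make_table(n=5)
        dag = CausalNetwork(["A", "T"],
                            [CausalEdge("A", "T", 0.5, lag_steps=-7)], "T")
        with pytest.raises(ValueError):
            shift_align(table, dag)


class TestFitCpds:
    def aligned_from(self, frame, cards):
        return AlignedTable(frame, {c: 0 for c in frame}, "T", cards)

    def test_parentless_node_smoothed_frequencies(self):
        frame = pd.DataFrame({"T": [1, 1, 0, 0]})
        dag = CausalNetwork(["T"], [], "T")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bn = fit_cpds(dag, self.aligned_from(frame, {"T": 2}), split=1.0)
        # (2 + 1) / (4 + 2) with add-1 smoothing
        assert np.allclose(bn.cpds["T"][1], [0.5, 0.5])

    def test_deterministic_copy_near_identity(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, 4000)
        frame = pd.DataFrame({"A": a, "T": a})
        dag = CausalNetwork(["A", "T"],
                            [CausalEdge("A", "T", 0.9, lag_steps=0)], "T")
        bn = fit_cpds(dag, self.aligned_from(frame, {"A": 2, "T": 2}))
        tab = bn.cpds["T"][1]
        assert tab[1, 1] > 0.99 and tab[0, 0] > 0.99

    def test_unseen_parent_configuration_uniform(self):
        frame = pd.DataFrame({"A": [0] * 50, "T": [0, 1] * 25})
        dag = CausalNetwork(["A", "T"],
                            [CausalEdge("A", "T", 0.9, lag_steps=0)], "T")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bn = fit_cpds(dag, self.aligned_from(frame, {"A": 2, "T": 2}))
        assert np.allclose(bn.cpds["T"][1][:, 1], 0.5)  # A=1 never observed

    def test_cpd_columns_normalized(self):
        bn = random_bayesnet(5, seed=3)
        rows = sample_rows(bn, 400, seed=4)
        aligned = AlignedTable(rows, {c: 0 for c in rows}, bn.target,
                               bn.cardinalities)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refit = fit_cpds(bn.dag, aligned)
        for node, (parents, tab) in refit.cpds.items():
            assert np.allclose(tab.sum(axis=0), 1.0, atol=1e-9)

    def test_cpd_recovery_within_tolerance(self):
        bn = chain_bayesnet(seed=11)
        rows = sample_rows(bn, 5000, seed=12)
        aligned = AlignedTable(rows, {c: 0 for c in rows}, bn.target,
                               bn.cardinalities)
        refit = fit_cpds(bn.dag, aligned, split=1.0)
        for node in bn.cardinalities:
            truth = bn.cpds[node][1]
            est = refit.cpds[node][1]
            assert np.max(np.abs(est - truth)) < 0.05


class TestInfer:
    @pytest.mark.parametrize("seed,n_nodes", [(0, 4), (1, 6), (2, 8)])
    def test_variable_elimination_matches_enumeration(self, seed, n_nodes):
        bn = random_bayesnet(n_nodes, seed=seed)
        rng = np.random.default_rng(seed + 50)
        for _ in range(5):
            others = [v for v in bn.cardinalities if v != bn.target]
            k = int(rng.integers(0, len(others) + 1))
            ev_vars = list(rng.choice(others, size=k, replace=False))
            ev = {v: int(rng.integers(bn.cardinalities[v])) for v in ev_vars}
            ve = infer(bn, ev)
            bf = brute_force_posterior(bn, ev, bn.target)
            assert np.allclose(ve, bf, atol=1e-9)

    def test_single_edge_reads_cpd_row(self):
        dag = CausalNetwork(["A", "T"],
                            [CausalEdge("A", "T", 0.9, lag_steps=0)], "T")
        cpds = {"A": ([], np.array([0.5, 0.5])),
                "T": (["A"], np.array([[0.7, 0.2], [0.3, 0.8]]))}
        bn = BayesNet(dag, {"A": 2, "T": 2}, cpds, "T")
        assert np.isclose(infer(bn, {"A": 1})[1], 0.8)

    def test_no_evidence_marginal(self):
        bn = random_bayesnet(5, seed=9)
        assert np.allclose(infer(bn, {}),
                           brute_force_posterior(bn, {}, bn.target), atol=1e-9)

    def test_contradictory_evidence_uniform_with_warning(self):
        dag = CausalNetwork(["A", "T"],
                            [CausalEdge("A", "T", 0.9, lag_steps=0)], "T")
        cpds = {"A": ([], np.array([1.0, 0.0])),
                "T": (["A"], np.array([[0.7, 0.2], [0.3, 0.8]]))}
        bn = BayesNet(dag, {"A": 2, "T": 2}, cpds, "T")
        with pytest.warns(UserWarning, match="contradictory"):
            post = infer(bn, {"A": 1})
        assert np.allclose(post, 0.5)

    def test_invalid_evidence_rejected(self):
        bn = random_bayesnet(4, seed=0)
        with pytest.raises(KeyError):
            infer(bn, {"nope": 0})
        first = [v for v in bn.cardinalities if v != bn.target][0]
        with pytest.raises(ValueError):
            infer(bn, {first: 99})


class TestEvaluate:
    def make_bn_with_test(self, probs, truth):
        """Single-parent net whose P(T=1|A=a) enumerates ``probs``."""
        k = len(probs)
        dag = CausalNetwork(["A", "T"],
                            [CausalEdge("A", "T", 0.9, lag_steps=0)], "T")
        tab = np.vstack([1 - np.asarray(probs), probs])
        cpds = {"A": ([], np.full(k, 1.0 / k)), "T": (["A"], tab)}
        bn = BayesNet(dag, {"A": k, "T": 2}, cpds, "T")
        bn.test_frame = pd.DataFrame({"A": range(k), "T": truth})
        return bn

    def test_hand_counted_accuracy_and_auc(self):
        bn = self.make_bn_with_test([0.9, 0.2, 0.7], [1, 0, 0])
        ev = evaluate(bn)
        assert ev.accuracy == pytest.approx(2 / 3)
        assert ev.auc == pytest.approx(1.0)

    def test_perfect_predictor(self):
        bn = self.make_bn_with_test([0.99, 0.01], [1, 0])
        ev = evaluate(bn)
        assert ev.accuracy == 1.0 and ev.auc == 1.0

    def test_constant_predictor_auc_half(self):
        bn = self.make_bn_with_test([0.5, 0.5], [1, 0])
        assert evaluate(bn).auc == pytest.approx(0.5)

    def test_confusion_matrix_counts(self):
        bn = self.make_bn_with_test([0.9, 0.2, 0.7], [1, 0, 0])
        ev = evaluate(bn)
        assert ev.confusion.tolist() == [[1, 1], [0, 1]]


class TestHillClimb:
    def test_independent_columns_no_edge(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"X": rng.integers(0, 2, 1500),
                              "Y": rng.integers(0, 2, 1500)})
        aligned = AlignedTable(frame, {"X": 0, "Y": 0}, "Y",
                               {"X": 2, "Y": 2})
        assert learn_structure_hillclimb(aligned).edges == []

    def test_copy_pair_single_edge(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 1000)
        frame = pd.DataFrame({"X": x, "Y": x})
        aligned = AlignedTable(frame, {"X": 0, "Y": 0}, "Y",
                               {"X": 2, "Y": 2})
        net = learn_structure_hillclimb(aligned)
        assert len(net.edges) == 1
        assert net.edge_pairs() <= {("X", "Y"), ("Y", "X")}

    def test_empty_table_rejected(self):
        aligned = AlignedTable(pd.DataFrame(), {}, "T", {})
        with pytest.raises(ValueError):
            learn_structure_hillclimb(aligned)

    def test_recovers_strong_chain(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, 2000)
        b = a ^ (rng.random(2000) < 0.05)
        frame = pd.DataFrame({"A": a, "B": b.astype(int)})
        aligned = AlignedTable(frame, {"A": 0, "B": 0}, "B",
                               {"A": 2, "B": 2})
        assert len(learn_structure_hillclimb(aligned).edges) == 1


class TestStateSupport:
    def test_balanced_three_state_passes(self):
        frame = pd.DataFrame({"A": [0, 1, 2] * 30, "T": [0, 1] * 45})
        aligned = AlignedTable(frame, {"A": 0, "T": 0}, "T",
                               {"A": 3, "T": 2})
        assert check_state_support(aligned).passed

    def test_exactly_twenty_fails_strict_rule(self):
        frame = pd.DataFrame({"A": [0] * 20 + [1] * 30,
                              "T": [0, 1] * 25})
        aligned = AlignedTable(frame, {"A": 0, "T": 0}, "T",
                               {"A": 2, "T": 2})
        report = check_state_support(aligned)
        assert not report.passed
        assert ("A", 0, 20) in report.failures

    def test_missing_state_fails(self):
        frame = pd.DataFrame({"A": [1] * 50, "T": [0, 1] * 25})
        aligned = AlignedTable(frame, {"A": 0, "T": 0}, "T",
                               {"A": 2, "T": 2})
        assert not check_state_support(aligned).passed


class TestSerialization:
    def test_json_round_trip_preserves_inference(self, tmp_path):
        bn = random_bayesnet(5, seed=21)
        path = tmp_path / "bn.json"
        bn.to_json(path)
        back = BayesNet.from_json(path)
        ev = {[v for v in bn.cardinalities if v != bn.target][0]: 1}
        assert np.allclose(infer(bn, ev), infer(back, ev), atol=1e-12)
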