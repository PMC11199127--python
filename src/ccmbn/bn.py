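"""Lag-aligned discrete Bayesian network.

The causal DAG (with per-edge lags from the ECCM stage) fixes the
structure; the categorized data, shifted so that each cause is aligned
with its delayed effect, supplies the conditional probability tables.
Inference is exact (variable elimination).  A BIC hill-climbing structure
learner is included as the conventional baseline the causal structure is
compared against.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .netbuild import CausalEdge, CausalNetwork
from .preprocess import DiscreteTable

__all__ = [
    "AlignedTable",
    "BayesNet",
    "shift_align",
    "fit_cpds",
    "infer",
    "evaluate",
    "learn_structure_hillclimb",
    "check_state_support",
]


@dataclass
class AlignedTable:
    """Categorized observations with causes advanced onto their effects.

    ``shifts`` records, per variable, how many rows it was advanced by.
    """

    frame: pd.DataFrame
    shifts: dict
    target: str
    cardinalities: dict


@dataclass
class BayesNet:
    """DAG + conditional probability tables over category codes.

    ``cpds[node]`` is ``(parents, table)`` with table shape
    (card(node), card(p1), ..., card(pk)); summing over axis 0 gives 1.
    """

    dag: CausalNetwork
    cardinalities: dict
    cpds: dict
    target: str
    test_frame: pd.DataFrame | None = None

    def parents(self, node: str) -> list:
        return list(self.cpds[node][0])

    # -- serialization --------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "target": self.target,
            "nodes": list(self.dag.nodes),
            "cardinalities": {k: int(v) for k, v in self.cardinalities.items()},
            "edges": [[e.source, e.target, int(e.lag_steps)]
                      for e in self.dag.edges],
            # row-major tables; axis 0 is the node's own state, then the
            # parents in the order listed
            "cpds": {n: {"parents": list(p), "table": t.tolist()}
                     for n, (p, t) in self.cpds.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "BayesNet":
        with open(path) as fh:
            payload = json.load(fh)
        edges = [CausalEdge(s, t, float("nan"), 0, lag) for s, t, lag
                 in payload["edges"]]
        dag = CausalNetwork(payload["nodes"], edges, payload["target"])
        cpds = {n: (list(d["parents"]), np.asarray(d["table"], float))
                for n, d in payload["cpds"].items()}
        return cls(dag, payload["cardinalities"], cpds, payload["target"])


def _target_shifts(dag: CausalNetwork) -> dict:
    """Per-variable advance (in rows) aligning each cause with the target.

    A parent of the target is advanced by the |lag| of its edge into the
    target.  A variable further upstream accumulates the lag of its
    maximum-skill out-edge plus the shift of that edge's head.  The target
    itself is never shifted.
    """
    g = dag.to_graph()
    target = dag.target
    shifts: dict[str, int] = {target: 0}

    def shift_of(v: str, stack=()) -> int:
        if v in shifts:
            return shifts[v]
        if v in stack:  # defensive; dag is acyclic
            return 0
        out = [e for e in dag.edges if e.source == v]
        if not out:
            shifts[v] = 0
            return 0
        direct = [e for e in out if e.target == target]
        if direct:
            best = max(direct, key=lambda e: (np.nan_to_num(e.mean_skill, nan=-1.0)))
            shifts[v] = abs(int(best.lag_steps))
        else:
            best = max(out, key=lambda e: np.nan_to_num(e.mean_skill, nan=-1.0))
            shifts[v] = abs(int(best.lag_steps)) + shift_of(best.target,
                                                            stack + (v,))
        return shifts[v]

    for n in g.nodes:
        shift_of(n)
    return shifts


def shift_align(table: DiscreteTable, dag: CausalNetwork) -> AlignedTable:
    """Advance each cause column by its lag so rows are cause/effect pairs.

    Rows without full coverage (the leading max-shift rows) are dropped.
    """
    for e in dag.edges:
        if e.lag_steps > 0:
            raise ValueError(f"edge {e.source}->{e.target} has positive lag")
    shifts = _target_shifts(dag)
    frame = table.frame
    n = len(frame)
    max_shift = max(shifts.values(), default=0)
    if max_shift >= n:
        raise ValueError(f"shift {max_shift} exceeds table length {n}")
    cols = {}
    for v in dag.nodes:
        if v not in frame.columns:
            raise KeyError(f"DAG node {v!r} missing from the table")
        s = shifts.get(v, 0)
        x = frame[v].to_numpy()
        cols[v] = x[max_shift - s: n - s]
    out = pd.DataFrame(cols, index=frame.index[max_shift:])
    cards = {v: table.cardinalities.get(v, int(frame[v].max()) + 1)
             for v in dag.nodes}
    return AlignedTable(out, shifts, table.target, cards)


@dataclass
class SupportReport:
    counts: pd.DataFrame
    passed: bool
    failures: list


def check_state_support(aligned: AlignedTable, min_cases: int = 20
                        ) -> SupportReport:
    """Per variable x state counts; each state must have > min_cases rows."""
    rows, failures = {}, []
    for col in aligned.frame.columns:
        card = aligned.cardinalities[col]
        counts = aligned.frame[col].value_counts()
        rows[col] = {s: int(counts.get(s, 0)) for s in range(card)}
        for s in range(card):
            if rows[col][s] <= min_cases:
                failures.append((col, s, rows[col][s]))
    frame = pd.DataFrame(rows).T.fillna(0).astype(int)
    return SupportReport(frame, not failures, failures)


def fit_cpds(dag: CausalNetwork, aligned: AlignedTable, split: float = 0.75,
             alpha: float = 1.0, min_cases: int = 20,
             enforce_support: bool = False) -> BayesNet:
    """Maximum-likelihood CPTs with add-``alpha`` smoothing.

    Fit uses the chronological first ``split`` of the rows; the remainder
    is kept on the returned net (``test_frame``) for evaluation.  State
    support below ``min_cases`` raises when ``enforce_support`` is set and
    warns otherwise.
    """
    report = check_state_support(aligned, min_cases)
    if not report.passed:
        msg = f"states with <= {min_cases} cases: {report.failures}"
        if enforce_support:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    frame = aligned.frame
    n_train = int(np.floor(split * len(frame)))
    train, test = frame.iloc[:n_train], frame.iloc[n_train:]
    if n_train < 1:
        raise ValueError("empty training partition")
    g = dag.to_graph()
    cards = aligned.cardinalities
    cpds = {}
    for node in dag.nodes:
        parents = sorted(g.predecessors(node))
        shape = (cards[node], *[cards[p] for p in parents])
        counts = np.zeros(shape)
        idx = tuple(train[c].to_numpy() for c in [node, *parents])
        np.add.at(counts, idx, 1.0)
        counts += alpha
        table = counts / counts.sum(axis=0, keepdims=True)
        cpds[node] = (parents, table)
    return BayesNet(dag, dict(cards), cpds, aligned.target, test)


# ---------------------------------------------------------------------------
# exact inference (variable elimination)


def _restrict(variables: list, table: np.ndarray, evidence: dict):
    """Slice a factor on its observed variables."""
    index = []
    keep = []
    for v in variables:
        if v in evidence:
            index.append(int(evidence[v]))
        else:
            index.append(slice(None))
            keep.append(v)
    return keep, table[tuple(index)]


def _expand(vars_: list, arr: np.ndarray, out_vars: list) -> np.ndarray:
    """Broadcast a factor's array onto a superset variable ordering."""
    missing = [v for v in out_vars if v not in vars_]
    arr = arr.reshape(arr.shape + (1,) * len(missing))
    cur = list(vars_) + missing
    return np.transpose(arr, [cur.index(v) for v in out_vars])


def _multiply(f1, f2):
    """Pointwise product of two factors (vars, array)."""
    v1, a1 = f1
    v2, a2 = f2
    out_vars = list(v1) + [v for v in v2 if v not in v1]
    return out_vars, _expand(v1, a1, out_vars) * _expand(v2, a2, out_vars)


def _sum_out(factor, var):
    vars_, arr = factor
    ax = vars_.index(var)
    return [v for v in vars_ if v != var], arr.sum(axis=ax)


def infer(bn: BayesNet, evidence: dict | None = None,
          query: str | None = None) -> np.ndarray:
    """Exact posterior over the query node (default: the target).

    Evidence maps variable names to category codes.  Contradictory
    (zero-probability) evidence yields a uniform distribution with a
    warning.
    """
    evidence = dict(evidence or {})
    query = query or bn.target
    if query in evidence:
        raise ValueError("query variable cannot also be evidence")
    for v, code in evidence.items():
        if v not in bn.cardinalities:
            raise KeyError(f"unknown evidence variable {v!r}")
        if not 0 <= int(code) < bn.cardinalities[v]:
            raise ValueError(f"evidence code {code} invalid for {v!r}")
    factors = []
    for node, (parents, table) in bn.cpds.items():
        keep, arr = _restrict([node, *parents], table, evidence)
        factors.append((keep, np.asarray(arr, float)))
    # eliminate hidden variables in a fixed (sorted) order
    hidden = sorted(v for v in bn.cardinalities
                    if v != query and v not in evidence)
    for h in hidden:
        related = [f for f in factors if h in f[0]]
        if not related:
            continue
        factors = [f for f in factors if h not in f[0]]
        prod = related[0]
        for f in related[1:]:
            prod = _multiply(prod, f)
        factors.append(_sum_out(prod, h))
    result = ([], np.array(1.0))
    for f in factors:
        result = _multiply(result, f)
    vars_, arr = result
    if vars_ != [query]:  # all hidden vars eliminated, so only query remains
        raise AssertionError(f"elimination left variables {vars_}")
    total = arr.sum()
    if total <= 0 or not np.isfinite(total):
        warnings.warn("contradictory evidence: posterior undefined, "
                      "returning uniform", stacklevel=2)
        card = bn.cardinalities[query]
        return np.full(card, 1.0 / card)
    return arr / total


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class Evaluation:
    accuracy: float
    auc: float
    confusion: np.ndarray        # rows: observed, cols: predicted
    probabilities: np.ndarray
    observed: np.ndarray


def evaluate(bn: BayesNet, test: pd.DataFrame | None = None,
             cutoff: float = 0.5) -> Evaluation:
    """Score P(target = 1 | parents) on the held-out rows.

    Predicted class is 1 iff the probability is >= ``cutoff``.  AUC is the
    rank statistic over the predicted probabilities (ties get half
    credit); with a single observed class it is undefined (nan).
    """
    test = bn.test_frame if test is None else test
    if test is None or len(test) == 0:
        raise ValueError("no test partition available")
    parents = bn.parents(bn.target)
    probs = np.empty(len(test))
    for i, (_, row) in enumerate(test.iterrows()):
        ev = {p: int(row[p]) for p in parents}
        probs[i] = infer(bn, ev)[1]
    obs = test[bn.target].to_numpy().astype(int)
    pred = (probs >= cutoff).astype(int)
    accuracy = float(np.mean(pred == obs))
    confusion = np.zeros((2, 2), dtype=int)
    np.add.at(confusion, (obs, pred), 1)
    n_pos = int(obs.sum())
    n_neg = len(obs) - n_pos
    if n_pos == 0 or n_neg == 0:
        auc = float("nan")
    else:
        ranks = rankdata(probs)
        auc = float((ranks[obs == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                    / (n_pos * n_neg))
    return Evaluation(accuracy, auc, confusion, probs, obs)


# ---------------------------------------------------------------------------
# hill-climbing structure learning (baseline)


def _bic_node(data: pd.DataFrame, node: str, parents: tuple, cards: dict,
              cache: dict) -> float:
    key = (node, parents)
    if key in cache:
        return cache[key]
    n = len(data)
    shape = (cards[node], *[cards[p] for p in parents])
    counts = np.zeros(shape)
    idx = tuple(data[c].to_numpy() for c in [node, *parents])
    np.add.at(counts, idx, 1.0)
    parent_tot = counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0,
                      counts * np.log(counts / parent_tot), 0.0).sum()
    n_free = (cards[node] - 1) * int(np.prod(shape[1:], dtype=float))
    score = ll - 0.5 * np.log(n) * n_free
    cache[key] = score
    return score


def learn_structure_hillclimb(aligned: AlignedTable, max_parents: int = 4,
                              seed: int | None = None) -> CausalNetwork:
    """Greedy BIC hill climbing from the empty graph.

    Moves are edge additions, removals and reversals; the best
    score-improving move is taken until none remains.  Move enumeration is
    lexicographic, so the procedure is deterministic (``seed`` is accepted
    for interface symmetry but unused).
    """
    data = aligned.frame
    if len(data) == 0:
        raise ValueError("empty table")
    cards = aligned.cardinalities
    nodes = sorted(data.columns)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    cache: dict = {}

    def node_score(node, graph):
        parents = tuple(sorted(graph.predecessors(node)))
        return _bic_node(data, node, parents, cards, cache)

    scores = {n: node_score(n, g) for n in nodes}
    improved = True
    while improved:
        improved = False
        best_gain, best_move = 1e-9, None
        for u in nodes:
            for v in nodes:
                if u == v:
                    continue
                if g.has_edge(u, v):
                    for move in ("remove", "reverse"):
                        g.remove_edge(u, v)
                        if move == "reverse":
                            g.add_edge(v, u)
                            ok = nx.is_directed_acyclic_graph(g) and \
                                g.in_degree(u) <= max_parents
                            gain = (node_score(v, g) - scores[v]
                                    + node_score(u, g) - scores[u]) if ok else -np.inf
                            g.remove_edge(v, u)
                        else:
                            gain = node_score(v, g) - scores[v]
                        g.add_edge(u, v)
                        if gain > best_gain:
                            best_gain, best_move = gain, (move, u, v)
                elif g.in_degree(v) < max_parents:
                    g.add_edge(u, v)
                    if nx.is_directed_acyclic_graph(g):
                        gain = node_score(v, g) - scores[v]
                        if gain > best_gain:
                            best_gain, best_move = gain, ("add", u, v)
                    g.remove_edge(u, v)
        if best_move is not None:
            move, u, v = best_move
            if move == "add":
                g.add_edge(u, v)
            elif move == "remove":
                g.remove_edge(u, v)
            else:
                g.remove_edge(u, v)
                g.add_edge(v, u)
            scores = {n: node_score(n, g) for n in nodes}
            improved = True
    edges = [CausalEdge(u, v, mean_skill=float("nan"), provenance="ccm")
             for u, v in sorted(g.edges)]
    return CausalNetwork(nodes, edges, aligned.target)
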