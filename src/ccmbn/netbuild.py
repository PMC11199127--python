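"""Target-focused causal network construction and DAG conversion.

The protocol: (1) screen every variable against the designated target by
sliding-window CCM in both directions; (2) run CCM over all ordered pairs
within the screening survivors; (3) keep edges with enough converged
windows and mean skill; (4) refine with ECCM lag scans (dropping false and
synchrony-driven interactions and attaching lags); (5) validate with
phase-randomized surrogates; (6) break feedback loops and prune sinks so a
Bayesian network can be fit on the result.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from .ccm import (cross_map, sliding_window_ccm, surrogate_significance,
                  window_diff_flags)
from .eccm import eccm_scan
from .edm import EmbeddingParams, select_embedding
from .series import MultivariateSeries

__all__ = [
    "CausalEdge",
    "CausalNetwork",
    "build_target_network",
    "pairwise_ccm_network",
    "refine_with_eccm",
    "apply_surrogate_filter",
    "to_dag",
    "add_expert_edges",
]

log = logging.getLogger("ccmbn.netbuild")

SKILL_MIN = 0.01
MIN_WINDOWS = 10


@dataclass
class CausalEdge:
    """A directed causal edge source -> target with its CCM evidence."""

    source: str
    target: str
    mean_skill: float
    n_converged_windows: int = 0
    lag_steps: int = 0              # <= 0: cause precedes effect
    significant: bool | None = None
    provenance: str = "ccm"         # "ccm" or "expert"

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("self edges are not allowed")


@dataclass
class CausalNetwork:
    """Directed weighted edge set over named nodes (may contain cycles)."""

    nodes: list
    edges: list
    target: str | None = None

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, mean_skill=e.mean_skill,
                       lag_steps=e.lag_steps, provenance=e.provenance)
        return g

    def edge(self, source: str, target: str) -> CausalEdge | None:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        return None

    def edge_pairs(self) -> set:
        return {(e.source, e.target) for e in self.edges}

    def to_json(self, path=None) -> str:
        payload = {"target": self.target, "nodes": list(self.nodes),
                   "edges": [asdict(e) for e in self.edges]}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "CausalNetwork":
        with open(path) as fh:
            payload = json.load(fh)
        edges = [CausalEdge(**e) for e in payload["edges"]]
        return cls(payload["nodes"], edges, payload.get("target"))

    def to_dot(self) -> str:
        lines = ["digraph causal {"]
        for n in self.nodes:
            lines.append(f'  "{n}";')
        for e in self.edges:
            lines.append(
                f'  "{e.source}" -> "{e.target}" '
                f'[label="p={e.mean_skill:.3f}, lag={e.lag_steps}"];')
        lines.append("}")
        return "\n".join(lines)

    def adjacency_frame(self):
        """Binary cause (rows) x effect (columns) adjacency matrix."""
        import pandas as pd

        mat = pd.DataFrame(0, index=self.nodes, columns=self.nodes, dtype=int)
        for e in self.edges:
            mat.loc[e.source, e.target] = 1
        return mat


def _pair_ccm(cause: np.ndarray, effect: np.ndarray, params: EmbeddingParams,
              window: int, gap: int, sliding: bool,
              stationarity: bool, diff_flags=None,
              rng=None) -> tuple[float | None, int]:
    """Mean skill and converged-window count for one ordered pair."""
    if sliding:
        res = sliding_window_ccm(cause, effect, params, window=window,
                                 gap=gap, stationarity=stationarity,
                                 diff_flags=diff_flags)
        return res.mean_skill, res.n_converged
    curve = cross_map(cause, effect, params, rng=rng)
    if not curve.converged:
        return None, 0
    return curve.final_skill, 1


def pairwise_ccm_network(
    series: MultivariateSeries,
    params: EmbeddingParams | dict | None = None,
    window: int = 100,
    gap: int = 10,
    skill_min: float = SKILL_MIN,
    min_windows: int = MIN_WINDOWS,
    sliding: bool = True,
    stationarity: bool = True,
    seed: int = 0,
    target: str | None = None,
) -> CausalNetwork:
    """CCM over every ordered pair of variables, with the standard filters.

    The validation protocol for systems small enough to skip the
    target-focused screen: each ordered pair is cross-mapped (sliding
    windows by default, whole-frame leave-one-out cross maps with
    ``sliding=False``) and edges pass with mean converged skill >=
    ``skill_min`` over >= ``min_windows`` converged windows.
    """
    cols = {v: series.column(v) for v in series.variables}
    if isinstance(params, EmbeddingParams):
        pmap = {v: params for v in series.variables}
    elif isinstance(params, dict):
        pmap = dict(params)
    else:
        span = (window // 4) if sliding else None
        pmap = {v: select_embedding(x[: min(len(x), 500)], max_span=span)
                for v, x in cols.items()}
    flags = None
    if sliding and stationarity:
        flags = {v: window_diff_flags(x, window, gap) for v, x in cols.items()}
    rng = None if sliding else np.random.default_rng(seed)
    min_w = min_windows if sliding else 1
    edges = []
    for cause in series.variables:
        for effect in series.variables:
            if cause == effect:
                continue
            df = (flags[cause], flags[effect]) if flags is not None else None
            skill, n_conv = _pair_ccm(cols[cause], cols[effect], pmap[effect],
                                      window, gap, sliding, stationarity,
                                      df, rng)
            if skill is not None and skill >= skill_min and n_conv >= min_w:
                edges.append(CausalEdge(cause, effect, float(skill), n_conv))
    return CausalNetwork(list(series.variables), edges, target)


def build_target_network(
    series: MultivariateSeries,
    target: str,
    params: EmbeddingParams | dict | None = None,
    window: int = 100,
    gap: int = 10,
    skill_min: float = SKILL_MIN,
    min_windows: int = MIN_WINDOWS,
    sliding: bool = True,
    stationarity: bool = True,
    select_params: bool = True,
    seed: int = 0,
) -> CausalNetwork:
    """Two-iteration target-focused CCM screen.

    Iteration 1 cross-maps every variable against the target in both
    directions; variables reaching mean skill >= ``skill_min`` in either
    direction form the screening set.  Iteration 2 cross-maps all ordered
    pairs within the screening set plus the target, and edges passing the
    converged-window and skill filters are retained.  With
    ``sliding=False`` a single whole-series cross map is used instead and
    the window-count filter degenerates to requiring convergence.

    Embedding parameters: a dict maps variable name -> EmbeddingParams for
    the *effect* (manifold) variable; a single EmbeddingParams applies
    everywhere; None selects per variable (mutual-information lag, simplex
    dimension) capped at 20, falling back to E=5, l=2.
    """
    if target not in series.variables:
        raise KeyError(f"target {target!r} not found in series")
    cols = {v: series.column(v) for v in series.variables}
    if isinstance(params, EmbeddingParams):
        pmap = {v: params for v in series.variables}
    elif isinstance(params, dict):
        pmap = dict(params)
    elif select_params:
        span = (window // 4) if sliding else None
        pmap = {v: select_embedding(x[: min(len(x), 500)], max_span=span)
                for v, x in cols.items()}
    else:
        pmap = {v: EmbeddingParams() for v in series.variables}
    min_w = min_windows if sliding else 1
    flags = None
    if sliding and stationarity:
        # ADF decisions depend only on the variable and window, not the
        # pair, so compute them once per variable
        flags = {v: window_diff_flags(x, window, gap) for v, x in cols.items()}

    rng = None if sliding else np.random.default_rng(seed)

    def pair_stat(cause: str, effect: str):
        df = (flags[cause], flags[effect]) if flags is not None else None
        return _pair_ccm(cols[cause], cols[effect], pmap[effect],
                         window, gap, sliding, stationarity, df, rng)

    screening: list[str] = []
    stats: dict[tuple, tuple] = {}
    for v in series.variables:
        if v == target:
            continue
        hit = False
        for cause, effect in ((v, target), (target, v)):
            skill, n_conv = pair_stat(cause, effect)
            stats[(cause, effect)] = (skill, n_conv)
            if skill is not None and skill >= skill_min:
                hit = True
        log.info("screen %s <-> %s: %s", v, target, hit)
        if hit:
            screening.append(v)
    if not screening:
        warnings.warn("screening set empty: no variable cross-maps the "
                      "target above the skill threshold", stacklevel=2)
        return CausalNetwork([target], [], target)

    members = screening + [target]
    edges: list[CausalEdge] = []
    for cause in members:
        for effect in members:
            if cause == effect:
                continue
            if (cause, effect) in stats:
                skill, n_conv = stats[(cause, effect)]
            else:
                skill, n_conv = pair_stat(cause, effect)
            keep = skill is not None and skill >= skill_min and n_conv >= min_w
            log.info("edge %s->%s skill=%s converged=%d kept=%s",
                     cause, effect, skill, n_conv, keep)
            if keep:
                edges.append(CausalEdge(cause, effect, float(skill), n_conv))
    return CausalNetwork(members, edges, target)


def refine_with_eccm(
    network: CausalNetwork,
    series: MultivariateSeries,
    params: EmbeddingParams = EmbeddingParams(5, 2),
    frame: int = 400,
    max_library: int = 200,
    max_shift: int = 20,
) -> CausalNetwork:
    """Filter the network with ECCM lag scans.

    Each undirected pair is scanned once; edges classified as false
    interactions or common-force synchrony are dropped, enslavement keeps
    only the dominant direction, and surviving edges carry their best
    non-positive lag.
    """
    if not network.edges:
        return CausalNetwork(list(network.nodes), [], network.target)
    pairs = {tuple(sorted((e.source, e.target))) for e in network.edges}
    profiles = {}
    for a, b in sorted(pairs):
        profiles[(a, b)] = eccm_scan(series.column(a), series.column(b),
                                     params, frame, max_library, max_shift)
    kept: list[CausalEdge] = []
    for e in network.edges:
        a, b = sorted((e.source, e.target))
        prof = profiles[(a, b)]
        forward = (e.source, e.target) == (a, b)  # edge direction is a->b?
        cls = prof.classification
        keep, lag = False, 0
        if cls in ("false_interaction", "synchrony_common_force"):
            keep = False
        elif cls == "bidirectional":
            keep = True
            lag = prof.causal_lag_xy if forward else prof.causal_lag_yx
        elif cls == "unidirectional_xy" or cls == "synchrony_enslaved_xy":
            keep = forward
            lag = prof.causal_lag_xy
        elif cls == "unidirectional_yx" or cls == "synchrony_enslaved_yx":
            keep = not forward
            lag = prof.causal_lag_yx
        log.info("eccm %s->%s class=%s kept=%s lag=%d",
                 e.source, e.target, cls, keep, lag)
        if keep:
            kept.append(CausalEdge(e.source, e.target, e.mean_skill,
                                   e.n_converged_windows, int(lag),
                                   e.significant, e.provenance))
    return CausalNetwork(list(network.nodes), kept, network.target)


def apply_surrogate_filter(
    network: CausalNetwork,
    series: MultivariateSeries,
    params: EmbeddingParams = EmbeddingParams(5, 2),
    n_surrogates: int = 1000,
    quantile: float = 0.9,
    seed: int = 0,
    frame: int = 400,
) -> CausalNetwork:
    """Drop edges whose cross-map skill does not beat phase-randomized
    surrogates of the cause at the given quantile."""
    kept = []
    rng = np.random.default_rng(seed)
    for e in sorted(network.edges, key=lambda e: (e.source, e.target)):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        if e.provenance == "expert":
            kept.append(e)
            continue
        obs, qval, sig = surrogate_significance(
            series.column(e.source), series.column(e.target), params,
            n_surrogates=n_surrogates, quantile=quantile, seed=sub_seed,
            frame=frame)
        log.info("surrogate %s->%s obs=%.3f q=%.3f sig=%s",
                 e.source, e.target, obs, qval, sig)
        if sig:
            kept.append(CausalEdge(e.source, e.target, e.mean_skill,
                                   e.n_converged_windows, e.lag_steps,
                                   True, e.provenance))
    return CausalNetwork(list(network.nodes), kept, network.target)


def _canonical_cycles(g: nx.DiGraph) -> list:
    """Simple cycles rotated to start at their lexicographically smallest
    node, sorted lexicographically — a deterministic processing order."""
    cycles = []
    for cyc in nx.simple_cycles(g):
        i = min(range(len(cyc)), key=lambda j: str(cyc[j]))
        cycles.append(tuple(cyc[i:] + cyc[:i]))
    return sorted(cycles, key=lambda c: (len(c), tuple(map(str, c))))


def to_dag(network: CausalNetwork, target: str | None = None
           ) -> CausalNetwork:
    """Break feedback loops and prune non-target sinks.

    While cycles remain (processed in canonical order): a cycle through
    the target loses the target's out-edge inside the cycle; otherwise the
    lowest-mean-skill cycle edge entering a confounder (a node with >= 2
    out-edges) is removed, ties broken lexicographically; a cycle with no
    confounder loses its weakest edge.  Then nodes without out-edges other
    than the target are deleted repeatedly.  In-edges of the target are
    never removed, and the result is acyclic and idempotent under
    re-application.
    """
    target = target or network.target
    if target is None:
        raise ValueError("a target node is required for DAG conversion")
    if not network.edges:
        return CausalNetwork([target], [], target)
    g = network.to_graph()
    edges = {(e.source, e.target): e for e in network.edges}

    while True:
        cycles = _canonical_cycles(g)
        if not cycles:
            break
        cyc = cycles[0]
        cyc_edges = [(cyc[i], cyc[(i + 1) % len(cyc)]) for i in range(len(cyc))]
        if target in cyc:
            i = cyc.index(target)
            drop = (target, cyc[(i + 1) % len(cyc)])
        else:
            confounders = {n for n in g.nodes if g.out_degree(n) >= 2}
            into_conf = [ed for ed in cyc_edges if ed[1] in confounders]
            pool = into_conf if into_conf else cyc_edges
            drop = min(pool, key=lambda ed: (edges[ed].mean_skill,
                                             str(ed[0]), str(ed[1])))
        log.info("dagify: removing cycle edge %s->%s", *drop)
        g.remove_edge(*drop)
        del edges[drop]

    changed = True
    while changed:
        changed = False
        for n in sorted(g.nodes, key=str):
            if n != target and g.out_degree(n) == 0:
                log.info("dagify: pruning sink %s", n)
                g.remove_node(n)
                edges = {k: v for k, v in edges.items() if n not in k}
                changed = True
    kept = [edges[(u, v)] for u, v in g.edges]
    return CausalNetwork(sorted(g.nodes, key=str), kept, target)


def add_expert_edges(dag: CausalNetwork, new_edges: list) -> CausalNetwork:
    """Append expert-knowledge edges (source, target[, lag]) to a DAG.

    Edges that already exist are ignored; edges that would create a cycle
    are rejected.
    """
    g = dag.to_graph()
    out = CausalNetwork(list(dag.nodes), list(dag.edges), dag.target)
    for spec in new_edges:
        source, tgt = spec[0], spec[1]
        lag = int(spec[2]) if len(spec) > 2 else 0
        if (source, tgt) in out.edge_pairs():
            continue
        g.add_edge(source, tgt)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError(f"expert edge {source}->{tgt} would create a cycle")
        out.edges.append(CausalEdge(source, tgt, mean_skill=float("nan"),
                                    n_converged_windows=0, lag_steps=lag,
                                    significant=None, provenance="expert"))
        for n in (source, tgt):
            if n not in out.nodes:
                out.nodes.append(n)
    return out
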