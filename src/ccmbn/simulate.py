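"""Synthetic validation systems with known causal structure.

Two generators live here:

* a four-species coupled logistic map (chaotic, discrete time) with the
  causal chain Y1 -> Y2 -> Y3 -> Y4, in a homogeneous regime and a
  heterogeneous regime where the couplings through Y2 and Y3 are weakened
  by multiplicative noise over the later part of the run;
* a "lake-like" seasonal multivariate series in which the user declares
  lagged parent->child dependencies (a DAG) and gets the ground truth back
  alongside the data — used to exercise the preprocessing, network and
  Bayesian-network stages against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import MultivariateSeries

__all__ = [
    "SimConfig",
    "GroundTruth",
    "FOUR_SPECIES_DIRECT_EDGES",
    "FOUR_SPECIES_INDIRECT_EDGES",
    "four_species_step",
    "simulate_four_species",
    "heterogenize",
    "simulate_lake_like",
]

FOUR_SPECIES_DIRECT_EDGES = (("Y1", "Y2"), ("Y2", "Y3"), ("Y3", "Y4"))
FOUR_SPECIES_INDIRECT_EDGES = (("Y1", "Y3"), ("Y1", "Y4"), ("Y2", "Y4"))


@dataclass
class SimConfig:
    """Configuration of the four-species simulator.

    ``weaken_fraction`` is the trailing fraction of the series in which the
    Y2/Y3 couplings are degraded (heterogeneous regime only).  ``burn_in``
    steps are simulated and discarded before the returned series starts, so
    analyses see post-transient chaotic dynamics.
    """

    n_steps: int = 1000
    init: tuple[float, float, float, float] = (0.4, 0.4, 0.4, 0.4)
    regime: str = "homogeneous"
    weaken_fraction: float = 2.0 / 3.0
    noise_low: float = 0.5
    noise_high: float = 1.0
    seed: int = 0
    burn_in: int = 100

    def __post_init__(self) -> None:
        if self.n_steps < 50:
            raise ValueError("n_steps must be >= 50")
        if len(self.init) != 4 or not all(0.0 < v < 1.0 for v in self.init):
            raise ValueError("init must be 4 values strictly inside (0, 1)")
        if self.regime not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0.0 <= self.weaken_fraction <= 1.0:
            raise ValueError("weaken_fraction must lie in [0, 1]")
        if self.noise_low > self.noise_high:
            raise ValueError("noise_low must be <= noise_high")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """True causal edges of a simulated system (direct vs. indirect)."""

    direct_edges: tuple[tuple[str, str], ...]
    indirect_edges: tuple[tuple[str, str], ...] = ()
    lag_steps: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        direct = set(self.direct_edges)
        if direct & set(self.indirect_edges):
            raise ValueError("direct and indirect edge sets must be disjoint")
        for a, b in list(self.direct_edges) + list(self.indirect_edges):
            if a == b:
                raise ValueError("self edges are not allowed")


FOUR_SPECIES_TRUTH = GroundTruth(
    direct_edges=FOUR_SPECIES_DIRECT_EDGES,
    indirect_edges=FOUR_SPECIES_INDIRECT_EDGES,
    lag_steps={e: 1 for e in FOUR_SPECIES_DIRECT_EDGES},
)


def four_species_step(state: np.ndarray) -> np.ndarray:
    """One update of the coupled logistic maps.

    Y1(t+1) = Y1 (3.9  - 3.9 Y1)
    Y2(t+1) = Y2 (3.6  - 0.4 Y1 - 3.6 Y2)
    Y3(t+1) = Y3 (3.6  - 0.4 Y2 - 3.6 Y3)
    Y4(t+1) = Y4 (3.8  - 0.35 Y3 - 3.8 Y4)
    """
    y1, y2, y3, y4 = state
    return np.array(
        [
            y1 * (3.9 - 3.9 * y1),
            y2 * (3.6 - 0.4 * y1 - 3.6 * y2),
            y3 * (3.6 - 0.4 * y2 - 3.6 * y3),
            y4 * (3.8 - 0.35 * y3 - 3.8 * y4),
        ]
    )


def _iterate(init: np.ndarray, n: int) -> np.ndarray:
    out = np.empty((n, 4))
    state = np.asarray(init, dtype=float)
    for i in range(n):
        out[i] = state
        state = four_species_step(state)
        if np.any(np.abs(state) > 10.0):
            raise ValueError(
                "trajectory diverged (|Y| > 10); invalid initial condition"
            )
    return out

def simulate_four_species(config: SimConfig) -> MultivariateSeries:
    """Homogeneous run of the four-species system (deterministic).

    Returns ``n_steps`` rows after discarding ``burn_in`` transient steps.
    """
    traj = _iterate(np.asarray(config.init, float), config.n_steps + config.burn_in)
    traj = traj[config.burn_in :]
    frame = pd.DataFrame(traj, columns=["Y1", "Y2", "Y3", "Y4"],
                         index=pd.RangeIndex(config.n_steps))
    return MultivariateSeries(frame, step_days=1.0)


def heterogenize(series: MultivariateSeries, config: SimConfig) -> MultivariateSeries:
    """Weaken the Y2/Y3 couplings over the trailing ``weaken_fraction`` rows.

    The leading 1 - weaken_fraction of the series is left untouched.  From
    the split point on, the system is re-iterated from the state at the
    split, and after every update Y2 and Y3 are multiplied by i.i.d.
    Uniform(noise_low, noise_high) draws and clipped to [0, 1], so the
    perturbation propagates through the dynamics.
    """
    vals = series.values.copy()
    n = len(vals)
    n_weak = int(round(config.weaken_fraction * n))
    if n_weak == 0:
        return series.copy()
    rng = np.random.default_rng(config.seed)
    # row 0 has no predecessor to iterate from, so it always stays
    split = max(n - n_weak, 1)
    state = vals[split - 1].copy()
    for i in range(split, n):
        state = four_species_step(state)
        state[1] *= rng.uniform(config.noise_low, config.noise_high)
        state[2] *= rng.uniform(config.noise_low, config.noise_high)
        state = np.clip(state, 0.0, 1.0)
        vals[i] = state
    frame = pd.DataFrame(vals, columns=series.variables, index=series.frame.index)
    return MultivariateSeries(frame, step_days=series.step_days)


def simulate_heterogeneous(config: SimConfig) -> MultivariateSeries:
    """Convenience: homogeneous run followed by :func:`heterogenize`."""
    return heterogenize(simulate_four_species(config), config)


def simulate(config: SimConfig) -> MultivariateSeries:
    """Dispatch on ``config.regime``."""
    if config.regime == "heterogeneous":
        return simulate_heterogeneous(config)
    return simulate_four_species(config)


def four_species_replicate(n_steps: int = 1000, regime: str = "homogeneous",
                           seed: int = 0) -> MultivariateSeries:
    """One replicate run: the default initial condition (0.4, 0.4, 0.4, 0.4)
    jittered by +-0.05 under the seed, so replicates sample different
    stretches of the attractor."""
    rng = np.random.default_rng(seed)
    init = tuple(0.4 + rng.uniform(-0.05, 0.05, 4))
    cfg = SimConfig(n_steps=n_steps, init=init, regime=regime, seed=seed)
    return simulate(cfg)


def simulate_lake_like(
    n_steps: int = 600,
    edges: list[tuple] | None = None,
    seasonal_period: float = 73.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    step_days: float = 5.0,
    variables: list[str] | None = None,
) -> tuple[MultivariateSeries, GroundTruth]:
    """Seasonal multivariate series with declared lagged causal edges.

    Parameters
    ----------
    edges
        Tuples ``(parent, child, lag)`` or ``(parent, child, lag, coef)``;
        lags are positive sample counts (child at t depends on parent at
        t - lag).  The declaration must form a DAG.
    seasonal_period
        Period (in samples) of the sinusoidal drive given to root
        variables; with 5-day steps the default 73 is one year.
    variables
        Optional explicit variable list (roots with no edges are allowed).

    Root variables are phase-shifted sinusoids plus Gaussian noise; each
    child is the coefficient-weighted sum of its lagged parents plus noise.
    Returns the series together with its :class:`GroundTruth`.
    """
    import networkx as nx

    edges = list(edges or [])
    norm_edges = []
    for e in edges:
        if len(e) == 3:
            parent, child, lag = e
            coef = 0.8
        else:
            parent, child, lag, coef = e
        if lag < 0:
            raise ValueError("edge lags must be non-negative sample counts")
        norm_edges.append((str(parent), str(child), int(lag), float(coef)))

    g = nx.DiGraph()
    names: list[str] = list(variables or [])
    for parent, child, _, _ in norm_edges:
        g.add_edge(parent, child)
        for v in (parent, child):
            if v not in names:
                names.append(v)
    if not names:
        names = ["A", "B"]
    g.add_nodes_from(names)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("declared edges contain a cycle; a DAG is required")

    rng = np.random.default_rng(seed)
    order = list(nx.topological_sort(g))
    t = np.arange(n_steps)
    data: dict[str, np.ndarray] = {}
    for k, name in enumerate(order):
        parents = [(p, lag, coef) for p, c, lag, coef in norm_edges if c == name]
        noise = rng.normal(0.0, noise_sd, n_steps) if noise_sd > 0 else 0.0
        if not parents:
            phase = 2.0 * np.pi * (names.index(name) / max(len(names), 1))
            data[name] = np.sin(2.0 * np.pi * t / seasonal_period + phase) + noise
        else:
            x = np.zeros(n_steps)
            for p, lag, coef in parents:
                shifted = np.roll(data[p], lag)
                if lag > 0:
                    shifted[:lag] = data[p][0]
                x += coef * shifted
            data[name] = x + noise
    frame = pd.DataFrame({n: data[n] for n in names},
                         index=np.arange(n_steps, dtype=float) * step_days)
    truth = GroundTruth(
        direct_edges=tuple((p, c) for p, c, _, _ in norm_edges),
        lag_steps={(p, c): lag for p, c, lag, _ in norm_edges},
    )
    return MultivariateSeries(frame, step_days=step_days), truth
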