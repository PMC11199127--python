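"""Permutation-based sensitivity analysis of a fitted Bayesian network.

Random category assignments over all non-target nodes ("environmental
scenarios") are pushed through exact inference; the spread of the inferred
bloom probabilities, grouped by each variable's categories on the
high-probability and low-probability sides, measures that variable's
contribution to the model output.  Mean maximizing / minimizing scenarios
summarize which category profiles drive the target up or down.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .bn import BayesNet, infer

__all__ = [
    "ScenarioSet",
    "random_scenarios",
    "variable_contributions",
    "mean_scenarios",
]

MAX_SCENARIOS = 20000


@dataclass
class ScenarioSet:
    """Category assignments over BN inputs plus inferred P(target = high)."""

    scenarios: pd.DataFrame
    probabilities: np.ndarray
    seed: int
    target: str

    def __post_init__(self) -> None:
        if len(self.scenarios) > MAX_SCENARIOS:
            raise ValueError(f"scenario count exceeds {MAX_SCENARIOS}")
        p = self.probabilities
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


def random_scenarios(bn: BayesNet, n: int = MAX_SCENARIOS, seed: int = 0
                     ) -> ScenarioSet:
    """Up to ``n`` distinct uniform random assignments of all non-target
    nodes, with P(target = high) inferred for each.

    When the full category space holds no more than ``n`` assignments it
    is enumerated exhaustively instead of sampled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    n = min(n, MAX_SCENARIOS)
    inputs = sorted(v for v in bn.cardinalities if v != bn.target)
    cards = [bn.cardinalities[v] for v in inputs]
    space = int(np.prod(cards, dtype=float)) if cards else 0
    rng = np.random.default_rng(seed)
    if space and space <= n:
        rows = np.array(list(product(*[range(c) for c in cards])), dtype=int)
    else:
        draws = np.column_stack([rng.integers(0, c, size=2 * n) for c in cards])
        rows = np.unique(draws, axis=0)
        if len(rows) > n:
            sel = rng.choice(len(rows), size=n, replace=False)
            rows = rows[np.sort(sel)]
    frame = pd.DataFrame(rows, columns=inputs)
    probs = np.empty(len(frame))
    for i in range(len(frame)):
        ev = {v: int(frame.iloc[i][v]) for v in inputs}
        probs[i] = infer(bn, ev)[1]
    return ScenarioSet(frame, probs, seed, bn.target)


def variable_contributions(scenario_set: ScenarioSet, cutoff: float = 0.5
                           ) -> pd.Series:
    """Mean-residual contribution score per input variable.

    Residuals are r_s = P_s - mean(P).  The maximizing side (P > cutoff)
    picks each variable's bloom-promoting category (its modal category
    among those scenarios); the variable's term is then the mean residual
    over *all* scenarios holding that category, so a variable whose
    categories are unrelated to the output averages residuals from both
    sides and contributes ~0.  The minimizing side (P < cutoff) is
    analogous, and the contribution is the sum of the two absolute terms.
    """
    probs = scenario_set.probabilities
    frame = scenario_set.scenarios
    resid = probs - probs.mean()
    hi = probs > cutoff
    lo = probs < cutoff
    if not hi.any() or not lo.any():
        warnings.warn("no scenarios on one side of the cutoff; that term "
                      "contributes 0", stacklevel=2)
    scores = {}
    for v in frame.columns:
        terms = []
        for mask in (hi, lo):
            if not mask.any():
                terms.append(0.0)
                continue
            modal = frame.loc[mask, v].mode().iloc[0]
            sel = (frame[v] == modal).to_numpy()
            terms.append(abs(float(resid[sel].mean())) if sel.any() else 0.0)
        scores[v] = terms[0] + terms[1]
    return pd.Series(scores).sort_values(ascending=False)


def mean_scenarios(scenario_set: ScenarioSet, cutoff: float = 0.5
                   ) -> tuple[pd.Series, pd.Series, int, int]:
    """Mean category profiles of the maximizing (P > cutoff) and
    minimizing (P < cutoff) scenario subsets.

    Returns (maximizing profile, minimizing profile, n_max, n_min);
    scenarios at exactly the cutoff belong to neither side.
    """
    probs = scenario_set.probabilities
    frame = scenario_set.scenarios
    hi = probs > cutoff
    lo = probs < cutoff
    prof_hi = frame[hi].mean() if hi.any() else pd.Series(dtype=float)
    prof_lo = frame[lo].mean() if lo.any() else pd.Series(dtype=float)
    return prof_hi, prof_lo, int(hi.sum()), int(lo.sum())
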