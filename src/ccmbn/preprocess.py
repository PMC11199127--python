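"""Data conditioning: outlier removal, resampling, normalization,
stationarity handling, and categorization for the Bayesian-network stage.

The canonical pipeline order is fixed: outliers -> resample -> min-max
normalize for the cross-mapping stages, while categorization reads the
resampled *raw* values (quantile codes are scale invariant, and the stored
cutoffs stay in physical units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import adfuller

from .series import MultivariateSeries

__all__ = [
    "remove_outliers",
    "resample",
    "normalize_minmax",
    "ensure_stationary",
    "CategorizationScheme",
    "DiscreteTable",
    "categorize",
]


def remove_outliers(series: MultivariateSeries, z_threshold: float = 3.0
                    ) -> MultivariateSeries:
    """Replace |z| >= threshold cells by interpolation between neighbours.

    z-scores use the population standard deviation; flagging is one-pass
    (scores are not recomputed after removal).  Boundary outliers take the
    nearest retained value.  Zero-variance columns pass through unchanged.
    """
    frame = series.frame.copy()
    for col in frame.columns:
        x = frame[col].to_numpy(dtype=float)
        sd = float(np.std(x))
        if sd == 0.0 or not np.isfinite(sd):
            continue
        z = (x - np.mean(x)) / sd
        bad = np.abs(z) >= z_threshold
        if bad.all():
            raise ValueError(f"column {col!r}: every value flagged as outlier")
        if bad.any():
            s = pd.Series(np.where(bad, np.nan, x), index=frame.index)
            s = s.interpolate(method="linear", limit_direction="both")
            frame[col] = s.to_numpy()
    return MultivariateSeries(frame, series.step_days)


def resample(series: MultivariateSeries, step_days: float = 5.0
             ) -> MultivariateSeries:
    """Linear interpolation onto a uniform grid (default 5-day step).

    Duplicate timestamps are averaged first; the grid spans the observed
    range only (no extrapolation).
    """
    t = series.time_days()
    vals = series.values
    order = np.argsort(t, kind="stable")
    t, vals = t[order], vals[order]
    # average duplicates
    uniq, inverse = np.unique(t, return_inverse=True)
    if len(uniq) < len(t):
        agg = np.zeros((len(uniq), vals.shape[1]))
        counts = np.bincount(inverse).astype(float)
        for j in range(vals.shape[1]):
            agg[:, j] = np.bincount(inverse, weights=vals[:, j]) / counts
        t, vals = uniq, agg
    if len(t) < 2:
        raise ValueError("resampling needs at least 2 distinct time points")
    grid = np.arange(t[0], t[-1] + 1e-9, step_days)
    out = np.column_stack([np.interp(grid, t, vals[:, j])
                           for j in range(vals.shape[1])])
    frame = pd.DataFrame(out, columns=series.variables, index=grid)
    frame.index.name = series.frame.index.name
    return MultivariateSeries(frame, step_days=float(step_days))


def normalize_minmax(series: MultivariateSeries) -> MultivariateSeries:
    """Map each column to [0, 1] by (x - min) / (max - min); constants to 0."""
    frame = series.frame.copy()
    for col in frame.columns:
        x = frame[col].to_numpy(dtype=float)
        lo, hi = np.min(x), np.max(x)
        frame[col] = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
    return MultivariateSeries(frame, series.step_days)


def ensure_stationary(segment: np.ndarray, alpha: float = 0.05
                      ) -> tuple[np.ndarray, bool]:
    """Difference a segment if the ADF test cannot reject a unit root.

    Returns ``(segment', differenced)``.  The ADF regression includes a
    constant with AIC lag selection.  Constant segments are treated as
    stationary and returned unchanged.
    """
    x = np.asarray(segment, dtype=float)
    if len(x) < 25:
        raise ValueError("segment too short for a stationarity decision (< 25)")
    if np.ptp(x) == 0.0:
        return x, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            pvalue = adfuller(x, regression="c", autolag="AIC")[1]
        except (ValueError, np.linalg.LinAlgError):
            return x, False
    if pvalue >= alpha:
        return np.diff(x), True
    return x, False


# ---------------------------------------------------------------------------
# categorization


@dataclass
class CategorizationScheme:
    """How to discretize variables for the Bayesian network.

    Predictors get 3 codes {0,1,2}; by default the cutoffs are the tertiles
    of each variable.  The target gets 2 codes {0,1}, split at its
    ``target_quantile`` (high = value >= quantile, closed upper interval).
    Explicit per-variable cutoffs override the quantile rule.
    """

    target: str
    target_quantile: float = 0.75
    predictor_quantiles: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    cutoffs: dict = field(default_factory=dict)


@dataclass
class DiscreteTable:
    """Categorized data plus the cutoffs that produced it."""

    frame: pd.DataFrame          # integer codes
    cutoffs: dict                # variable -> list of thresholds
    target: str
    cardinalities: dict = field(default_factory=dict)

    def state_counts(self) -> pd.DataFrame:
        """Per variable x state counts (for the >20-cases support check)."""
        rows = {}
        for col in self.frame.columns:
            card = self.cardinalities.get(col, int(self.frame[col].max()) + 1)
            counts = self.frame[col].value_counts()
            rows[col] = {s: int(counts.get(s, 0)) for s in range(card)}
        return pd.DataFrame(rows).T.fillna(0).astype(int)


def _codes(x: np.ndarray, cuts: list[float]) -> np.ndarray:
    """Left-closed, right-open intervals; the last interval is closed."""
    return np.searchsorted(np.asarray(cuts, dtype=float), x, side="right")


def categorize(series: MultivariateSeries, scheme: CategorizationScheme
               ) -> DiscreteTable:
    """Code predictors 0/1/2 and the target 0/1.

    The target is coded 1 where its value is >= the ``target_quantile``
    threshold.  Cutoffs are stored so the same coding can be replayed on
    held-out data via :func:`apply_cutoffs`.
    """
    if scheme.target not in series.variables:
        raise KeyError(f"target {scheme.target!r} not in series")
    cutoffs: dict[str, list[float]] = {}
    cards: dict[str, int] = {}
    coded = {}
    for col in series.variables:
        x = series.column(col)
        if col in scheme.cutoffs:
            cuts = list(scheme.cutoffs[col])
        elif col == scheme.target:
            cuts = [float(np.quantile(x, scheme.target_quantile))]
        else:
            cuts = [float(np.quantile(x, q)) for q in scheme.predictor_quantiles]
        if col == scheme.target:
            codes = (x >= cuts[0]).astype(int)
        else:
            codes = _codes(x, cuts)
            # boundary convention: interior intervals right-open, but values
            # at a cutoff belong to the upper category (searchsorted 'right'
            # gives left-closed intervals already)
        cutoffs[col] = cuts
        cards[col] = 2 if col == scheme.target else len(cuts) + 1
        counts = np.bincount(codes, minlength=cards[col])
        if (counts == 0).any():
            warnings.warn(f"variable {col!r}: empty category under the given "
                          f"cutoffs {cuts}", stacklevel=2)
        coded[col] = codes
    frame = pd.DataFrame(coded, index=series.frame.index)
    return DiscreteTable(frame, cutoffs, scheme.target, cards)


def apply_cutoffs(series: MultivariateSeries, table: DiscreteTable
                  ) -> DiscreteTable:
    """Re-code new data with a fitted table's stored cutoffs."""
    coded = {}
    for col in series.variables:
        cuts = table.cutoffs[col]
        x = series.column(col)
        if col == table.target:
            coded[col] = (x >= cuts[0]).astype(int)
        else:
            coded[col] = _codes(x, cuts)
    frame = pd.DataFrame(coded, index=series.frame.index)
    return DiscreteTable(frame, dict(table.cutoffs), table.target,
                         dict(table.cardinalities))
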