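"""Multivariate time-series container used throughout the package.

A :class:`MultivariateSeries` is a thin wrapper around a pandas DataFrame
whose index is time in days (float) or a DatetimeIndex.  After resampling
the grid is uniform with a known step (``step_days``); most analysis
routines require that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MultivariateSeries", "read_series", "write_series"]


@dataclass
class MultivariateSeries:
    """Regularly- or irregularly-sampled multivariate series.

    Parameters
    ----------
    frame
        Rows are time points, columns are variables.  The index holds time
        in days (numeric) or timestamps.
    step_days
        Grid step in days if the series is on a uniform grid, else None.
    """

    frame: pd.DataFrame
    step_days: float | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.frame, pd.DataFrame):
            raise TypeError("frame must be a pandas DataFrame")
        if self.frame.shape[1] == 0:
            raise ValueError("series needs at least one variable column")

    # -- basic protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def variables(self) -> list[str]:
        return [str(c) for c in self.frame.columns]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(dtype=float)

    def time_days(self) -> np.ndarray:
        """Time axis in float days (datetimes are converted)."""
        idx = self.frame.index
        if isinstance(idx, pd.DatetimeIndex):
            t0 = idx[0]
            return (idx - t0).total_seconds().to_numpy() / 86400.0
        return np.asarray(idx, dtype=float)

    def is_uniform(self, rtol: float = 1e-9) -> bool:
        t = self.time_days()
        if len(t) < 3:
            return True
        d = np.diff(t)
        return bool(np.allclose(d, d[0], rtol=rtol, atol=1e-9))

    def copy(self) -> "MultivariateSeries":
        return MultivariateSeries(self.frame.copy(), self.step_days)


def read_series(path) -> MultivariateSeries:
    """Read a CSV with a leading time column (ISO date or numeric step).

    Raises ``ValueError`` with the offending line number on malformed rows.
    """
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus at least one variable")
    time_col = frame.columns[0]
    raw = frame[time_col]
    try:
        idx = pd.to_numeric(raw)
    except (ValueError, TypeError):
        idx = pd.to_datetime(raw, format="mixed")
    data = frame.drop(columns=[time_col])
    bad = data.apply(lambda c: pd.to_numeric(c, errors="coerce")).isna() & data.notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy().any(axis=1))[0][0])
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: malformed value on line {row + 2}")
    data = data.astype(float)
    data.index = pd.Index(idx, name=time_col)
    out = MultivariateSeries(data)
    t = out.time_days()
    if len(t) >= 3:
        d = np.diff(t)
        if np.allclose(d, d[0], rtol=1e-9, atol=1e-9):
            out.step_days = float(d[0])
    return out


def write_series(series: MultivariateSeries, path) -> None:
    """Write CSV: header row, first column the time index, float columns."""
    frame = series.frame.copy()
    frame.index.name = frame.index.name or "t"
    frame.to_csv(path, float_format="%.12g")
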