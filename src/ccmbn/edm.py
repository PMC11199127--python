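"""Empirical dynamic modeling primitives.

State-space reconstruction by time-delay embedding, simplex (nearest
neighbour) projection, embedding-parameter selection, and the S-map
locality test for nonlinearity.  Distances are Euclidean throughout, and a
point never serves as its own neighbour (exact time matches are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "EmbeddingParams",
    "ForecastResult",
    "delay_embed",
    "knn_simplex_weights",
    "simplex_predict",
    "simplex_forecast",
    "select_embedding_dimension",
    "select_lag",
    "smap_nonlinearity",
    "pearson_skill",
]

DEFAULT_E = 5
DEFAULT_LAG = 2
MAX_PARAM = 20


@dataclass(frozen=True)
class EmbeddingParams:
    """Time-delay embedding parameters: dimension E and lag step l."""

    E: int = DEFAULT_E
    l: int = DEFAULT_LAG

    def __post_init__(self) -> None:
        if self.E < 1 or self.l < 1:
            raise ValueError("E and l must be positive integers")


@dataclass
class ForecastResult:
    predictions: np.ndarray
    observed: np.ndarray
    skill: float


def pearson_skill(pred: np.ndarray, obs: np.ndarray) -> float:
    """Pearson correlation as prediction skill; 0 for degenerate inputs."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if len(pred) < 2 or np.std(pred) == 0.0 or np.std(obs) == 0.0:
        return 0.0
    r = float(np.corrcoef(pred, obs)[0, 1])
    return r if np.isfinite(r) else 0.0


def delay_embed(x: np.ndarray, params: EmbeddingParams
                ) -> tuple[np.ndarray, np.ndarray]:
    """Embed a scalar series into E-dimensional lagged-coordinate vectors.

    The vector at time t is (x_t, x_{t-l}, ..., x_{t-(E-1)l}).  Returns
    ``(vectors, times)`` where ``times`` are the indices t into ``x``;
    there are ``len(x) - (E-1)*l`` vectors.
    """
    x = np.asarray(x, dtype=float)
    E, l = params.E, params.l
    start = (E - 1) * l
    if len(x) <= start:
        raise ValueError(
            f"series of length {len(x)} too short for E={E}, l={l}")
    times = np.arange(start, len(x))
    cols = [x[start - j * l: len(x) - j * l] for j in range(E)]
    return np.column_stack(cols), times


def knn_simplex_weights(dist: np.ndarray, k: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Simplex neighbour indices and weights for a query x library distance
    matrix.

    Per query row the k nearest library points get weights exp(-d_i/d_1)
    (d_1 = nearest distance).  A zero d_1 switches the row to equal
    weights on its zero-distance neighbours only; all-equal distances
    degenerate to uniform.  Infinite distances (excluded points) get zero
    weight.  Returns ``(idx, w)`` of shape (n_queries, k), w row-normalized.
    """
    k = min(k, dist.shape[1])
    idx = np.argpartition(dist, k - 1, axis=1)[:, :k]
    dn = np.take_along_axis(dist, idx, axis=1)
    order = np.argsort(dn, axis=1, kind="stable")
    idx = np.take_along_axis(idx, order, axis=1)
    dn = np.take_along_axis(dn, order, axis=1)
    d1 = dn[:, :1]
    if not np.all(np.isfinite(d1)):
        raise ValueError("a query point has no finite-distance neighbour")
    with np.errstate(invalid="ignore"):
        w = np.where(d1 > 0, np.exp(-dn / np.where(d1 > 0, d1, 1.0)),
                     (dn == 0).astype(float))
    w[~np.isfinite(dn)] = 0.0
    return idx, w / w.sum(axis=1, keepdims=True)


def simplex_predict(
    lib_vectors: np.ndarray,
    lib_values: np.ndarray,
    query_vectors: np.ndarray,
    n_neighbors: int | None = None,
    lib_times: np.ndarray | None = None,
    query_times: np.ndarray | None = None,
    dist: np.ndarray | None = None,
) -> np.ndarray:
    """Simplex projection: weighted nearest-neighbour prediction.

    ``lib_values[i]`` is the quantity co-registered with library vector i
    (its own future for forecasting, the concurrent value of another
    variable for cross mapping).  If both time arrays are given, library
    points sharing a query's time stamp are excluded (leave-one-out).
    ``dist`` lets callers reuse a precomputed distance matrix.
    """
    lib_vectors = np.atleast_2d(lib_vectors)
    query_vectors = np.atleast_2d(query_vectors)
    k = n_neighbors or (lib_vectors.shape[1] + 1)
    if dist is None:
        dist = cdist(query_vectors, lib_vectors)
    else:
        dist = dist.copy()
    if lib_times is not None and query_times is not None:
        same = np.asarray(query_times)[:, None] == np.asarray(lib_times)[None, :]
        dist[same] = np.inf
    idx, w = knn_simplex_weights(dist, k)
    lib_values = np.asarray(lib_values, float)
    return (w * lib_values[idx]).sum(axis=1)


def simplex_forecast(x: np.ndarray, params: EmbeddingParams,
                     horizon: int = 1) -> ForecastResult:
    """Leave-one-out simplex self-forecast of a scalar series.

    Every embedded point is predicted ``horizon`` steps ahead from its E+1
    nearest neighbours among the other points.  Skill is the Pearson
    correlation between predictions and observations.
    """
    x = np.asarray(x, dtype=float)
    vectors, times = delay_embed(x, params)
    keep = times + horizon < len(x)
    vec, t = vectors[keep], times[keep]
    futures = x[t + horizon]
    if len(vec) < params.E + 2:
        raise ValueError("series too short for leave-one-out forecasting")
    preds = simplex_predict(vec, futures, vec, lib_times=t, query_times=t)
    return ForecastResult(preds, futures, pearson_skill(preds, futures))


def select_embedding_dimension(x: np.ndarray, E_range=None, l: int = 1,
                               horizon: int = 1,
                               max_span: int | None = None) -> int:
    """E* maximizing leave-one-out simplex skill; ties go to smaller E.

    The candidate range is truncated to what the series length supports
    (and, when ``max_span`` is given, to embeddings spanning at most that
    many samples, so windowed analyses keep enough state vectors per
    window); a selection above 20 falls back to the default E=5.
    """
    x = np.asarray(x, dtype=float)
    candidates = list(E_range) if E_range is not None else list(range(1, MAX_PARAM + 1))
    best_E, best_skill = None, -np.inf
    for E in candidates:
        if (E - 1) * l + horizon + E + 2 > len(x):
            continue
        if max_span is not None and (E - 1) * l > max_span:
            continue
        try:
            res = simplex_forecast(x, EmbeddingParams(E, l), horizon)
        except ValueError:
            continue
        if res.skill > best_skill + 1e-12:
            best_E, best_skill = E, res.skill
    if best_E is None or best_E > MAX_PARAM:
        return DEFAULT_E
    return best_E


def _mutual_information(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    """Plug-in MI from a 2-D histogram (nats)."""
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))


def mutual_information_profile(x: np.ndarray, max_lag: int = MAX_PARAM
                               ) -> np.ndarray:
    """MI between the series and its lag-shifted copy, lags 0..max_lag+1."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    bins = max(int(np.ceil(np.sqrt(n / 5.0))), 2)
    out = []
    for lag in range(0, max_lag + 2):
        if n - lag < 10:
            break
        a = x[lag:] if lag else x
        b = x[: n - lag] if lag else x
        out.append(_mutual_information(a, b, bins))
    return np.asarray(out)


def select_lag(x: np.ndarray, max_lag: int = MAX_PARAM) -> int:
    """First minimum of the lagged self mutual information.

    l* is the smallest lag with MI(l) < MI(l-1) and MI(l) < MI(l+1)
    (MI(0) is the self-information).  Without an interior minimum within
    ``max_lag`` the default l=2 is returned.
    """
    mi = mutual_information_profile(x, max_lag)
    for lag in range(1, min(max_lag, len(mi) - 1) + 1):
        if lag + 1 >= len(mi):
            break
        if mi[lag] < mi[lag - 1] and mi[lag] < mi[lag + 1]:
            return lag if lag <= MAX_PARAM else DEFAULT_LAG
    return DEFAULT_LAG


def select_embedding(x: np.ndarray, max_lag: int = MAX_PARAM,
                     max_span: int | None = None) -> EmbeddingParams:
    """Joint embedding-parameter selection for cross-mapping.

    The mutual-information first minimum proposes the lag, and the
    proposal is capped at the series' decorrelation time — the first lag
    where the autocorrelation drops below 1/e.  The lag exists to
    decorrelate embedding coordinates: strongly chaotic series decorrelate
    within a step (their MI profile decays to the estimator floor with no
    real interior minimum, so the MI rule alone overshoots), while smooth
    seasonal series keep their MI lag.  E then maximizes leave-one-out
    simplex forecast skill at that lag.  With ``max_span`` the search is
    restricted to embeddings spanning at most that many samples (so
    windowed analyses keep enough vectors per window).
    """
    x = np.asarray(x, dtype=float)
    l = min(select_lag(x, max_lag), _decorrelation_lag(x, max_lag))
    if max_span is not None and l > max_span:
        l = DEFAULT_LAG
    E = select_embedding_dimension(x, l=l, max_span=max_span)
    return EmbeddingParams(E, l)


def _decorrelation_lag(x: np.ndarray, max_lag: int = MAX_PARAM) -> int:
    """First lag where the autocorrelation falls below 1/e."""
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return 1
    for lag in range(1, min(max_lag, len(x) - 2) + 1):
        r = float(np.dot(x[lag:], x[:-lag])) / denom
        if r < np.exp(-1.0):
            return lag
    return max_lag


DEFAULT_THETA_GRID = (0.0, 0.1, 0.3, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0)


def smap_nonlinearity(x: np.ndarray, theta_grid=DEFAULT_THETA_GRID,
                      E: int = 2, l: int = 1, nl_margin: float = 0.01
                      ) -> tuple[np.ndarray, bool]:
    """S-map locality sweep: skill per theta and a nonlinearity flag.

    For each theta, every embedded point is forecast one step ahead by a
    locally weighted linear regression over all other points, weights
    exp(-theta * d / d_mean).  theta=0 reduces to a global linear model.
    The flag is raised when some theta > 0 beats theta=0 by more than
    ``nl_margin`` — localized (state-dependent) dynamics.
    """
    x = np.asarray(x, dtype=float)
    params = EmbeddingParams(E, l)
    vectors, times = delay_embed(x, params)
    keep = times + 1 < len(x)
    vec, t = vectors[keep], times[keep]
    futures = x[t + 1]
    n = len(vec)
    if n < E + 3:
        raise ValueError("series too short for the S-map test")
    dist = cdist(vec, vec)
    np.fill_diagonal(dist, np.inf)
    theta_grid = np.asarray(theta_grid, dtype=float)
    skills = np.empty(len(theta_grid))
    A_full = np.column_stack([np.ones(n), vec])
    ridge = 1e-8 * np.eye(E + 1)
    for k, theta in enumerate(theta_grid):
        preds = np.empty(n)
        for i in range(n):
            d = dist[i]
            finite = np.isfinite(d)
            dbar = np.mean(d[finite])
            w = np.ones(n) if (theta == 0 or dbar == 0) else np.exp(-theta * d / dbar)
            w[~finite] = 0.0
            Aw = A_full * w[:, None]
            lhs = A_full.T @ Aw + ridge
            rhs = Aw.T @ futures
            beta = np.linalg.solve(lhs, rhs)
            preds[i] = np.dot(np.concatenate(([1.0], vec[i])), beta)
        skills[k] = pearson_skill(preds, futures)
    base = skills[theta_grid == 0.0][0] if np.any(theta_grid == 0.0) else skills[0]
    nonlinear = bool(np.max(skills[theta_grid > 0], initial=-np.inf) > base + nl_margin)
    return skills, nonlinear
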