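"""Convergent cross mapping.

To test "X causes Y" the *effect's* reconstructed manifold is used to
predict the cause: if X drives Y, the history of Y encodes X.  Skill that
grows with library size (convergence) is the causal signature.  The module
also implements the sliding-window protocol (100-sample windows, 10-sample
gap, per-window stationarity handling) and phase-randomized (Ebisuzaki)
surrogate significance testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import kendalltau

from .edm import EmbeddingParams, delay_embed, knn_simplex_weights, pearson_skill
from .preprocess import ensure_stationary

__all__ = [
    "CrossMapCurve",
    "WindowedCCM",
    "cross_map",
    "convergence_test",
    "sliding_window_ccm",
    "ebisuzaki_surrogate",
    "surrogate_significance",
]


@dataclass
class CrossMapCurve:
    """Cross-map skill as a function of library size.

    ``n_test`` is the number of held-out points behind each skill value;
    when present, the convergence test additionally requires the final
    skill to clear its one-sided sampling noise.
    """

    library_sizes: np.ndarray
    skill: np.ndarray
    converged: bool
    final_skill: float
    n_test: int | None = None


@dataclass
class WindowedCCM:
    """Per-window cross-map curves plus the converged-window aggregate."""

    window_starts: list
    curves: list
    n_converged: int
    mean_skill: float | None  # mean final skill over converged windows


def _library_schedule(pool: int, E: int, n_sizes: int = 15) -> np.ndarray:
    """Log-spaced library sizes from E+2 up to the pool maximum."""
    lo = E + 2
    if pool < lo:
        raise ValueError(f"library pool ({pool}) smaller than E+2 ({lo})")
    sizes = np.unique(np.round(np.geomspace(lo, pool, n_sizes)).astype(int))
    return sizes


def cross_map(
    cause: np.ndarray,
    effect: np.ndarray,
    params: EmbeddingParams,
    library_sizes: np.ndarray | None = None,
    split: float = 0.75,
    rng: np.random.Generator | None = None,
    loo: bool = False,
    n_draws: int = 8,
    subsample: str = "random",
) -> CrossMapCurve:
    """Cross-map skill curve for "cause -> effect".

    The effect series is embedded and its state vectors predict the
    cause's concurrent values by simplex weights; skill per library size L
    is the Pearson correlation.  Two prediction protocols:

    * chronological (default, used inside sliding windows): the first
      ``split`` of the vectors is the library pool and the held-out tail
      is predicted;
    * ``loo=True`` (whole-frame runs): the library lives in the entire
      frame and every point is predicted leave-one-out, the convention of
      single-frame CCM analyses.

    At each size L the library is a random draw of L pool points and the
    skill is averaged over ``n_draws`` draws (seeded; pass ``rng`` to
    control it), which keeps the skill-vs-L curve smooth enough for the
    convergence test.  ``subsample="head"`` uses the first L pool points
    deterministically instead.
    """
    cause = np.asarray(cause, float)
    effect = np.asarray(effect, float)
    if len(cause) != len(effect):
        raise ValueError("cause and effect must have equal length")
    vectors, times = delay_embed(effect, params)
    m = len(vectors)
    if loo:
        pool_vec, pool_t = vectors, times
        test_vec, test_t = vectors, times
    else:
        n_pool = int(np.floor(split * m))
        pool_vec, pool_t = vectors[:n_pool], times[:n_pool]
        test_vec, test_t = vectors[n_pool:], times[n_pool:]
    pool_val = cause[pool_t]
    observed = cause[test_t]
    n_pool = len(pool_vec)
    if len(test_vec) < 3:
        raise ValueError("held-out partition too small for skill estimation")
    if library_sizes is None:
        sizes = _library_schedule(n_pool - (1 if loo else 0), params.E)
    else:
        sizes = np.asarray(library_sizes, int)
        valid = (sizes >= params.E + 2) & (sizes <= n_pool)
        if not valid.all():
            warnings.warn("library sizes outside [E+2, pool] dropped",
                          stacklevel=2)
            sizes = sizes[valid]
        if len(sizes) == 0:
            raise ValueError("no admissible library sizes")
    k = params.E + 1
    dist = cdist(test_vec, pool_vec)
    if loo:
        dist[test_t[:, None] == pool_t[None, :]] = np.inf
    if subsample == "random" and rng is None:
        rng = np.random.default_rng(0)
    n_test = len(test_vec)
    skills = np.empty(len(sizes))
    for j, L in enumerate(sizes):
        if subsample != "random" or L >= n_pool:
            idx, w = knn_simplex_weights(dist[:, :L], k)
            preds = (w * pool_val[:L][idx]).sum(axis=1)
            skills[j] = pearson_skill(preds, observed)
            continue
        # all draws at once: (draws*test, L) distance block, one kNN pass
        sel = np.stack([rng.choice(n_pool, size=L, replace=False)
                        for _ in range(n_draws)])
        sub = dist[:, sel].transpose(1, 0, 2).reshape(n_draws * n_test, L)
        idx, w = knn_simplex_weights(sub, min(k, L))
        vals = np.repeat(pool_val[sel], n_test, axis=0)
        preds = (w * np.take_along_axis(vals, idx, axis=1)).sum(axis=1)
        preds = preds.reshape(n_draws, n_test)
        pc = preds - preds.mean(axis=1, keepdims=True)
        oc = observed - observed.mean()
        denom = np.sqrt((pc ** 2).sum(axis=1) * (oc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (pc * oc[None, :]).sum(axis=1) / denom, 0.0)
        skills[j] = float(np.mean(r))
    curve = CrossMapCurve(sizes, skills, False, float(skills[-1]), n_test)
    curve.converged = convergence_test(curve)
    return curve


def convergence_test(curve: CrossMapCurve, min_gain: float = 0.05,
                     alpha: float = 0.05) -> bool:
    """Converged iff skill gained >= ``min_gain`` from the smallest to the
    largest library, the (L, skill) trend is positive by a one-sided
    Kendall-tau test at level ``alpha``, and — when the curve records its
    held-out sample size — the final skill is significantly positive
    (one-sided Fisher z at the same level), so a curve drifting inside the
    noise band of the correlation estimate does not count as converged."""
    if len(curve.library_sizes) < 3:
        return False
    gain = curve.skill[-1] - curve.skill[0]
    if gain < min_gain:
        return False
    with np.errstate(invalid="ignore"):
        tau, p_two = kendalltau(curve.library_sizes, curve.skill)
    if not np.isfinite(tau) or tau <= 0:
        return False
    if (p_two / 2.0) >= alpha:
        return False
    if curve.n_test is not None and curve.n_test > 3:
        z_crit = 1.6448536269514722  # one-sided 5%
        if np.arctanh(np.clip(curve.final_skill, -0.999999, 0.999999)) \
                * np.sqrt(curve.n_test - 3) < z_crit:
            return False
    return True


def sliding_window_ccm(
    cause: np.ndarray,
    effect: np.ndarray,
    params: EmbeddingParams,
    window: int = 100,
    gap: int = 10,
    split: float = 0.75,
    stationarity: bool = True,
    diff_flags: tuple | None = None,
) -> WindowedCCM:
    """Cross map over length-``window`` windows advanced by ``gap`` samples.

    Each window is differenced first when the ADF test flags a unit root
    (both series are differenced together so their alignment is kept).
    ``diff_flags`` can supply precomputed per-window (cause, effect) flag
    sequences to avoid repeating the ADF tests across pairs.
    The aggregate skill is the mean final skill of converged windows only.
    """
    cause = np.asarray(cause, float)
    effect = np.asarray(effect, float)
    n = len(cause)
    if n < window:
        raise ValueError(f"series length {n} shorter than window {window}")
    starts, curves = [], []
    for w_i, s in enumerate(range(0, n - window + 1, gap)):
        c_seg = cause[s: s + window]
        e_seg = effect[s: s + window]
        if diff_flags is not None:
            if diff_flags[0][w_i] or diff_flags[1][w_i]:
                c_seg = np.diff(c_seg)
                e_seg = np.diff(e_seg)
        elif stationarity:
            _, c_diff = ensure_stationary(c_seg)
            _, e_diff = ensure_stationary(e_seg)
            if c_diff or e_diff:
                # difference both so cause/effect rows stay aligned
                c_seg = np.diff(c_seg)
                e_seg = np.diff(e_seg)
        try:
            curve = cross_map(c_seg, e_seg, params, split=split)
        except ValueError:
            continue
        starts.append(s)
        curves.append(curve)
    conv = [c for c in curves if c.converged]
    mean_skill = float(np.mean([c.final_skill for c in conv])) if conv else None
    return WindowedCCM(starts, curves, len(conv), mean_skill)


def window_diff_flags(x: np.ndarray, window: int = 100, gap: int = 10
                      ) -> tuple:
    """Per-window ADF differencing decisions for one series (cacheable)."""
    x = np.asarray(x, float)
    return tuple(ensure_stationary(x[s: s + window])[1]
                 for s in range(0, len(x) - window + 1, gap))


def ebisuzaki_surrogate(x: np.ndarray, rng: np.random.Generator
                        ) -> np.ndarray:
    """Phase-randomized surrogate preserving the periodogram.

    The DC component is kept (mean preserved), interior frequencies get
    uniform random phases, and the Nyquist bin (even length) keeps its
    magnitude with a random sign, so the output is real with the same
    power spectrum as ``x``.
    """
    x = np.asarray(x, float)
    n = len(x)
    spec = np.fft.rfft(x)
    mag = np.abs(spec)
    phases = rng.uniform(0.0, 2.0 * np.pi, len(spec))
    new = mag * np.exp(1j * phases)
    new[0] = spec[0]
    if n % 2 == 0:
        new[-1] = mag[-1] * (1.0 if rng.random() < 0.5 else -1.0)
    return np.fft.irfft(new, n=n)


def surrogate_significance(
    cause: np.ndarray,
    effect: np.ndarray,
    params: EmbeddingParams,
    n_surrogates: int = 1000,
    quantile: float = 0.9,
    seed: int = 0,
    frame: int = 400,
    split: float = 0.75,
) -> tuple[float, float, bool]:
    """Surrogate test of a cross-map skill on a fixed-length frame.

    The observed skill is the full-library cross-map skill on the last
    ``frame`` points.  Surrogates replace the *cause* series by
    phase-randomized copies; since the effect manifold (and hence the
    neighbour geometry) is unchanged, each surrogate only re-weights the
    predicted values, which keeps 1000 surrogates cheap.  Returns
    (observed skill, surrogate quantile, significant), with significance
    the strict ``observed > quantile`` comparison; the observed value is
    not pooled with the surrogates.
    """
    if n_surrogates < 100:
        warnings.warn(f"n_surrogates={n_surrogates} < 100: calibration of "
                      "the quantile will be coarse", stacklevel=2)
    cause = np.asarray(cause, float)[-frame:]
    effect = np.asarray(effect, float)[-frame:]
    vectors, times = delay_embed(effect, params)
    m = len(vectors)
    n_pool = int(np.floor(split * m))
    if n_pool < params.E + 2:
        raise ValueError("frame too short for the surrogate test")
    pool_vec, test_vec = vectors[:n_pool], vectors[n_pool:]
    pool_t, test_t = times[:n_pool], times[n_pool:]
    dist = cdist(test_vec, pool_vec)
    idx, w = knn_simplex_weights(dist, params.E + 1)
    preds = (w * cause[pool_t][idx]).sum(axis=1)
    observed = pearson_skill(preds, cause[test_t])

    rng = np.random.default_rng(seed)
    # all surrogates at once: rows are surrogate series
    surr = np.stack([ebisuzaki_surrogate(cause, rng) for _ in range(n_surrogates)])
    lib_vals = surr[:, pool_t]                      # (S, n_pool)
    sp = np.einsum("tk,stk->st", w, lib_vals[:, idx])
    obs_vals = surr[:, test_t]
    sp_c = sp - sp.mean(axis=1, keepdims=True)
    ob_c = obs_vals - obs_vals.mean(axis=1, keepdims=True)
    denom = np.sqrt((sp_c ** 2).sum(axis=1) * (ob_c ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        skills = np.where(denom > 0, (sp_c * ob_c).sum(axis=1) / denom, 0.0)
    qval = float(np.quantile(skills, quantile))
    return observed, qval, bool(observed > qval)
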