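"""Extended CCM: lagged cross-map scans and interaction classification.

Cross-map skill is computed over a grid of time shifts between the pair.
A genuine cause must precede (or be simultaneous with) its effect, so the
effect's manifold can only predict present or *past* values of the cause:
the optimal-skill lag of a true interaction is non-positive.  The joint
pattern of optimal lags in both directions separates unidirectional and
bidirectional causation from synchrony (a strong common driver, or one
variable enslaving the other) and from false interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .edm import EmbeddingParams, delay_embed, knn_simplex_weights, pearson_skill

__all__ = ["ECCMProfile", "eccm_scan", "classify_interaction", "lag_to_days"]

CLASSES = (
    "unidirectional_xy",
    "unidirectional_yx",
    "bidirectional",
    "synchrony_common_force",
    "synchrony_enslaved_xy",
    "synchrony_enslaved_yx",
    "false_interaction",
)


@dataclass
class ECCMProfile:
    """Skill-vs-shift curves for both directions plus the classification.

    ``opt_lag_xy`` is the global argmax of the "X causes Y" curve (ties
    toward 0) and drives classification; ``causal_lag_xy`` is the best
    non-positive lag (the paper-style highest peak at lag <= 0) and is the
    lag carried onto network edges.
    """

    shifts: np.ndarray
    skill_xy: np.ndarray
    skill_yx: np.ndarray
    opt_lag_xy: int
    opt_lag_yx: int
    causal_lag_xy: int
    causal_lag_yx: int
    classification: str = ""

    def peak_skill(self, direction: str) -> float:
        s = self.skill_xy if direction == "xy" else self.skill_yx
        lag = self.opt_lag_xy if direction == "xy" else self.opt_lag_yx
        return float(s[np.where(self.shifts == lag)[0][0]])


def _argmax_toward_zero(shifts: np.ndarray, skill: np.ndarray) -> int:
    """Lag of maximum skill; ties broken toward |lag| = 0."""
    best = np.max(skill)
    tied = shifts[skill >= best - 1e-12]
    return int(tied[np.argmin(np.abs(tied))])


def _best_nonpositive(shifts: np.ndarray, skill: np.ndarray) -> int:
    neg = shifts <= 0
    sub_s, sub_k = shifts[neg], skill[neg]
    best = np.max(sub_k)
    tied = sub_s[sub_k >= best - 1e-12]
    return int(tied[np.argmin(np.abs(tied))])


def _lagged_crossmap_skill(cause: np.ndarray, effect: np.ndarray,
                           shift: int, params: EmbeddingParams,
                           max_library: int) -> float:
    """Cross-map skill for effect-manifold -> cause at one time shift.

    ``shift`` aligns cause(t + shift) with effect(t); a negative shift
    asks the effect to predict past cause values.  The library is the
    chronological first ``max_library`` embedded points; skill is
    leave-one-out over all points (library included), matching a fixed
    maximum-library ECCM scan.
    """
    n = len(cause)
    if shift >= 0:
        c = cause[shift:]
        e = effect[: n - shift]
    else:
        c = cause[: n + shift]
        e = effect[-shift:]
    vectors, times = delay_embed(e, params)
    lib = min(max_library, len(vectors))
    lib_vec, lib_t = vectors[:lib], times[:lib]
    dist = cdist(vectors, lib_vec)
    # exclude exact self-matches (leave-one-out inside the library span)
    same = times[:, None] == lib_t[None, :]
    dist[same] = np.inf
    idx, w = knn_simplex_weights(dist, params.E + 1)
    lib_vals = c[lib_t]
    preds = (w * lib_vals[idx]).sum(axis=1)
    return pearson_skill(preds, c[times])


def eccm_scan(
    x: np.ndarray,
    y: np.ndarray,
    params: EmbeddingParams = EmbeddingParams(5, 2),
    frame: int = 400,
    max_library: int = 200,
    max_shift: int = 20,
    sync_tol: float = 0.05,
    skill_min: float = 0.01,
) -> ECCMProfile:
    """Scan cross-map skill over shifts -max_shift..max_shift for both
    directions and classify the interaction.

    The most recent ``frame`` points of the aligned pair are used (after
    reserving ``max_shift`` samples so every shift sees the same frame
    length).  Series shorter than frame + max_shift shrink the frame with
    a warning, down to a floor of 100 points.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("series must be aligned and of equal length")
    n = len(x)
    use_frame = frame
    if n < frame + max_shift:
        use_frame = max(n - max_shift, 100)
        if use_frame < 100 + 0:
            raise ValueError("series too short for an ECCM scan")
        warnings.warn(f"frame shrunk to {use_frame} (series length {n})",
                      stacklevel=2)
    x = x[-(use_frame + max_shift):]
    y = y[-(use_frame + max_shift):]
    shifts = np.arange(-max_shift, max_shift + 1)
    skill_xy = np.empty(len(shifts))
    skill_yx = np.empty(len(shifts))
    for i, s in enumerate(shifts):
        # "X causes Y": y's manifold predicts x shifted by s
        skill_xy[i] = _lagged_crossmap_skill(x, y, int(s), params, max_library)
        skill_yx[i] = _lagged_crossmap_skill(y, x, int(s), params, max_library)
    profile = ECCMProfile(
        shifts=shifts,
        skill_xy=skill_xy,
        skill_yx=skill_yx,
        opt_lag_xy=_argmax_toward_zero(shifts, skill_xy),
        opt_lag_yx=_argmax_toward_zero(shifts, skill_yx),
        causal_lag_xy=_best_nonpositive(shifts, skill_xy),
        causal_lag_yx=_best_nonpositive(shifts, skill_yx),
    )
    profile.classification = classify_interaction(profile, sync_tol, skill_min)
    return profile


def classify_interaction(profile: ECCMProfile, sync_tol: float = 0.05,
                         skill_min: float = 0.01) -> str:
    """Total classification of an ECCM profile.

    Rules (optimal lag = global argmax, ties toward 0; a direction is
    "supported" when its peak skill >= ``skill_min``):

    * neither direction supported                       -> false_interaction
    * both lags 0, peak skills within ``sync_tol``      -> synchrony_common_force
    * both lags 0, dissimilar skills                    -> unidirectional toward
      the stronger direction (a driver plus its echo)
    * lag_xy < 0 and lag_yx > 0                         -> synchrony_enslaved_xy
      (X enslaves Y); mirrored for yx
    * both lags <= 0 (at least one < 0), both supported -> bidirectional
    * exactly one supported direction with lag <= 0     -> unidirectional
    * anything else (best lags strictly positive)       -> false_interaction
    """
    lag_xy, lag_yx = profile.opt_lag_xy, profile.opt_lag_yx
    p_xy, p_yx = profile.peak_skill("xy"), profile.peak_skill("yx")
    ok_xy = p_xy >= skill_min
    ok_yx = p_yx >= skill_min
    if not ok_xy and not ok_yx:
        return "false_interaction"
    if ok_xy and ok_yx:
        if lag_xy == 0 and lag_yx == 0:
            if abs(p_xy - p_yx) < sync_tol:
                return "synchrony_common_force"
            return "unidirectional_xy" if p_xy > p_yx else "unidirectional_yx"
        if lag_xy < 0 and lag_yx > 0:
            return "synchrony_enslaved_xy"
        if lag_yx < 0 and lag_xy > 0:
            return "synchrony_enslaved_yx"
        if lag_xy <= 0 and lag_yx <= 0:
            return "bidirectional"
        if lag_xy == 0 and lag_yx > 0:
            return "unidirectional_xy"
        if lag_yx == 0 and lag_xy > 0:
            return "unidirectional_yx"
        return "false_interaction"
    if ok_xy:
        return "unidirectional_xy" if lag_xy <= 0 else "false_interaction"
    return "unidirectional_yx" if lag_yx <= 0 else "false_interaction"


def lag_to_days(opt_lag: int, step_days: float = 5.0) -> float:
    """Delay between cause and effect in days (|lag| grid steps)."""
    return abs(int(opt_lag)) * float(step_days)
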