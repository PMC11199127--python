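"""End-to-end pipeline: preprocess -> CCM screen -> CCM pairwise -> ECCM
refine -> surrogate filter -> DAG -> lag-align/fit/evaluate BN ->
sensitivity.

Every stage writes a JSON artifact; a single global seed fans out to
per-stage seeds through ``numpy.random.SeedSequence(seed).spawn``, so no
stage touches OS entropy and a fixed config + seed reproduces every
artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import bn as bn_mod
from . import netbuild, sensitivity
from .edm import EmbeddingParams
from .preprocess import (CategorizationScheme, categorize, normalize_minmax,
                         remove_outliers, resample)
from .series import MultivariateSeries, read_series

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("ccmbn.pipeline")


@dataclass
class PipelineConfig:
    """All pipeline knobs; defaults follow the canonical protocol."""

    input: str | None = None
    target: str = ""
    step_days: float = 5.0
    z_threshold: float = 3.0
    window: int = 100
    gap: int = 10
    skill_min: float = 0.01
    min_windows: int = 10
    surrogates: int = 1000
    surrogate_quantile: float = 0.9
    eccm_frame: int = 400
    eccm_max_library: int = 200
    eccm_max_shift: int = 20
    target_quantile: float = 0.75
    split: float = 0.75
    sensitivity_n: int = 20000
    expert_edges: list = field(default_factory=list)
    sliding: bool = True
    resample_input: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.surrogate_quantile < 1:
            raise ValueError("surrogate quantile must be in (0, 1)")
        if not 0 < self.split < 1:
            raise ValueError("split fraction must be in (0, 1)")
        for name in ("window", "gap", "min_windows", "surrogates",
                     "eccm_frame", "eccm_max_library", "eccm_max_shift",
                     "sensitivity_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds derived from the global seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in children]


def _dump(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def run_pipeline(config: PipelineConfig,
                 series: MultivariateSeries | None = None,
                 outdir: str = ".") -> dict:
    """Run the full causal-analysis pipeline and write its artifacts.

    ``series`` may be passed directly (otherwise ``config.input`` is
    read).  Returns a dict with the in-memory stage results; the artifacts
    network.json, dag.json, bn.json, eval.json and sensitivity.json are
    written under ``outdir`` together with the resolved config.
    """
    os.makedirs(outdir, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    if series is None:
        if not config.input:
            raise ValueError("config.input or an in-memory series is required")
        series = read_series(config.input)
    if config.target not in series.variables:
        raise ValueError(f"target {config.target!r} not in input columns "
                         f"{series.variables}")
    import hashlib

    run_hash = hashlib.sha1(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:12]
    _dump({"config": config.to_dict(), "run_hash": run_hash},
          os.path.join(outdir, "config.json"))

    log.info("stage 1/8: preprocessing")
    clean = remove_outliers(series, config.z_threshold)
    if config.resample_input:
        clean = resample(clean, config.step_days)
    normalized = normalize_minmax(clean)

    log.info("stage 2-3/8: target-focused CCM network")
    network = netbuild.build_target_network(
        normalized, config.target, window=config.window, gap=config.gap,
        skill_min=config.skill_min, min_windows=config.min_windows,
        sliding=config.sliding)
    network.to_json(os.path.join(outdir, "network.json"))

    log.info("stage 4/8: ECCM refinement")
    refined = netbuild.refine_with_eccm(
        network, normalized, frame=config.eccm_frame,
        max_library=config.eccm_max_library, max_shift=config.eccm_max_shift)

    log.info("stage 5/8: surrogate validation")
    validated = netbuild.apply_surrogate_filter(
        refined, normalized, n_surrogates=config.surrogates,
        quantile=config.surrogate_quantile, seed=seeds[0],
        frame=min(config.eccm_frame, len(normalized)))

    log.info("stage 6/8: DAG conversion")
    dag = netbuild.to_dag(validated, config.target)
    if config.expert_edges:
        dag = netbuild.add_expert_edges(dag, config.expert_edges)
    dag.to_json(os.path.join(outdir, "dag.json"))

    results: dict = {"series": clean, "network": network, "refined": refined,
                     "validated": validated, "dag": dag, "bn": None,
                     "evaluation": None, "sensitivity": None}
    if not dag.edges:
        log.warning("empty DAG: skipping BN fit, evaluation and sensitivity")
        _dump({"note": "empty DAG"}, os.path.join(outdir, "bn.json"))
        return results

    log.info("stage 7/8: categorize, lag-align, fit and evaluate the BN")
    scheme = CategorizationScheme(config.target,
                                  target_quantile=config.target_quantile)
    sub = MultivariateSeries(clean.frame[dag.nodes], clean.step_days)
    table = categorize(sub, scheme)
    aligned = bn_mod.shift_align(table, dag)
    net = bn_mod.fit_cpds(dag, aligned, split=config.split)
    net.to_json(os.path.join(outdir, "bn.json"))
    try:
        ev = bn_mod.evaluate(net)
        _dump({"accuracy": ev.accuracy, "auc": ev.auc,
               "confusion": ev.confusion.tolist(), "run_hash": run_hash},
              os.path.join(outdir, "eval.json"))
    except ValueError:
        ev = None

    log.info("stage 8/8: sensitivity analysis")
    scen = sensitivity.random_scenarios(net, n=config.sensitivity_n,
                                        seed=seeds[1])
    contrib = sensitivity.variable_contributions(scen)
    hi, lo, n_hi, n_lo = sensitivity.mean_scenarios(scen)
    _dump({"contributions": contrib.to_dict(),
           "maximizing_profile": hi.to_dict(), "n_maximizing": n_hi,
           "minimizing_profile": lo.to_dict(), "n_minimizing": n_lo,
           "run_hash": run_hash},
          os.path.join(outdir, "sensitivity.json"))

    results.update(bn=net, evaluation=ev,
                   sensitivity={"scenarios": scen, "contributions": contrib,
                                "maximizing": hi, "minimizing": lo,
                                "n_maximizing": n_hi, "n_minimizing": n_lo})
    return results
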