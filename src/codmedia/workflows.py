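"""End-to-end analysis workflows: surface fit -> GA optimization.

Ties the stages into the two hybrid pipelines — quadratic response
surface + GA, and neural network + GA — with YAML configuration, a
single top-level seed fanned out deterministically to every stochastic
stage, and JSON/CSV artifact output with input-content hashes for
provenance.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import ann as ann_mod
from . import ga as ga_mod
from . import metrics, rsm
from .doe import DesignTable, FactorSpec, cod_factors, load_paper_fixture

__all__ = ["RunConfig", "split_seed", "run_rsm_ga", "run_ann_ga", "fold_change"]


def split_seed(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2^31) from one top-level seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % 2**31) for s in state]


def fold_change(activity: float, baseline: float) -> float:
    """Improvement ratio of an achieved activity over a baseline medium."""
    if baseline <= 0:
        raise ValueError("baseline activity must be positive")
    return activity / baseline


@dataclass
class RunConfig:
    """Configuration of one workflow run (YAML-loadable)."""

    factors: list[FactorSpec] = field(default_factory=cod_factors)
    design_csv: str | None = None  # None -> bundled fixture
    out_dir: str = "results"
    seed: int = 0
    basis: str = "uncoded"
    n_hidden: int = 15
    restarts: int = 10
    ann: ann_mod.TrainingConfig | None = None
    ga_bounds: list[tuple[float, float]] | None = None  # None -> design box
    ga_overrides: dict = field(default_factory=dict)
    ga_restarts: int = 3  # repeated seeded runs guard the global optimum
    baseline_activity: float | None = None
    verified_activity: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "factors" in raw:
            kwargs["factors"] = [
                FactorSpec(
                    name=f["name"],
                    center=float(f["center"]),
                    half_range=float(f["half_range"]),
                    alpha=float(f.get("alpha", 2.0)),
                    low_clip=float(f.get("low_clip", 0.0)),
                    units=f.get("units", "g/50 mL"),
                )
                for f in raw["factors"]
            ]
        for key in (
            "design_csv",
            "out_dir",
            "seed",
            "basis",
            "n_hidden",
            "restarts",
            "ga_restarts",
            "baseline_activity",
            "verified_activity",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "ann" in raw:
            kwargs["ann"] = ann_mod.TrainingConfig(**raw["ann"])
        if "ga" in raw:
            ga_block = dict(raw["ga"])
            if "bounds" in ga_block:
                kwargs["ga_bounds"] = [tuple(map(float, b)) for b in ga_block.pop("bounds")]
            kwargs["ga_overrides"] = ga_block
        return cls(**kwargs)

    def load_design(self) -> DesignTable:
        if self.design_csv is None:
            return load_paper_fixture()
        return DesignTable.from_csv(self.design_csv, self.factors)

    def ga_config(self, seed: int, vectorized: bool) -> ga_mod.GAConfig:
        bounds = self.ga_bounds or [f.bounds for f in self.factors]
        kwargs = dict(self.ga_overrides)
        kwargs.pop("bounds", None)
        return ga_mod.GAConfig(bounds=bounds, seed=seed, vectorized=vectorized, **kwargs)


def _design_hash(design: DesignTable) -> str:
    payload = design.df.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()


def _write_log(out_dir: Path, name: str, records: list[dict]) -> None:
    with open(out_dir / name, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def run_rsm_ga(config: RunConfig) -> dict:
    """Quadratic-surface workflow: fit -> ANOVA -> GA maximization.

    Writes ``rsm_model.json``, ``rsm_anova.csv``, ``rsm_ga_trace.csv``
    and ``rsm_ga_summary.json`` under ``config.out_dir`` and returns the
    summary dict.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = split_seed(config.seed, 4)
    log: list[dict] = []

    t0 = time.perf_counter()
    design = config.load_design()
    model, diag = rsm.fit_quadratic(design, basis=config.basis)
    log.append({"stage": "fit_quadratic", "seconds": time.perf_counter() - t0})

    t0 = time.perf_counter()
    anova = rsm.anova_table(model, design)
    anova.to_csv(out_dir / "rsm_anova.csv")
    log.append({"stage": "anova", "seconds": time.perf_counter() - t0})

    t0 = time.perf_counter()
    ga_cfg = config.ga_config(seed=seeds[0], vectorized=True)
    run = ga_mod.optimize_multistart(
        lambda P: model.predict(P), ga_cfg, n_restarts=config.ga_restarts
    )
    log.append({"stage": "ga", "seconds": time.perf_counter() - t0, "seed": seeds[0]})

    model.to_json(out_dir / "rsm_model.json", diagnostics=diag)
    run.trace_to_csv(out_dir / "rsm_ga_trace.csv")

    report = metrics.compare(design.observed, model.predict(design.uncoded))
    summary = {
        "workflow": "rsm_ga",
        "seed": config.seed,
        "input_design_sha256": _design_hash(design),
        "r_squared": diag.r_squared,
        "r": diag.r,
        "f_overall": diag.f_overall,
        "p_overall": diag.p_overall,
        "rmse_standard": report.rmse_standard,
        "rmse_paper_scale": report.rmse_paper_scale,
        "mape_percent": report.mape_percent,
        "best_composition": dict(zip(design.factor_names, run.best_point.tolist())),
        "predicted_activity": run.best_fitness,
        "generations_used": run.generations_used,
        "stop_reason": run.stop_reason,
    }
    if config.baseline_activity is not None:
        achieved = (
            config.verified_activity
            if config.verified_activity is not None
            else run.best_fitness
        )
        summary["fold_change"] = fold_change(achieved, config.baseline_activity)
    (out_dir / "rsm_ga_summary.json").write_text(json.dumps(summary, indent=2))
    _write_log(out_dir, "rsm_ga_log.jsonl", log)
    return summary


def run_ann_ga(config: RunConfig) -> dict:
    """Network workflow: multi-restart training -> GA maximization.

    Trains ``config.restarts`` networks from different seeded
    initializations, keeps the one with the highest validation
    correlation (training correlation when no validation rows exist),
    then maximizes its predicted activity over the bounds with the GA.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    design = config.load_design()
    base_cfg = config.ann or ann_mod.TrainingConfig()
    n_restarts = max(1, config.restarts)
    seeds = split_seed(config.seed, n_restarts + 1)
    log: list[dict] = []

    has_val = (design.df["split"] == "validation").sum() >= 2
    best = None
    t0 = time.perf_counter()
    for i in range(n_restarts):
        net0 = ann_mod.init_network(config.n_hidden, seed=seeds[i], n_inputs=len(config.factors))
        net, rep = ann_mod.train(net0, design, base_cfg)
        score = rep.r_validation if has_val else rep.r_train
        if best is None or score > best[2]:
            best = (net, rep, score)
    net, rep, _ = best
    log.append(
        {
            "stage": "train_ann",
            "seconds": time.perf_counter() - t0,
            "restarts": n_restarts,
            "best_seed": net.seed,
        }
    )

    t0 = time.perf_counter()
    ga_cfg = config.ga_config(seed=seeds[-1], vectorized=True)
    run = ga_mod.optimize_multistart(
        lambda P: net.forward(P), ga_cfg, n_restarts=config.ga_restarts
    )
    log.append({"stage": "ga", "seconds": time.perf_counter() - t0, "seed": seeds[-1]})

    net.to_json(out_dir / "ann_model.json")
    rep.trace_to_csv(out_dir / "ann_training_trace.csv")
    run.trace_to_csv(out_dir / "ann_ga_trace.csv")

    obs_ok = ~np.isnan(design.observed)
    report = metrics.compare(
        design.observed[obs_ok], ann_mod.predict_table(net, design)[obs_ok]
    )
    summary = {
        "workflow": "ann_ga",
        "seed": config.seed,
        "input_design_sha256": _design_hash(design),
        "n_hidden": config.n_hidden,
        "restarts": n_restarts,
        "r_train": rep.r_train,
        "r_test": rep.r_test,
        "r_validation": rep.r_validation,
        "stop_reason_training": rep.stop_reason,
        "rmse_standard": report.rmse_standard,
        "rmse_paper_scale": report.rmse_paper_scale,
        "mape_percent": report.mape_percent,
        "best_composition": dict(zip(design.factor_names, run.best_point.tolist())),
        "predicted_activity": run.best_fitness,
        "generations_used": run.generations_used,
        "stop_reason": run.stop_reason,
    }
    if config.baseline_activity is not None:
        achieved = (
            config.verified_activity
            if config.verified_activity is not None
            else run.best_fitness
        )
        summary["fold_change"] = fold_change(achieved, config.baseline_activity)
    (out_dir / "ann_ga_summary.json").write_text(json.dumps(summary, indent=2))
    _write_log(out_dir, "ann_ga_log.jsonl", log)
    return summary
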