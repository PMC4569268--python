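"""Synthetic CCD datasets with known ground truth.

Emulates the structure of the fermentation study's data: a central
composite design over the five medium components with responses drawn
from a known surface (a quadratic polynomial or a small network) plus
i.i.d. homoscedastic Gaussian noise, and a random train/test/validation
partition in 24/6/6-like proportions.  Because the generating model is
known exactly, every pipeline stage (fitting, diagnostics, GA search)
can be benchmarked for recovery of the truth.

The default noise level (sd 0.15 U/mL) matches the spread of the
replicated center points of the real dataset (observed 2.98-3.28 U/mL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import ga as ga_mod
from .ann import NeuralModel
from .doe import DesignTable, FactorSpec, cod_factors, generate_ccd
from .rsm import QuadraticModel, fit_quadratic

__all__ = [
    "SyntheticSpec",
    "simulate",
    "recovery_benchmark",
    "grid_search_max",
]

DEFAULT_NOISE_SD = 0.15


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset."""

    factors: list[FactorSpec] = field(default_factory=cod_factors)
    truth: QuadraticModel | NeuralModel | None = None
    noise_sd: float = DEFAULT_NOISE_SD
    n_center: int = 10
    fraction: str = "half"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


def _evaluate_truth(truth, X: np.ndarray) -> np.ndarray:
    if isinstance(truth, QuadraticModel):
        return np.asarray(truth.predict(X), dtype=float)
    if isinstance(truth, NeuralModel):
        return np.asarray(truth.forward(X), dtype=float)
    raise TypeError(f"unsupported truth model {type(truth).__name__}")


def _assign_splits(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random partition with test and validation each ~1/6 of the runs."""
    n_hold = max(1, round(n / 6))
    labels = np.array(["train"] * n, dtype=object)
    idx = rng.permutation(n)
    labels[idx[:n_hold]] = "test"
    labels[idx[n_hold : 2 * n_hold]] = "validation"
    return labels


def simulate(spec: SyntheticSpec) -> DesignTable:
    """Generate a CCD with noisy responses from the spec's truth model."""
    if spec.truth is None:
        raise ValueError("spec.truth must be set")
    design = generate_ccd(spec.factors, n_center=spec.n_center, fraction=spec.fraction)
    rng = np.random.default_rng(spec.seed)
    mu = _evaluate_truth(spec.truth, design.uncoded)
    y = mu + rng.normal(0.0, spec.noise_sd, size=len(design))
    out = design.with_observed(y)
    out.df["split"] = _assign_splits(len(design), rng)
    return out


def grid_search_max(
    fn: Callable[[np.ndarray], np.ndarray],
    bounds: Sequence[tuple[float, float]],
    n_per_axis: int = 21,
    chunk_size: int = 200_000,
) -> tuple[np.ndarray, float]:
    """Exhaustive lattice maximization of a vectorized function.

    Evaluates ``fn`` on the full n_per_axis^k lattice over the box in
    memory-bounded chunks and returns (argmax point, max value).  Serves
    as a brute-force cross-check for the GA.
    """
    axes = [np.linspace(lo, hi, n_per_axis) for lo, hi in bounds]
    k = len(axes)
    total = n_per_axis**k
    best_val = -np.inf
    best_point = None
    for start in range(0, total, chunk_size):
        idx = np.arange(start, min(start + chunk_size, total))
        pts = np.empty((len(idx), k))
        rem = idx
        for d in range(k - 1, -1, -1):
            pts[:, d] = axes[d][rem % n_per_axis]
            rem = rem // n_per_axis
        vals = np.asarray(fn(pts), dtype=float)
        j = int(np.argmax(vals))
        if vals[j] > best_val:
            best_val = float(vals[j])
            best_point = pts[j].copy()
    return best_point, best_val


def recovery_benchmark(
    spec: SyntheticSpec,
    n_reps: int,
    ga_config: ga_mod.GAConfig | None = None,
    include_ga: bool = True,
    grid_n: int = 21,
) -> dict:
    """Repeated simulate -> refit -> optimize recovery study.

    For ``n_reps`` independent datasets drawn from the spec, refits the
    21-term quadratic and (optionally) runs the GA on each fitted
    surface, then summarizes per-coefficient bias and RMSE against the
    truth's coefficients and the mean distance between the GA optimum
    and the truth's grid-search optimum over the design box.
    """
    if n_reps < 2:
        raise ValueError(f"n_reps must be >= 2, got {n_reps}")
    if not isinstance(spec.truth, QuadraticModel):
        raise TypeError("recovery_benchmark requires a QuadraticModel truth")

    truth_vec = spec.truth.coefficient_vector()
    bounds = [f.bounds for f in spec.factors]
    true_opt_point, true_opt_val = grid_search_max(
        lambda P: spec.truth.predict(P), bounds, n_per_axis=grid_n
    )

    seeds = np.random.SeedSequence(spec.seed).generate_state(n_reps, dtype=np.uint32)
    coefs = np.empty((n_reps, len(truth_vec)))
    distances = []
    for r in range(n_reps):
        rep_spec = SyntheticSpec(
            factors=spec.factors,
            truth=spec.truth,
            noise_sd=spec.noise_sd,
            n_center=spec.n_center,
            fraction=spec.fraction,
            seed=int(seeds[r] % 2**31),
        )
        table = simulate(rep_spec)
        model, _ = fit_quadratic(table, basis=spec.truth.basis)
        coefs[r] = model.coefficient_vector()
        if include_ga:
            cfg = ga_config or ga_mod.GAConfig(
                bounds=bounds,
                population_size=100,
                generations=60,
                stall_generation_limit=30,
                vectorized=True,
            )
            cfg.seed = int(seeds[r] % 2**31)
            run = ga_mod.optimize_multistart(
                lambda P: model.predict(P), cfg, n_restarts=3
            )
            distances.append(np.linalg.norm(run.best_point - true_opt_point))

    errors = coefs - truth_vec
    out = {
        "term_names": spec.truth.term_names(),
        "truth": truth_vec,
        "bias": errors.mean(axis=0),
        "bias_mc_se": errors.std(axis=0, ddof=1) / np.sqrt(n_reps),
        "rmse": np.sqrt((errors**2).mean(axis=0)),
        "true_optimum_point": true_opt_point,
        "true_optimum_value": true_opt_val,
        "n_reps": n_reps,
    }
    if include_ga:
        out["mean_optimum_distance"] = float(np.mean(distances))
        out["grid_resolution"] = float(
            np.linalg.norm([(hi - lo) / (grid_n - 1) for lo, hi in bounds])
        )
    return out
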