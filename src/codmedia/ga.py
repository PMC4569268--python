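"""Real-coded genetic algorithm for maximizing fitted response models.

Operators mirror a classic generational GA for box-constrained search:
rank-based fitness scaling (scaled fitness 1/sqrt(rank)), stochastic
universal sampling ("stochastic uniform") selection, scattered (uniform)
crossover, elitism, and Gaussian mutation clipped to the bounds.  The
fitness function is any callable over composition vectors — typically a
fitted quadratic surface or neural network — and is maximized.

With a crossover fraction of 1 every non-elite child is a crossover
offspring; an optional per-gene post-crossover mutation rate (default
0.01) keeps the search from stagnating and can be set to 0 for strict
emulation of that configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GAConfig",
    "GARun",
    "DegenerateSelectionError",
    "FitnessEvaluationError",
    "rank_scale",
    "stochastic_uniform_selection",
    "scattered_crossover",
    "optimize",
    "optimize_multistart",
]


class DegenerateSelectionError(ValueError):
    """Selection is impossible because all scaled fitnesses are zero."""


class FitnessEvaluationError(RuntimeError):
    """The fitness function returned a non-finite value."""


@dataclass
class GAConfig:
    """Operator and stopping configuration of the GA.

    ``bounds`` is one (low, high) pair per decision variable and defines
    both the sampling box of the initial population and the clipping box
    for mutation.  ``migration_*`` fields are recorded for fidelity with
    multi-population settings but are no-ops for this single population.
    """

    bounds: Sequence[tuple[float, float]]
    population_size: int = 200
    elite_count: int = 2
    crossover_fraction: float = 1.0
    generations: int = 100
    stall_generation_limit: int = 50
    seed: int = 0
    mutation_rate: float = 0.01
    mutation_sd_fraction: float = 0.1
    fitness_scaling: str = "rank"
    selection: str = "stochastic_uniform"
    crossover: str = "scattered"
    migration_interval: int = 20
    migration_fraction: float = 0.2
    vectorized: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossover_fraction <= 1.0:
            raise ValueError("crossover_fraction must be in [0, 1]")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("require 0 <= elite_count < population_size")
        self.bounds = [(float(lo), float(hi)) for lo, hi in self.bounds]
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"infeasible bounds ({lo}, {hi})")

    @property
    def low(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def high(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])


@dataclass
class GARun:
    best_point: np.ndarray
    best_fitness: float
    trace: list[tuple[float, float]]  # per-generation (best, mean)
    generations_used: int
    stop_reason: str
    seed: int

    def trace_to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.trace, columns=["best", "mean"])
        df.insert(0, "generation", np.arange(1, len(df) + 1))
        df.to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None, config: GAConfig | None = None) -> str:
        obj = {
            "best_point": self.best_point.tolist(),
            "best_fitness": self.best_fitness,
            "generations_used": self.generations_used,
            "stop_reason": self.stop_reason,
            "seed": self.seed,
        }
        if config is not None:
            obj["config"] = {
                k: (list(map(list, v)) if k == "bounds" else v)
                for k, v in config.__dict__.items()
            }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def rank_scale(raw_fitness: np.ndarray | Sequence[float]) -> np.ndarray:
    """Rank-based fitness scaling: scaled_i = 1/sqrt(rank_i), rank 1 = best.

    Ties are broken by input order (earlier entries rank better).
    """
    raw = np.asarray(raw_fitness, dtype=float)
    if raw.size == 0:
        raise ValueError("empty fitness vector")
    order = np.argsort(-raw, kind="stable")
    ranks = np.empty(raw.size, dtype=float)
    ranks[order] = np.arange(1, raw.size + 1)
    return 1.0 / np.sqrt(ranks)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def stochastic_uniform_selection(
    scaled_fitness: np.ndarray | Sequence[float],
    n_picks: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Stochastic universal sampling over the cumulative fitness line.

    A single uniformly offset comb of ``n_picks`` equally spaced pointers
    is laid over the cumulative scaled-fitness line; each pointer selects
    the individual whose segment it lands in.  Expected pick counts are
    proportional to scaled fitness, with integer expectations met exactly.
    """
    scaled = np.asarray(scaled_fitness, dtype=float)
    if np.any(scaled < 0):
        raise ValueError("scaled fitness must be non-negative")
    total = scaled.sum()
    if total <= 0:
        raise DegenerateSelectionError("all scaled fitnesses are zero")
    rng = _as_rng(seed)
    step = total / n_picks
    start = rng.uniform(0.0, step)
    pointers = start + step * np.arange(n_picks)
    edges = np.cumsum(scaled)
    return np.searchsorted(edges, pointers, side="right")


def scattered_crossover(
    parent_a: np.ndarray | Sequence[float],
    parent_b: np.ndarray | Sequence[float],
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Uniform crossover: each gene copied from either parent with p=1/2."""
    pa = np.asarray(parent_a, dtype=float)
    pb = np.asarray(parent_b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError(f"parent length mismatch: {pa.shape} vs {pb.shape}")
    rng = _as_rng(seed)
    mask = rng.integers(0, 2, size=pa.shape).astype(bool)
    return np.where(mask, pa, pb)


def _evaluate(
    fitness: Callable, pop: np.ndarray, vectorized: bool
) -> np.ndarray:
    if vectorized:
        vals = np.asarray(fitness(pop), dtype=float)
    else:
        vals = np.array([float(fitness(ind)) for ind in pop])
    if not np.all(np.isfinite(vals)):
        bad = pop[~np.isfinite(vals)][0]
        raise FitnessEvaluationError(
            f"fitness returned a non-finite value at point {bad.tolist()}"
        )
    return vals


def optimize(fitness: Callable, config: GAConfig) -> GARun:
    """Maximize ``fitness`` over the configured box by a generational GA.

    Stops after ``generations`` generations or when the best fitness has
    not improved for ``stall_generation_limit`` consecutive generations.
    With ``elite_count >= 1`` the best-so-far fitness is non-decreasing.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.low, config.high
    k = len(lo)
    n = config.population_size
    pop = rng.uniform(lo, hi, size=(n, k))

    trace: list[tuple[float, float]] = []
    best_fit = -np.inf
    best_point = pop[0].copy()
    stall = 0
    stop_reason = "generations"
    gen = 0

    for gen in range(1, config.generations + 1):
        vals = _evaluate(fitness, pop, config.vectorized)
        gen_best = float(vals.max())
        trace.append((max(gen_best, best_fit), float(vals.mean())))
        if gen_best > best_fit + 1e-12:
            best_fit = gen_best
            best_point = pop[int(np.argmax(vals))].copy()
            stall = 0
        else:
            stall += 1
            if stall >= config.stall_generation_limit:
                stop_reason = "stall_generation_limit"
                break

        # -- reproduction ------------------------------------------------
        elite_idx = np.argsort(-vals, kind="stable")[: config.elite_count]
        elites = pop[elite_idx].copy()
        n_offspring = n - config.elite_count
        n_xover = int(round(config.crossover_fraction * n_offspring))
        n_mut = n_offspring - n_xover

        scaled = rank_scale(vals)
        parent_idx = stochastic_uniform_selection(scaled, 2 * n_xover + n_mut, rng)
        parent_idx = rng.permutation(parent_idx)

        children = np.empty((n_offspring, k))
        pa = pop[parent_idx[:n_xover]]
        pb = pop[parent_idx[n_xover : 2 * n_xover]]
        mask = rng.integers(0, 2, size=(n_xover, k)).astype(bool)
        children[:n_xover] = np.where(mask, pa, pb)
        if config.mutation_rate > 0 and n_xover > 0:
            hit = rng.random((n_xover, k)) < config.mutation_rate
            noise = rng.normal(0.0, config.mutation_sd_fraction * (hi - lo), (n_xover, k))
            children[:n_xover] = np.where(
                hit, children[:n_xover] + noise, children[:n_xover]
            )
        if n_mut > 0:
            mut_parents = pop[parent_idx[2 * n_xover :]]
            noise = rng.normal(0.0, config.mutation_sd_fraction * (hi - lo), (n_mut, k))
            children[n_xover:] = mut_parents + noise
        np.clip(children, lo, hi, out=children)

        pop = np.vstack([elites, children])

    return GARun(
        best_point=best_point,
        best_fitness=best_fit,
        trace=trace,
        generations_used=gen,
        stop_reason=stop_reason,
        seed=config.seed,
    )


def optimize_multistart(
    fitness: Callable, config: GAConfig, n_restarts: int = 3
) -> GARun:
    """Best of several independently seeded GA runs.

    The fitted surfaces being maximized can be multimodal, and a single
    generational run may converge to a secondary basin; repeating the
    optimization from fresh seeded populations and keeping the best run
    guards the global optimum (the original study likewise repeated its
    optimization to ensure the global optimum).  Restart seeds are
    derived deterministically from ``config.seed``.
    """
    if n_restarts < 1:
        raise ValueError(f"n_restarts must be >= 1, got {n_restarts}")
    seeds = np.random.SeedSequence(config.seed).generate_state(
        n_restarts, dtype=np.uint32
    )
    best: GARun | None = None
    for s in seeds:
        cfg = GAConfig(**{**config.__dict__, "seed": int(s % 2**31)})
        run = optimize(fitness, cfg)
        if best is None or run.best_fitness > best.best_fitness:
            best = run
    return best
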