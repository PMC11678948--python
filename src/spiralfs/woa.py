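"""Canonical Whale Optimization Algorithm (WOA).

The WOA models the bubble-net feeding of humpback whales as a population of
continuous search agents.  Each iteration an agent either (i) shrinks an
encircling move toward the best solution found so far, (ii) performs a
logarithmic-spiral "bubble-net" move around it, or (iii) takes an exploratory
step relative to a randomly chosen agent.  The branch is chosen by a uniform
draw ``p`` and the magnitude of the coefficient ``A``, whose envelope ``a``
decays linearly from 2 to 0 over the run.

This module provides the scalar schedules, the three position-update
operators, boundary clamping, and a reference optimizer loop.  The
multipopulation variant in :mod:`spiralfs.mswoa` reuses these operators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Agent",
    "RunRecord",
    "update_a",
    "encircle",
    "spiral_attack",
    "random_search",
    "correct_bounds",
    "init_population",
    "woa_step",
    "woa_run",
]


@dataclass(eq=False)
class Agent:
    """A candidate solution: continuous position plus cached fitness."""

    position: np.ndarray
    fitness: float | None = None

    def copy(self) -> "Agent":
        return Agent(self.position.copy(), self.fitness)


@dataclass
class RunRecord:
    """Outcome of one optimizer run."""

    best_position: np.ndarray
    best_fitness: float
    history: list[float] = field(default_factory=list)
    n_evaluations: int = 0


def update_a(t: int, max_iter: int) -> float:
    """Convergence envelope ``a = 2 - 2 t / MaxIter``, decaying 2 -> 0.

    ``t`` is 0-based, so the schedule starts exactly at 2 and reaches 0 at
    ``t == max_iter``.
    """
    if max_iter <= 0:
        raise ValueError("max_iter must be positive")
    if not 0 <= t <= max_iter:
        raise ValueError(f"iteration t={t} outside [0, {max_iter}]")
    return 2.0 - 2.0 * t / max_iter


def encircle(x: np.ndarray, x_ref: np.ndarray, a_coef: np.ndarray, c_coef: np.ndarray) -> np.ndarray:
    """Shrinking-encirclement move toward a reference (best) position.

    Returns ``x_ref - A * |C * x_ref - x|`` element-wise, before boundary
    correction.
    """
    x, x_ref = np.asarray(x, float), np.asarray(x_ref, float)
    if x.shape != x_ref.shape:
        raise ValueError("position vectors must have equal length")
    d = np.abs(c_coef * x_ref - x)
    return x_ref - a_coef * d


def spiral_attack(x: np.ndarray, x_ref: np.ndarray, l: float, b: float = 1.0) -> np.ndarray:
    """Logarithmic-spiral move around the reference position.

    ``D' = |x_ref - x|`` and the new position is ``D' e^{bl} cos(2 pi l) +
    x_ref``; the spiral factor is a single scalar applied to every dimension.
    """
    x, x_ref = np.asarray(x, float), np.asarray(x_ref, float)
    if x.shape != x_ref.shape:
        raise ValueError("position vectors must have equal length")
    d = np.abs(x_ref - x)
    return d * (np.exp(b * l) * np.cos(2.0 * np.pi * l)) + x_ref


def random_search(x: np.ndarray, x_rand: np.ndarray, a_coef: np.ndarray, c_coef: np.ndarray) -> np.ndarray:
    """Exploration move relative to a randomly chosen agent."""
    x, x_rand = np.asarray(x, float), np.asarray(x_rand, float)
    if x.shape != x_rand.shape:
        raise ValueError("position vectors must have equal length")
    d = np.abs(c_coef * x_rand - x)
    return x_rand - a_coef * d


def correct_bounds(x: np.ndarray, lb: float = 0.0, ub: float = 1.0) -> np.ndarray:
    """Clamp every component into ``[lb, ub]``."""
    if lb >= ub:
        raise ValueError("lower bound must be strictly below upper bound")
    return np.clip(np.asarray(x, float), lb, ub)


def init_population(n: int, d: int, rng: np.random.Generator,
                    lb: float = 0.0, ub: float = 1.0) -> list[Agent]:
    """Uniformly random initial population of ``n`` agents in ``[lb, ub]^d``."""
    return [Agent(rng.uniform(lb, ub, size=d)) for _ in range(n)]


def _draws(a: float, d: int, rng: np.random.Generator):
    """One agent's random draws, in fixed order: p, scalar A, vector C, l.

    ``A`` is a single scalar per agent (broadcast over dimensions) so the
    ``|A| >= 1`` branch test is well defined; ``C`` is a per-dimension vector.
    """
    p = rng.uniform()
    a_coef = 2.0 * a * rng.uniform() - a
    c_coef = 2.0 * rng.uniform(size=d)
    l = rng.uniform(-1.0, 1.0)
    return p, a_coef, c_coef, l


def woa_step(population: list[Agent], x_best: Agent, t: int, max_iter: int,
             objective, rng: np.random.Generator,
             b: float = 1.0, lb: float = 0.0, ub: float = 1.0) -> int:
    """One in-place WOA iteration over the whole population.

    Each agent takes exactly one of the three moves (encircle when
    ``p < 0.5`` and ``|A| < 1``; random search when ``p < 0.5`` and
    ``|A| >= 1``; spiral otherwise, with ``p == 0.5`` falling to the spiral
    branch), is clamped to the bounds, and re-evaluated.  Returns the number
    of objective evaluations performed.
    """
    if not population:
        raise ValueError("population must be non-empty")
    a = update_a(t, max_iter)
    d = population[0].position.size
    n = len(population)
    for i, agent in enumerate(population):
        p, a_coef, c_coef, l = _draws(a, d, rng)
        if p < 0.5:
            if abs(a_coef) < 1.0:
                new = encircle(agent.position, x_best.position, a_coef, c_coef)
            else:
                j = int(rng.integers(n))
                new = random_search(agent.position, population[j].position, a_coef, c_coef)
        else:
            new = spiral_attack(agent.position, x_best.position, l, b)
        agent.position = correct_bounds(new, lb, ub)
        agent.fitness = float(objective(agent.position))
    return n


def woa_run(objective, d: int, n: int = 10, max_iter: int = 100,
            seed: int | np.random.Generator = 0, b: float = 1.0,
            lb: float = 0.0, ub: float = 1.0) -> RunRecord:
    """Baseline WOA minimization of ``objective`` over ``[lb, ub]^d``.

    The recorded best is elitist: it is only replaced by a strictly better
    solution, so the returned history is non-increasing.  With a fixed seed
    two runs are bit-identical.
    """
    if d < 1:
        raise ValueError("dimension must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    population = init_population(n, d, rng, lb, ub)
    for ag in population:
        ag.fitness = float(objective(ag.position))
    n_eval = n
    best = min(population, key=lambda ag: ag.fitness).copy()
    history = [best.fitness]
    for t in range(max_iter):
        n_eval += woa_step(population, best, t, max_iter, objective, rng, b, lb, ub)
        cand = min(population, key=lambda ag: ag.fitness)
        if cand.fitness < best.fitness:
            best = cand.copy()
        history.append(best.fitness)
    return RunRecord(best.position, best.fitness, history, n_eval)
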