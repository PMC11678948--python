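"""Multispiral whale optimization (MSWOA).

Extends the canonical WOA with three cooperating strategies:

* **Adaptive multipopulation merging (AMS).**  The population is split into
  ``K`` subpopulations, where ``K`` decays exponentially from about ``N/2``
  to one over the run.  Membership is ordered by a fitness-distance score
  that rewards both good fitness and distance from the global best, and
  every ``R`` iterations the subpopulations are instead regrouped at random
  to exchange information.  Each subpopulation follows its own leader, which
  widens exploration and delays premature convergence.

* **Double-spiral search (DSS).**  The exploratory branch is replaced by a
  golden-spiral step around the agent's *own* position with a radius drawn
  from a randomly damped difference to an agent of another subpopulation.
  Because ``e^theta cos(2 pi theta)`` takes both signs and magnitudes above
  and below one, the agent can spiral inward or far outward, which breaks
  search stagnation when agents have clustered.

* **Baleen neighborhood exploitation (BES).**  During the first 20% of the
  run, each subpopulation leader is refined by three-point quadratic
  interpolation (per dimension) followed by a uniform crossover with the
  leader; the candidate replaces the leader only if strictly better.  This
  costs one extra objective evaluation per subpopulation member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .woa import Agent, RunRecord, correct_bounds, encircle, init_population, spiral_attack, update_a

__all__ = [
    "MSWOAConfig",
    "PartitionPlan",
    "subpop_count",
    "fd_scores",
    "partition",
    "dss_update",
    "qi_point",
    "bes_refine",
    "mswoa_run",
]

_QI_TOL = 1e-12  # |denominator| below this -> fall back to the leader coordinate


@dataclass
class MSWOAConfig:
    """Run parameters for both MSWOA and the WOA baseline.

    ``gamma`` is the merge offset of the subpopulation-count schedule,
    ``regroup_period`` the number of iterations between random regroupings,
    and ``bes_fraction`` the fraction of the run in which leader refinement
    is active.
    """

    n: int = 10
    max_iter: int = 100
    gamma: float = 0.8
    regroup_period: int = 10
    bes_fraction: float = 0.2
    b: float = 1.0
    seed: int = 0
    lb: float = 0.0
    ub: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("population size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.regroup_period < 1:
            raise ValueError("regroup_period must be >= 1")
        if not 0.0 < self.bes_fraction <= 1.0:
            raise ValueError("bes_fraction must lie in (0, 1]")


@dataclass
class PartitionPlan:
    """Subpopulation layout for one iteration."""

    k: int
    m: int
    members: list[np.ndarray]  # agent indices per subpopulation

    @property
    def membership(self) -> np.ndarray:
        out = np.empty(sum(len(g) for g in self.members), dtype=int)
        for s, grp in enumerate(self.members):
            out[grp] = s
        return out


def subpop_count(t: int, n: int, max_iter: int, gamma: float = 0.8) -> int:
    """Number of subpopulations at iteration ``t``.

    ``K = floor(N/2 * exp(-ln(N/2) * t/MaxIter) + gamma)`` decays from
    ``floor(N/2 + gamma)`` at the start to ``floor(1 + gamma)`` (one for
    ``gamma < 1``) at the end, fast early and slowly late.
    """
    if n < 2:
        raise ValueError("population size must be >= 2 for the merge schedule")
    if max_iter <= 0 or not 0 <= t <= max_iter:
        raise ValueError("invalid iteration index")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    half = n / 2.0
    k = int(np.floor(half * np.exp(-np.log(half) * t / max_iter) + gamma))
    return max(k, 1)


def fd_scores(population: list[Agent], x_best: Agent) -> np.ndarray:
    """Fitness-distance score ``FD = (1 - fit_norm) + dis_norm`` per agent.

    Fitness and Euclidean distance to the global best are min-max normalized
    over the current population (a degenerate 0/0 normalization is defined
    as 0), so ``FD`` lies in [0, 2]: high for agents that are both fit and
    far from the incumbent best.
    """
    if not population:
        raise ValueError("population must be non-empty")
    if any(ag.fitness is None for ag in population):
        raise RuntimeError("all agents must have evaluated fitness")
    fits = np.array([ag.fitness for ag in population], float)
    dists = np.array([np.linalg.norm(ag.position - x_best.position) for ag in population])

    def _minmax(v: np.ndarray) -> np.ndarray:
        span = v.max() - v.min()
        if span == 0.0:
            return np.zeros_like(v)
        return (v - v.min()) / span

    return (1.0 - _minmax(fits)) + _minmax(dists)


def partition(population: list[Agent], x_best: Agent, t: int,
              config: MSWOAConfig, rng: np.random.Generator) -> PartitionPlan:
    """Assign agents to subpopulations for iteration ``t``.

    Default ordering is by FD score descending (ties by lower index) cut
    into contiguous blocks of ``M = floor(N/K)``; the ``N - K*M`` remainder
    agents are appended to the last subpopulation.  Every
    ``regroup_period`` iterations (t > 0) the ordering is a uniformly random
    permutation instead.
    """
    n = len(population)
    k = subpop_count(t, n, config.max_iter, config.gamma)
    m = n // k
    if t > 0 and t % config.regroup_period == 0:
        order = rng.permutation(n)
    else:
        scores = fd_scores(population, x_best)
        order = np.argsort(-scores, kind="stable")
    members = [order[s * m:(s + 1) * m] for s in range(k)]
    remainder = order[k * m:]
    if remainder.size:
        members[-1] = np.concatenate([members[-1], remainder])
    return PartitionPlan(k, m, members)


def dss_update(x_m: np.ndarray, x_rand: np.ndarray, theta: float,
               w: np.ndarray) -> np.ndarray:
    """Golden-spiral exploration step around the agent's own position.

    Radius ``r = |W * x_rand - x_m|`` with ``W`` a random vector in [0, 1];
    the new position is ``r e^theta cos(2 pi theta) + x_m`` with a single
    scalar spiral factor.  Unlike the canonical random-search move, the step
    is anchored at the agent itself and can reach both nearby and distant
    points regardless of how close the swarm has contracted.
    """
    x_m, x_rand = np.asarray(x_m, float), np.asarray(x_rand, float)
    if x_m.shape != x_rand.shape:
        raise ValueError("position vectors must have equal length")
    if x_m is x_rand or np.shares_memory(x_m, x_rand):
        raise ValueError("x_rand must be a different agent's position")
    r = np.abs(w * x_rand - x_m)
    return r * (np.exp(theta) * np.cos(2.0 * np.pi * theta)) + x_m


def qi_point(x_best_sub: np.ndarray, x_m: np.ndarray, x_r: np.ndarray,
             f_best: float, f_m: float, f_r: float) -> np.ndarray:
    """Per-dimension quadratic-interpolation vertex of three scored points.

    For each dimension the parabola through ``(g_j, F_g)``, ``(m_j, F_m)``,
    ``(r_j, F_r)`` is minimized analytically; dimensions whose denominator
    is (near) zero — collinear or coincident coordinates — fall back to the
    leader coordinate ``g_j``.
    """
    g = np.asarray(x_best_sub, float)
    m = np.asarray(x_m, float)
    r = np.asarray(x_r, float)
    num = (m ** 2 - r ** 2) * f_best + (r ** 2 - g ** 2) * f_m + (g ** 2 - m ** 2) * f_r
    den = 2.0 * ((m - r) * f_best + (r - g) * f_m + (g - m) * f_r)
    out = g.copy()
    ok = np.abs(den) > _QI_TOL
    out[ok] = num[ok] / den[ok]
    return out


def bes_refine(sub_indices: np.ndarray, leader_idx: int, population: list[Agent],
               objective, t: int, config: MSWOAConfig,
               rng: np.random.Generator) -> int:
    """Refine one subpopulation leader by quadratic interpolation + crossover.

    Active only while ``t / max_iter < bes_fraction``; otherwise a no-op.
    For each member, a quadratic-interpolation candidate is built from the
    leader, the member and a random agent of the whole population, then
    crossed per-dimension with the leader (candidate coordinate kept when a
    fresh uniform draw is >= 0.5).  The leader is replaced in place when the
    candidate is strictly better.  Returns the number of extra objective
    evaluations (one per member while active).
    """
    if len(sub_indices) < 1:
        raise ValueError("subpopulation must be non-empty")
    if t / config.max_iter >= config.bes_fraction:
        return 0
    n = len(population)
    leader = population[leader_idx]
    n_eval = 0
    for idx in sub_indices:
        member = population[idx]
        j = int(rng.integers(n))
        rand_agent = population[j]
        x_q = qi_point(leader.position, member.position, rand_agent.position,
                       leader.fitness, member.fitness, rand_agent.fitness)
        take_q = rng.uniform(size=x_q.size) >= 0.5
        x_c = np.where(take_q, x_q, leader.position)
        x_c = correct_bounds(x_c, config.lb, config.ub)
        f_c = float(objective(x_c))
        n_eval += 1
        if f_c < leader.fitness:
            leader.position = x_c
            leader.fitness = f_c
    return n_eval


def _leader_index(population: list[Agent], indices: np.ndarray) -> int:
    best = indices[0]
    for idx in indices[1:]:
        if population[idx].fitness < population[best].fitness:
            best = idx
    return int(best)


def mswoa_run(objective, d: int, config: MSWOAConfig | None = None,
              callback=None) -> RunRecord:
    """Minimize ``objective`` over ``[lb, ub]^d`` with MSWOA.

    Per iteration: partition via AMS; within each subpopulation every agent
    moves by leader-guided encirclement (``p < 0.5``, ``|A| < 1``), the
    double-spiral step (``p < 0.5``, ``|A| >= 1``) or the leader-guided
    spiral (``p >= 0.5``); leaders are then refreshed and refined by BES
    while its gate is open.  The recorded global best is elitist, so the
    returned history is non-increasing; with a fixed seed reruns are
    bit-identical.

    ``callback(t, best_fitness)`` is invoked once per iteration if given.
    """
    if d < 1:
        raise ValueError("dimension must be >= 1")
    cfg = config if config is not None else MSWOAConfig()
    rng = np.random.default_rng(cfg.seed)
    population = init_population(cfg.n, d, rng, cfg.lb, cfg.ub)
    for ag in population:
        ag.fitness = float(objective(ag.position))
    n_eval = cfg.n
    best = min(population, key=lambda ag: ag.fitness).copy()
    history = [best.fitness]
    for t in range(cfg.max_iter):
        plan = partition(population, best, t, cfg, rng)
        a = update_a(t, cfg.max_iter)
        for s, indices in enumerate(plan.members):
            leader_idx = _leader_index(population, indices)
            x_leader = population[leader_idx].position.copy()
            for idx in indices:
                agent = population[idx]
                p = rng.uniform()
                a_coef = 2.0 * a * rng.uniform() - a
                c_coef = 2.0 * rng.uniform(size=d)
                l = rng.uniform(-1.0, 1.0)
                if p < 0.5:
                    if abs(a_coef) < 1.0:
                        new = encircle(agent.position, x_leader, a_coef, c_coef)
                    else:
                        j = _draw_other(plan, s, idx, rng)
                        theta = rng.uniform(-1.0, 1.0)
                        w = rng.uniform(size=d)
                        new = dss_update(agent.position, population[j].position, theta, w)
                else:
                    new = spiral_attack(agent.position, x_leader, l, cfg.b)
                agent.position = correct_bounds(new, cfg.lb, cfg.ub)
                agent.fitness = float(objective(agent.position))
                n_eval += 1
        # leaders are refreshed after the full sweep, then refined
        for indices in plan.members:
            leader_idx = _leader_index(population, indices)
            n_eval += bes_refine(indices, leader_idx, population, objective, t, cfg, rng)
        cand = min(population, key=lambda ag: ag.fitness)
        if cand.fitness < best.fitness:
            best = cand.copy()
        history.append(best.fitness)
        if callback is not None:
            callback(t, best.fitness)
    return RunRecord(best.position, best.fitness, history, n_eval)


def _draw_other(plan: PartitionPlan, s: int, self_idx: int,
                rng: np.random.Generator) -> int:
    """Random agent of another subpopulation (any other agent when K = 1)."""
    if plan.k > 1:
        pool = np.concatenate([grp for q, grp in enumerate(plan.members) if q != s])
    else:
        pool = np.array([i for i in plan.members[0] if i != self_idx])
    return int(pool[rng.integers(pool.size)])
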