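import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spiralfs.mswoa import (
    MSWOAConfig,
    bes_refine,
    dss_update,
    fd_scores,
    mswoa_run,
    partition,
    qi_point,
    subpop_count,
)
from spiralfs.woa import Agent


def _sphere(x):
    return float(np.sum((x - 0.5) ** 2))


def _population(rng, n, d, objective=_sphere):
    pop = [Agent(rng.uniform(size=d)) for _ in range(n)]
    for ag in pop:
        ag.fitness = objective(ag.position)
    return pop


class TestMergeSchedule:
    @pytest.mark.parametrize("t,expected", [(0, 5), (50, 3), (100, 1)])
    def test_reference_values(self, t, expected):
        assert subpop_count(t, n=10, max_iter=100, gamma=0.8) == expected

    def test_non_increasing_and_reaches_one(self):
        ks = [subpop_count(t, 10, 100, 0.8) for t in range(101)]
        assert all(a >= b for a, b in zip(ks, ks[1:]))
        assert ks[-1] == 1

    def test_small_population_rejected(self):
        with pytest.raises(ValueError):
            subpop_count(0, n=1, max_iter=10, gamma=0.5)


class TestFDScores:
    def test_best_agent_scores_one(self):
        rng = np.random.default_rng(0)
        pop = _population(rng, 6, 3)
        best = min(pop, key=lambda ag: ag.fitness)
        scores = fd_scores(pop, best)
        assert scores[pop.index(best)] == pytest.approx(1.0)

    def test_identical_population_degenerates_to_one(self):
        pop = [Agent(np.full(3, 0.2), 0.5) for _ in range(4)]
        assert np.allclose(fd_scores(pop, pop[0]), 1.0)

    def test_hand_computed_case(self):
        # fitness [0.1, 0.2, 0.9], distances to best [0, 0.4, 0.2]
        pop = [Agent(np.array([0.0]), 0.1), Agent(np.array([0.4]), 0.2),
               Agent(np.array([0.2]), 0.9)]
        scores = fd_scores(pop, pop[0])
        assert np.allclose(scores, [1.0, 1.875, 0.5])

    def test_bounds(self):
        rng = np.random.default_rng(3)
        pop = _population(rng, 20, 4)
        best = min(pop, key=lambda ag: ag.fitness)
        scores = fd_scores(pop, best)
        assert np.all((scores >= 0.0) & (scores <= 2.0))

    def test_unevaluated_fitness_rejected(self):
        pop = [Agent(np.zeros(2)), Agent(np.ones(2), 1.0)]
        with pytest.raises(RuntimeError):
            fd_scores(pop, pop[1])


class TestPartition:
    def _plan(self, n, t, max_iter=100, regroup=10, seed=0):
        rng = np.random.default_rng(seed)
        pop = _population(rng, n, 3)
        best = min(pop, key=lambda ag: ag.fitness)
        cfg = MSWOAConfig(n=n, max_iter=max_iter, regroup_period=regroup)
        return partition(pop, best, t, cfg, rng)

    def test_true_partition_five_blocks(self):
        plan = self._plan(10, t=0)
        assert plan.k == 5 and plan.m == 2
        all_members = np.concatenate(plan.members)
        assert sorted(all_members) == list(range(10))

    def test_remainder_to_last_subpopulation(self):
        # K = 3 at mid-run for N = 10: sizes (3, 3, 4)
        plan = self._plan(10, t=50)
        assert plan.k == 3
        assert [len(g) for g in plan.members] == [3, 3, 4]

    def test_single_subpopulation_at_end(self):
        plan = self._plan(10, t=99)
        assert plan.k == 1 and len(plan.members[0]) == 10

    def test_regrouping_changes_order_not_membership_set(self):
        plan_fd = self._plan(10, t=5)
        plan_rand = self._plan(10, t=10)
        for plan in (plan_fd, plan_rand):
            assert sorted(np.concatenate(plan.members)) == list(range(10))


class TestDSS:
    def test_quarter_turn_annihilates_radial_term(self):
        x = np.array([0.3, 0.7])
        out = dss_update(x, np.array([0.9, 0.1]), theta=0.25, w=np.full(2, 0.5))
        assert np.allclose(out, x)

    def test_zero_radius(self):
        x = np.array([0.2, 0.4])
        xr = np.array([0.4, 0.8])
        out = dss_update(x, xr, theta=0.7, w=np.full(2, 0.5))  # w*xr == x
        assert np.allclose(out, x)

    def test_scalar_case(self):
        # r = |1*0.6 - 0.5| = 0.1; 0.5 + 0.1 e^{0.5} cos(pi)
        out = dss_update(np.array([0.5]), np.array([0.6]), theta=0.5,
                         w=np.array([1.0]))
        assert out[0] == pytest.approx(0.5 - 0.1 * np.exp(0.5), abs=1e-6)

    def test_same_agent_rejected(self):
        x = np.array([0.5])
        with pytest.raises(ValueError):
            dss_update(x, x, theta=0.1, w=np.array([1.0]))


class TestQuadraticInterpolation:
    def test_recovers_parabola_vertex(self):
        # f(x) = (x-2)^2 through x = 1, 3, 4 -> vertex at 2
        out = qi_point(np.array([1.0]), np.array([3.0]), np.array([4.0]),
                       1.0, 1.0, 4.0)
        assert out[0] == pytest.approx(2.0)

    def test_degenerate_falls_back_to_leader(self):
        g = np.array([0.3])
        out = qi_point(g, g, g, 1.0, 1.0, 1.0)
        assert out[0] == 0.3

    def test_three_point_vertex_of_x_squared(self):
        out = qi_point(np.array([0.2]), np.array([0.5]), np.array([0.9]),
                       0.04, 0.25, 0.81)
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(-5, 5), st.floats(0.1, 5), st.floats(-3, 3),
           st.floats(-3, 3), st.floats(-3, 3))
    @settings(max_examples=200, deadline=None)
    def test_exact_vertex_for_random_quadratics(self, vertex, curvature, g, m, r):
        pts = np.array([g, m, r])
        if np.min(np.abs(pts[:, None] - pts[None, :])[np.triu_indices(3, 1)]) < 1e-3:
            return  # needs three distinct abscissae
        f = lambda x: curvature * (x - vertex) ** 2 + 1.0
        out = qi_point(np.array([g]), np.array([m]), np.array([r]),
                       f(g), f(m), f(r))
        assert out[0] == pytest.approx(vertex, abs=1e-6, rel=1e-6)


class TestBES:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        pop = _population(rng, 6, 3)
        indices = np.arange(6)
        leader = int(np.argmin([ag.fitness for ag in pop]))
        return rng, pop, indices, leader

    def test_gate_closes_after_fraction(self):
        rng, pop, indices, leader = self._setup()
        calls = []
        obj = lambda x: calls.append(1) or _sphere(x)
        cfg = MSWOAConfig(n=6, max_iter=100)
        n_eval = bes_refine(indices, leader, pop, obj, t=20, config=cfg, rng=rng)
        assert n_eval == 0 and not calls

    def test_one_extra_evaluation_per_member_when_open(self):
        rng, pop, indices, leader = self._setup()
        cfg = MSWOAConfig(n=6, max_iter=100)
        n_eval = bes_refine(indices, leader, pop, _sphere, t=0, config=cfg, rng=rng)
        assert n_eval == len(indices)

    def test_never_worsens_leader(self):
        for seed in range(10):
            rng, pop, indices, leader = self._setup(seed)
            before = pop[leader].fitness
            cfg = MSWOAConfig(n=6, max_iter=100)
            bes_refine(indices, leader, pop, _sphere, t=0, config=cfg, rng=rng)
            assert pop[leader].fitness <= before


class TestRun:
    def test_fixed_seed_bit_identical(self):
        cfg = MSWOAConfig(n=8, max_iter=30, seed=5)
        r1 = mswoa_run(_sphere, d=4, config=cfg)
        r2 = mswoa_run(_sphere, d=4, config=cfg)
        assert np.array_equal(r1.best_position, r2.best_position)
        assert r1.history == r2.history and r1.n_evaluations == r2.n_evaluations

    def test_history_non_increasing(self):
        for seed in range(5):
            rec = mswoa_run(_sphere, d=5, config=MSWOAConfig(n=10, max_iter=50, seed=seed))
            assert all(a >= b for a, b in zip(rec.history, rec.history[1:]))

    def test_evaluation_budget(self):
        # N per iteration plus one BES extra per agent while the gate is open
        cfg = MSWOAConfig(n=10, max_iter=50, seed=1)
        rec = mswoa_run(_sphere, d=3, config=cfg)
        base = 10 + 10 * 50
        bes_extra = 10 * 10  # first 20% of 50 iterations
        assert base <= rec.n_evaluations <= base + bes_extra

    def test_callback_invoked_each_iteration(self):
        seen = []
        mswoa_run(_sphere, d=2, config=MSWOAConfig(n=4, max_iter=12, seed=0),
                  callback=lambda t, f: seen.append(t))
        assert seen == list(range(12))
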