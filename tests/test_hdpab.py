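"""Swarm-optimizer unit tests: operator algebra on hand cases, elitism and
bound invariants, determinism, and benchmark convergence."""

import numpy as np
import pytest

from biosigfusion import hdpab as hd
from biosigfusion.synthetic_data import benchmark_function

SPHERE = lambda x: float(np.sum(np.asarray(x) ** 2))


def _config(dims=3, NP=8, **kw):
    kw.setdefault("bounds", (np.full(dims, -5.0), np.full(dims, 5.0)))
    kw.setdefault("seed", 0)
    return hd.HDPABConfig(NP=NP, dims=dims, **kw)


def _state(config, fn=SPHERE, seed=0):
    return hd.initialize_population(config, fn, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

def test_init_containment_and_determinism():
    cfg = _config(dims=4, NP=10)
    s1 = _state(cfg, seed=3)
    s2 = _state(cfg, seed=3)
    lo, hi = cfg.bounds
    assert np.all(s1.positions >= lo) and np.all(s1.positions <= hi)
    np.testing.assert_array_equal(s1.positions, s2.positions)
    np.testing.assert_array_equal(s1.fitness, s2.fitness)
    assert s1.elite_value == s1.gbest_value == s1.pbest_values.min()


def test_init_degenerate_bound_dimension():
    cfg = hd.HDPABConfig(
        NP=6, dims=2, bounds=(np.array([0.0, 2.0]), np.array([1.0, 2.0])),
        seed=0,
    )
    s = _state(cfg)
    assert np.all(s.positions[:, 1] == 2.0)


def test_population_too_small():
    with pytest.raises(ValueError):
        _config(NP=3)


# ---------------------------------------------------------------------------
# DE step
# ---------------------------------------------------------------------------

def test_de_mutant_arithmetic():
    # Y = A_x + G (A_z - A_w) with G = 0.5
    ax, az, aw = np.array([1.0, 1.0]), np.array([2.0, 0.0]), np.array([0.0, 2.0])
    np.testing.assert_array_equal(ax + 0.5 * (az - aw), [2.0, 0.0])


def test_de_step_greedy_never_worsens():
    cfg = _config(dims=5, NP=12)
    s = _state(cfg)
    before = s.fitness.copy()
    hd.de_step(s, G=0.7, CR=0.9, fitness_fn=SPHERE,
               rng=np.random.default_rng(1), bounds=cfg.bounds)
    assert np.all(s.fitness <= before)
    lo, hi = cfg.bounds
    assert np.all(s.positions >= lo) and np.all(s.positions <= hi)


def test_de_identical_population_is_stuck():
    cfg = _config(dims=3, NP=6)
    s = _state(cfg)
    s.positions[:] = 1.0
    s.fitness[:] = SPHERE(np.ones(3))
    before = s.fitness.copy()
    hd.de_step(s, G=0.5, CR=1.0, fitness_fn=SPHERE,
               rng=np.random.default_rng(0), bounds=cfg.bounds)
    np.testing.assert_array_equal(s.fitness, before)
    assert np.all(s.positions == 1.0)


def test_de_cr_zero_leaves_members_unchanged():
    cfg = _config(dims=3, NP=6)
    s = _state(cfg)
    pos = s.positions.copy()
    hd.de_step(s, G=0.5, CR=0.0, fitness_fn=SPHERE,
               rng=np.random.default_rng(0), bounds=cfg.bounds)
    np.testing.assert_array_equal(s.positions, pos)


# ---------------------------------------------------------------------------
# PSO step
# ---------------------------------------------------------------------------

def test_pso_pure_inertia_translates():
    cfg = _config(dims=2, NP=4)
    s = _state(cfg)
    s.velocities[:] = 0.25
    pos = s.positions.copy()
    hd.pso_step(s, q_inertia=1.0, w1=0.0, w2=0.0, fitness_fn=SPHERE,
                bounds=cfg.bounds)
    np.testing.assert_allclose(s.velocities, 0.25)
    np.testing.assert_allclose(s.positions, np.clip(pos + 0.25, *cfg.bounds))


def test_pso_velocity_halves_at_consensus():
    cfg = _config(dims=2, NP=4)
    s = _state(cfg)
    s.positions[:] = 0.5
    s.fitness[:] = SPHERE([0.5, 0.5])
    s.pbest_positions[:] = 0.5
    s.pbest_values[:] = s.fitness
    s.gbest_position[:] = 0.5
    s.velocities[:] = 0.8
    hd.pso_step(s, q_inertia=0.5, w1=1.0, w2=1.0, fitness_fn=SPHERE,
                bounds=cfg.bounds)
    # at the consensus point the attraction terms vanish before the move
    np.testing.assert_allclose(s.velocities[:, 0], 0.4)


def test_pso_stationary_at_gbest():
    cfg = _config(dims=2, NP=4)
    s = _state(cfg)
    s.positions[0] = s.gbest_position = np.zeros(2)
    s.pbest_positions[0] = np.zeros(2)
    s.velocities[0] = 0.0
    s.fitness[0] = 0.0
    s.pbest_values[0] = 0.0
    s.gbest_value = 0.0
    hd.pso_step(s, q_inertia=0.7, w1=0.9, w2=0.9, fitness_fn=SPHERE,
                bounds=cfg.bounds)
    np.testing.assert_allclose(s.positions[0], 0.0)


# ---------------------------------------------------------------------------
# ABC scout step
# ---------------------------------------------------------------------------

def test_scout_noop_below_limit():
    cfg = _config(dims=3, NP=6)
    s = _state(cfg)
    pos = s.positions.copy()
    hd.abc_scout_step(s, limit=5, bounds=cfg.bounds,
                      rng=np.random.default_rng(0), fitness_fn=SPHERE)
    np.testing.assert_array_equal(s.positions, pos)


def test_scout_reseeds_stale_members_in_bounds():
    cfg = _config(dims=3, NP=6)
    s = _state(cfg)
    s.trial_counters[:] = 99
    elite_before = s.elite_value
    hd.abc_scout_step(s, limit=1, bounds=cfg.bounds,
                      rng=np.random.default_rng(0), fitness_fn=SPHERE)
    assert np.all(s.trial_counters == 0)
    lo, hi = cfg.bounds
    assert np.all(s.positions >= lo) and np.all(s.positions <= hi)
    assert s.elite_value <= elite_before  # elite archive never lost


def test_scout_degenerate_bounds_land_on_amin():
    cfg = hd.HDPABConfig(
        NP=4, dims=2, bounds=(np.zeros(2), np.zeros(2)), seed=0
    )
    s = _state(cfg)
    s.trial_counters[:] = 1
    hd.abc_scout_step(s, limit=1, bounds=cfg.bounds,
                      rng=np.random.default_rng(0), fitness_fn=SPHERE)
    np.testing.assert_array_equal(s.positions, 0.0)


# ---------------------------------------------------------------------------
# Full loop
# ---------------------------------------------------------------------------

def test_optimize_elite_monotone_and_deterministic():
    cfg = _config(dims=6, NP=12, max_iter=30)
    p1, v1, h1 = hd.hdpab_optimize(SPHERE, cfg)
    p2, v2, h2 = hd.hdpab_optimize(SPHERE, cfg)
    np.testing.assert_array_equal(p1, p2)
    assert v1 == v2
    np.testing.assert_array_equal(h1, h2)
    assert np.all(np.diff(h1) <= 0.0 + 1e-15)


def test_optimize_zero_iterations_returns_initial_best():
    cfg = _config(dims=4, NP=10, max_iter=0)
    _, val, hist = hd.hdpab_optimize(SPHERE, cfg)
    s = hd.initialize_population(
        cfg.resolved(np.random.default_rng(cfg.seed)), SPHERE,
        np.random.default_rng(cfg.seed),
    )
    assert len(hist) == 1
    assert val <= s.fitness.min() + 1e-12


def test_optimize_rastrigin_beats_random_spread():
    fn, _, _ = benchmark_function("rastrigin", 5)
    cfg = hd.HDPABConfig(
        NP=40, dims=5, bounds=(np.full(5, -5.12), np.full(5, 5.12)),
        max_iter=300, seed=1,
    )
    _, val, _ = hd.hdpab_optimize(fn, cfg)
    assert val < 5.0


def test_non_finite_fitness_rejected():
    def nasty(x):
        return np.nan if x[0] > 0 else SPHERE(x)

    cfg = _config(dims=2, NP=6, max_iter=5)
    _, val, _ = hd.hdpab_optimize(nasty, cfg)
    assert np.isfinite(val)


# ---------------------------------------------------------------------------
# Feature-subset encoding
# ---------------------------------------------------------------------------

def test_position_to_mask_saturation_and_fallback():
    assert hd.position_to_mask(np.full(5, 10.0)).all()
    m = hd.position_to_mask(np.array([-10.0, -12.0, -9.0]))
    assert m.tolist() == [False, False, True]  # single best-scoring feature
    # exact zero with threshold 0.5 is excluded (strict inequality)
    m2 = hd.position_to_mask(np.array([0.0, 3.0]))
    assert m2.tolist() == [False, True]


def test_subset_fitness_separable_and_null(rng):
    n = 120
    y = np.repeat([0, 1], n // 2)
    X = np.column_stack([
        y * 4.0 + rng.normal(0, 0.2, n),       # perfectly separating
        rng.standard_normal(n),                 # noise
    ])
    good = hd.subset_fitness(np.array([True, False]), X, y, lam=0.0, seed=0)
    assert good < 0.02
    shuffled = hd.subset_fitness(
        np.array([True, False]), X, rng.permutation(y), lam=0.0, seed=0
    )
    assert 0.3 < 1.0 - shuffled < 0.7


def test_subset_fitness_sparsity_penalty(rng):
    n = 80
    y = np.repeat([0, 1], n // 2)
    X = np.column_stack([y * 4.0 + rng.normal(0, 0.2, n),
                         y * 4.0 + rng.normal(0, 0.2, n)])
    sparse = hd.subset_fitness(np.array([True, False]), X, y, lam=0.5, seed=0)
    full = hd.subset_fitness(np.array([True, True]), X, y, lam=0.5, seed=0)
    assert full > sparse  # equal accuracy, penalised for extra feature


def test_subset_fitness_single_class_error(rng):
    X = rng.standard_normal((20, 3))
    with pytest.raises(ValueError):
        hd.subset_fitness(np.array([True, False, False]), X, np.zeros(20))


def test_select_features_finds_informative_feature(rng):
    n = 100
    y = np.repeat([0, 1], n // 2)
    X = np.column_stack([
        rng.standard_normal(n),
        y * 3.0 + rng.normal(0, 0.3, n),
        rng.standard_normal(n),
    ])
    mask, history = hd.select_features(X, y, NP=10, max_iter=10, seed=0)
    assert mask[1]
    assert np.all(np.diff(history) <= 1e-15)
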