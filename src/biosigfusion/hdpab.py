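"""Hybrid DE -> PSO -> ABC optimizer (HDPAB) and its feature-selection wrapper.

Each iteration chains the three operator families over one shared
population: differential-evolution mutation/crossover/greedy selection,
a particle-swarm velocity/position update, and the artificial-bee-colony
scout rule that re-seeds members stagnant for ``limit`` sweeps.  The
best-ever solution is archived after every phase (elitism), so the elite
trajectory is non-increasing by construction.

The PSO velocity update is deterministic,

    Velo_i <- q Velo_i + w1 (pbest_i - A_i) + w2 (gbest - A_i),

with no stochastic multipliers; ``stochastic_pso=True`` restores the
canonical Uniform(0,1) factors.  Control parameters left unset are drawn
once per run from ``param_ranges``.

For feature selection, continuous positions encode subsets through a
sigmoid threshold and candidate subsets are scored by nearest-centroid
balanced accuracy under internal cross-validation plus a sparsity penalty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestCentroid

logger = logging.getLogger("biosigfusion")

#: Ranges the unset control parameters are drawn from.  The attraction
#: coefficients are scaled for the *deterministic* velocity rule: canonical
#: PSO multiplies c1 = c2 = 2 by Uniform(0,1) factors with mean 1/2, so the
#: deterministic analogue of the canonical attraction is w ~ 1.  Keeping
#: w1 + w2 <= 2 also guarantees the damped-oscillator stability condition
#: w1 + w2 < 2 (1 + q) for every draw.
DEFAULT_PARAM_RANGES = {
    "G": (0.4, 0.9),
    "CR": (0.1, 0.9),
    "q_inertia": (0.4, 0.9),
    "w1": (0.5, 1.0),
    "w2": (0.5, 1.0),
}

#: Velocity clamp as a fraction of the box width per dimension.
VMAX_FRACTION = 0.2


@dataclass
class HDPABConfig:
    """Optimizer configuration.  Control parameters left ``None`` are drawn
    uniformly from ``param_ranges`` once at the start of a run; ``limit``
    defaults to NP * dims / 2 abandonment sweeps."""

    NP: int
    dims: int
    bounds: tuple[np.ndarray, np.ndarray] | tuple[Sequence[float], Sequence[float]]
    G: float | None = None
    CR: float | None = None
    q_inertia: float | None = None
    w1: float | None = None
    w2: float | None = None
    limit: int | None = None
    max_iter: int = 100
    seed: int = 0
    param_ranges: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_RANGES))
    stochastic_pso: bool = False
    #: redraw unset control parameters every iteration (default) or once
    #: per run.  The deterministic velocity rule makes a single unlucky
    #: draw an absorbing collapse; varying the draw restores robustness.
    redraw_each_iter: bool = True

    def __post_init__(self) -> None:
        lo = np.broadcast_to(
            np.asarray(self.bounds[0], dtype=float), (self.dims,)
        ).copy()
        hi = np.broadcast_to(
            np.asarray(self.bounds[1], dtype=float), (self.dims,)
        ).copy()
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise ValueError("bounds must be finite")
        if np.any(lo > hi):
            raise ValueError("need a_min <= a_max per dimension")
        self.bounds = (lo, hi)
        if self.NP < 4:
            raise ValueError("DE needs a population of at least 4")

    def resolved(self, rng: np.random.Generator) -> "HDPABConfig":
        """Copy with every unset control parameter drawn from its range."""
        vals = {}
        for name in ("G", "CR", "q_inertia", "w1", "w2"):
            v = getattr(self, name)
            if v is None:
                a, b = self.param_ranges[name]
                v = float(rng.uniform(a, b))
            vals[name] = v
        limit = self.limit
        if limit is None:
            limit = max(1, self.NP * self.dims // 2)
        return HDPABConfig(
            NP=self.NP, dims=self.dims, bounds=self.bounds, limit=limit,
            max_iter=self.max_iter, seed=self.seed,
            param_ranges=self.param_ranges,
            stochastic_pso=self.stochastic_pso,
            redraw_each_iter=self.redraw_each_iter, **vals,
        )


@dataclass
class SwarmState:
    """Population state shared by the three operator phases."""

    positions: np.ndarray          # (NP, dims)
    velocities: np.ndarray         # (NP, dims)
    fitness: np.ndarray            # (NP,)
    pbest_positions: np.ndarray
    pbest_values: np.ndarray
    gbest_position: np.ndarray
    gbest_value: float
    trial_counters: np.ndarray     # (NP,) int
    elite_position: np.ndarray
    elite_value: float

    def refresh_bests(self) -> None:
        improved = self.fitness < self.pbest_values
        self.pbest_positions[improved] = self.positions[improved]
        self.pbest_values[improved] = self.fitness[improved]
        ib = int(np.argmin(self.pbest_values))
        self.gbest_position = self.pbest_positions[ib].copy()
        self.gbest_value = float(self.pbest_values[ib])
        if self.gbest_value < self.elite_value:
            self.elite_value = self.gbest_value
            self.elite_position = self.gbest_position.copy()


def _evaluate(fitness_fn: Callable, X: np.ndarray) -> np.ndarray:
    vals = np.array([fitness_fn(x) for x in X], dtype=float)
    bad = ~np.isfinite(vals)
    if np.any(bad):
        logger.warning("%d non-finite fitness values rejected", int(bad.sum()))
        vals[bad] = np.inf
    return vals


def initialize_population(
    config: HDPABConfig, fitness_fn: Callable, rng: np.random.Generator
) -> SwarmState:
    """Uniform positions in the box, zero velocities, evaluated fitness;
    the elite starts at the initial global best."""
    lo, hi = config.bounds
    positions = lo + rng.uniform(0.0, 1.0, (config.NP, config.dims)) * (hi - lo)
    fitness = _evaluate(fitness_fn, positions)
    ib = int(np.argmin(fitness))
    return SwarmState(
        positions=positions,
        velocities=np.zeros_like(positions),
        fitness=fitness,
        pbest_positions=positions.copy(),
        pbest_values=fitness.copy(),
        gbest_position=positions[ib].copy(),
        gbest_value=float(fitness[ib]),
        trial_counters=np.zeros(config.NP, dtype=int),
        elite_position=positions[ib].copy(),
        elite_value=float(fitness[ib]),
    )


def de_step(
    state: SwarmState,
    G: float,
    CR: float,
    fitness_fn: Callable,
    rng: np.random.Generator,
    bounds: tuple[np.ndarray, np.ndarray],
) -> SwarmState:
    """Differential-evolution sweep: rand/1 mutant Y_i = A_x + G (A_z - A_w)
    from three distinct partners (all != i), binomial crossover at rate CR
    (no forced crossover index, so CR = 0 leaves members unchanged), and
    greedy replacement only on strict improvement."""
    NP = state.positions.shape[0]
    lo, hi = bounds
    for i in range(NP):
        x, zz, w = rng.choice(
            [j for j in range(NP) if j != i], size=3, replace=False
        )
        mutant = state.positions[x] + G * (
            state.positions[zz] - state.positions[w]
        )
        n_j = rng.uniform(0.0, 1.0, state.positions.shape[1])
        trial = np.where(n_j <= CR, mutant, state.positions[i])
        trial = np.clip(trial, lo, hi)
        f_trial = float(fitness_fn(trial))
        if not np.isfinite(f_trial):
            logger.warning("non-finite fitness for DE trial rejected")
            continue
        if f_trial < state.fitness[i]:
            state.positions[i] = trial
            state.fitness[i] = f_trial
    state.refresh_bests()
    return state


def pso_step(
    state: SwarmState,
    q_inertia: float,
    w1: float,
    w2: float,
    fitness_fn: Callable,
    bounds: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator | None = None,
    stochastic: bool = False,
) -> SwarmState:
    """Particle-swarm sweep with the deterministic velocity rule (or the
    canonical stochastic one when ``stochastic=True``).  Velocities are
    clamped to ``VMAX_FRACTION`` of the box width per dimension so clipped
    particles cannot accumulate runaway velocity at the boundary."""
    lo, hi = bounds
    if stochastic:
        if rng is None:
            raise ValueError("stochastic PSO needs an rng")
        r1 = rng.uniform(0.0, 1.0, state.positions.shape)
        r2 = rng.uniform(0.0, 1.0, state.positions.shape)
    else:
        r1 = r2 = 1.0
    state.velocities = (
        q_inertia * state.velocities
        + w1 * r1 * (state.pbest_positions - state.positions)
        + w2 * r2 * (state.gbest_position[None, :] - state.positions)
    )
    vmax = VMAX_FRACTION * (hi - lo)
    state.velocities = np.clip(state.velocities, -vmax, vmax)
    state.positions = np.clip(state.positions + state.velocities, lo, hi)
    state.fitness = _evaluate(fitness_fn, state.positions)
    state.refresh_bests()
    return state


def abc_scout_step(
    state: SwarmState,
    limit: int,
    bounds: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator,
    fitness_fn: Callable,
) -> SwarmState:
    """ABC scout rule: members whose trial counter reached ``limit`` are
    re-seeded uniformly in the box and re-evaluated; counters reset.  The
    elite archive is untouched, so nothing is lost."""
    if limit < 1:
        raise ValueError("limit must be >= 1")
    lo, hi = bounds
    stale = state.trial_counters >= limit
    if np.any(stale):
        n = int(stale.sum())
        state.positions[stale] = lo + rng.uniform(
            0.0, 1.0, (n, state.positions.shape[1])
        ) * (hi - lo)
        state.fitness[stale] = _evaluate(fitness_fn, state.positions[stale])
        state.trial_counters[stale] = 0
        state.refresh_bests()
    return state


def hdpab_optimize(
    fitness_fn: Callable[[np.ndarray], float],
    config: HDPABConfig,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Run the DE -> PSO -> ABC loop for ``max_iter`` iterations.

    Returns the elite position, its value, and the per-iteration elite
    history (entry 0 is the post-initialisation elite).  Trial counters
    increment when a member fails to improve over a full DE+PSO sweep and
    reset on any improvement.  Unset control parameters are drawn from
    ``param_ranges`` — every iteration by default, or once per run with
    ``redraw_each_iter=False``.
    """
    rng = np.random.default_rng(config.seed)
    cfg = config.resolved(rng)
    state = initialize_population(cfg, fitness_fn, rng)
    history = [state.elite_value]
    for _ in range(cfg.max_iter):
        if config.redraw_each_iter:
            cfg = config.resolved(rng)
        before = state.fitness.copy()
        state = de_step(state, cfg.G, cfg.CR, fitness_fn, rng, cfg.bounds)
        state = pso_step(
            state, cfg.q_inertia, cfg.w1, cfg.w2, fitness_fn, cfg.bounds,
            rng=rng, stochastic=cfg.stochastic_pso,
        )
        improved = state.fitness < before
        state.trial_counters[improved] = 0
        state.trial_counters[~improved] += 1
        state = abc_scout_step(state, cfg.limit, cfg.bounds, rng, fitness_fn)
        history.append(state.elite_value)
    return state.elite_position, state.elite_value, np.asarray(history)


# ---------------------------------------------------------------------------
# Feature-subset encoding and fitness
# ---------------------------------------------------------------------------

def position_to_mask(position: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Decode a continuous position into a feature mask: feature j selected
    iff sigmoid(position_j) > threshold (strict).  An empty mask falls back
    to the single highest-scoring feature."""
    position = np.asarray(position, dtype=float)
    score = 1.0 / (1.0 + np.exp(-position))
    mask = score > threshold
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(score))] = True
    return mask


def subset_fitness(
    mask: np.ndarray,
    features: np.ndarray,
    labels: np.ndarray,
    lam: float = 0.01,
    n_splits: int = 5,
    seed: int = 0,
) -> float:
    """Fitness (minimised) of a feature subset: 1 - balanced accuracy of a
    nearest-centroid classifier under stratified CV, plus lam * fraction of
    features selected."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 1:
        raise ValueError("mask must select at least one feature")
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("subset fitness needs at least two classes")
    X = np.asarray(features, dtype=float)[:, mask]
    n_splits = min(n_splits, int(counts.min()))
    if n_splits < 2:
        raise ValueError("not enough members per class for internal CV")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    preds = np.empty_like(labels)
    for tr, te in skf.split(X, labels):
        clf = NearestCentroid()
        clf.fit(X[tr], labels[tr])
        preds[te] = clf.predict(X[te])
    bal = balanced_accuracy_score(labels, preds)
    return float(1.0 - bal + lam * mask.sum() / mask.size)


def select_features(
    features: np.ndarray,
    labels: np.ndarray,
    NP: int = 16,
    max_iter: int = 20,
    lam: float = 0.01,
    threshold: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """HDPAB wrapper feature selection.

    Optimizes continuous positions in [-4, 4]^d whose sigmoid decoding
    defines the subset; returns (boolean mask, elite history).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    d = features.shape[1]
    config = HDPABConfig(
        NP=NP, dims=d, bounds=(np.full(d, -4.0), np.full(d, 4.0)),
        max_iter=max_iter, seed=seed,
    )

    def fitness(position: np.ndarray) -> float:
        mask = position_to_mask(position, threshold)
        return subset_fitness(mask, features, labels, lam=lam, seed=seed)

    best_pos, _, history = hdpab_optimize(fitness, config)
    return position_to_mask(best_pos, threshold), history
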