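"""Binary particle swarm optimisation over selection masks.

Particles are 0/1 vectors; a set bit means "use this channel/feature".
Velocities follow the classic two-attractor update with a linearly
decreasing inertia weight and boundary absorption at +-v_max; positions are
resampled through a sigmoid transfer, P(bit = 1) = s(v).  The optimiser is
elitist: personal and global bests only ever improve, so the gbest fitness
trace is non-decreasing.

The wrapper fitness used for selection is the inverse squared error of the
discriminant's thresholded predictions on held-out evaluation trials; with
+-1 coding each misclassified trial contributes (+-2)^2 = 4, so k errors
give fitness 1 / (4 k + eps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .blda import BayesianDiscriminant
from .containers import FeatureMatrix

__all__ = [
    "PSOConfig",
    "SwarmState",
    "PSOResult",
    "inertia_weight",
    "initialize_swarm",
    "update_velocity",
    "update_position_binary",
    "mse_inverse_fitness",
    "run_pso",
]

log = logging.getLogger(__name__)


@dataclass
class PSOConfig:
    """Swarm hyperparameters.

    Defaults are the tuned operating point for this problem family:
    N = 100 particles, T = 100 iterations, c1 = c2 = 1.5, inertia decreasing
    linearly from 0.8 to 0.4, velocities clamped to +-20.
    """

    n_particles: int = 100
    n_iterations: int = 100
    c1: float = 1.5
    c2: float = 1.5
    w_max: float = 0.8
    w_min: float = 0.4
    v_max: float = 20.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.n_iterations < 1:
            raise ValueError("need at least 1 iteration")
        if not (self.c1 > 0 and self.c2 > 0):
            raise ValueError("acceleration coefficients must be positive")
        if not (self.w_max >= self.w_min > 0):
            raise ValueError("require w_max >= w_min > 0")
        if not self.v_max > 0:
            raise ValueError("v_max must be positive")


def inertia_weight(t: int, cfg: PSOConfig) -> float:
    """Linearly decreasing inertia: w_max at t = 0, w_min at t = T."""
    if not 0 <= t <= cfg.n_iterations:
        raise ValueError("iteration index out of range")
    return cfg.w_max - (cfg.w_max - cfg.w_min) * t / cfg.n_iterations


@dataclass
class SwarmState:
    """Positions, velocities and best-so-far bookkeeping for one run."""

    positions: np.ndarray  # (N, D) uint8 in {0, 1}
    velocities: np.ndarray  # (N, D) float in [-v_max, v_max]
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray  # (N,)
    gbest_position: np.ndarray  # (D,)
    gbest_fitness: float
    iteration: int = 0

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def dimension(self) -> int:
        return self.positions.shape[1]


def _check_fitness_values(values: np.ndarray) -> None:
    # -inf is the sentinel for an empty/degenerate mask and is allowed
    if np.any(np.isnan(values)) or np.any(values == np.inf):
        raise ValueError(
            "fitness function returned NaN or +inf; fix the fitness before optimising"
        )


def _evaluate_all(positions: np.ndarray, fitness) -> np.ndarray:
    out = np.empty(positions.shape[0])
    for i, pos in enumerate(positions):
        out[i] = -np.inf if not pos.any() else float(fitness(pos.astype(bool)))
    _check_fitness_values(out)
    return out


def _better(
    fit_new: float,
    pop_new: int,
    fit_old: float,
    pop_old: int,
    perfect: float = np.inf,
) -> bool:
    """Elitist comparison.

    Ties are broken toward fewer selected bits only at or above the
    ``perfect`` fitness level (a mask that already predicts every evaluation
    trial correctly cannot be improved, so the smaller of two perfect masks
    wins); below it, ties keep the incumbent.
    """
    if fit_new > fit_old:
        return True
    return fit_new == fit_old and fit_new >= perfect and pop_new < pop_old


def initialize_swarm(
    d: int,
    cfg: PSOConfig,
    fitness=None,
    rng: np.random.Generator | None = None,
    perfect_fitness: float = np.inf,
) -> SwarmState:
    """Bernoulli(0.5) positions, uniform velocities, bests from the start.

    Without a fitness function, best fitnesses are -inf placeholders and the
    first particle seeds gbest.
    """
    if d < 1:
        raise ValueError("dimension must be at least 1")
    rng = rng or np.random.default_rng(cfg.seed)
    positions = (rng.random((cfg.n_particles, d)) < 0.5).astype(np.uint8)
    velocities = rng.uniform(-cfg.v_max, cfg.v_max, size=(cfg.n_particles, d))
    if fitness is not None:
        fits = _evaluate_all(positions, fitness)
    else:
        fits = np.full(cfg.n_particles, -np.inf)
    best = 0
    pops = positions.sum(axis=1)
    for i in range(1, cfg.n_particles):
        if _better(fits[i], pops[i], fits[best], pops[best], perfect_fitness):
            best = i
    return SwarmState(
        positions=positions,
        velocities=velocities,
        pbest_positions=positions.copy(),
        pbest_fitness=fits,
        gbest_position=positions[best].copy(),
        gbest_fitness=float(fits[best]),
    )


def update_velocity(
    state: SwarmState,
    cfg: PSOConfig,
    rng: np.random.Generator,
    t: int | None = None,
) -> SwarmState:
    """v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x), clamped to +-v_max."""
    t = state.iteration if t is None else t
    w = inertia_weight(min(t, cfg.n_iterations), cfg)
    shape = state.velocities.shape
    r1 = rng.random(shape)
    r2 = rng.random(shape)
    x = state.positions.astype(np.float64)
    v = (
        w * state.velocities
        + cfg.c1 * r1 * (state.pbest_positions - x)
        + cfg.c2 * r2 * (state.gbest_position - x)
    )
    np.clip(v, -cfg.v_max, cfg.v_max, out=v)  # boundary absorption
    state.velocities = v
    return state


def update_position_binary(state: SwarmState, rng: np.random.Generator) -> SwarmState:
    """Resample every bit: P(bit = 1) = sigmoid(velocity)."""
    r = rng.random(state.velocities.shape)
    state.positions = (r < expit(state.velocities)).astype(np.uint8)
    return state


@dataclass
class PSOResult:
    """Best mask found, its fitness, and the per-iteration gbest trace."""

    mask: np.ndarray  # (D,) uint8
    fitness: float
    trace: np.ndarray  # (T + 1,) gbest fitness after init and each iteration
    n_evaluations: int
    popcount_trace: np.ndarray = None  # (T + 1,) gbest popcount per iteration
    state: SwarmState = field(repr=False, default=None)


def run_pso(
    d: int,
    cfg: PSOConfig,
    fitness,
    rng: np.random.Generator | None = None,
    perfect_fitness: float = np.inf,
) -> PSOResult:
    """Full synchronous binary-PSO run.

    Each iteration updates all velocities against the previous gbest, then
    all positions, then fitnesses, then the pbest/gbest records.
    ``perfect_fitness`` marks the fitness level at which ties are broken
    toward smaller masks (see :func:`mse_inverse_fitness`: 1/eps).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    state = initialize_swarm(d, cfg, fitness=fitness, rng=rng, perfect_fitness=perfect_fitness)
    n_evals = cfg.n_particles
    trace = [state.gbest_fitness]
    gbest_pop = int(state.gbest_position.sum())
    pop_trace = [gbest_pop]
    pbest_pops = state.pbest_positions.sum(axis=1)

    for t in range(cfg.n_iterations):
        update_velocity(state, cfg, rng, t=t)
        update_position_binary(state, rng)
        fits = _evaluate_all(state.positions, fitness)
        n_evals += cfg.n_particles
        pops = state.positions.sum(axis=1)
        for i in range(cfg.n_particles):
            if _better(
                fits[i], pops[i], state.pbest_fitness[i], pbest_pops[i], perfect_fitness
            ):
                state.pbest_fitness[i] = fits[i]
                state.pbest_positions[i] = state.positions[i]
                pbest_pops[i] = pops[i]
            if _better(
                state.pbest_fitness[i],
                pbest_pops[i],
                state.gbest_fitness,
                gbest_pop,
                perfect_fitness,
            ):
                state.gbest_fitness = float(state.pbest_fitness[i])
                state.gbest_position = state.pbest_positions[i].copy()
                gbest_pop = int(pbest_pops[i])
        state.iteration = t + 1
        trace.append(state.gbest_fitness)
        pop_trace.append(gbest_pop)

    return PSOResult(
        mask=state.gbest_position.copy(),
        fitness=state.gbest_fitness,
        trace=np.asarray(trace),
        n_evaluations=n_evals,
        popcount_trace=np.asarray(pop_trace),
        state=state,
    )


def mse_inverse_fitness(
    mask,
    train: FeatureMatrix,
    eval_: FeatureMatrix,
    *,
    epsilon: float = 1e-12,
    use_scores: bool = False,
    standardize: bool = True,
    target_coding: str = "label",
) -> float:
    """Wrapper fitness: 1 / (sum squared prediction error on eval + eps).

    Fits the Bayesian discriminant on the masked training columns and scores
    the masked evaluation columns.  By default predictions are the
    thresholded +-1 labels, so k evaluation errors give fitness
    ~ 1 / (4 k); a perfect mask caps at 1 / eps.  A degenerate training
    split (e.g. one class) yields -inf, the worst possible fitness.
    """
    cols = np.asarray(mask, dtype=bool)
    if cols.shape != (train.n_features,):
        raise ValueError("mask length must equal the number of feature columns")
    if not cols.any():
        return -np.inf
    try:
        res = BayesianDiscriminant(
            train.labels,
            train.values[:, cols],
            standardize=standardize,
            target_coding=target_coding,
        ).fit()
    except (ValueError, np.linalg.LinAlgError) as exc:
        log.warning("degenerate training split during fitness evaluation: %s", exc)
        return -np.inf
    pred = res.predict(eval_.values[:, cols]) if use_scores else res.classify(
        eval_.values[:, cols]
    )
    err = float(np.sum((pred - eval_.labels) ** 2))
    return 1.0 / (err + epsilon)
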