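"""Swarm optimizers over a bounded box: PSO, cuckoo search, and hybrid CS-PSO.

All three methods maximize a user-supplied fitness function over a
``D``-dimensional box (for SVM tuning, ``D = 2``: ``log2 C`` and
``log2 gamma``). They share one swarm representation and one seeded random
stream, so runs are exactly reproducible from ``(config, seed)``.

Particle swarm (PSO)
    ``v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x)``, ``x <- x + v``,
    with ``r1, r2 ~ U(0,1)`` drawn per particle per dimension. The update
    carries no inertia damping by default (``w = 1``); velocities are
    clamped to ``velocity_clamp_fraction * (upper - lower)`` to keep the
    undamped swarm stable.

Cuckoo search (CS)
    Each nest proposes a global-walk candidate by a Levy flight
    (``x + alpha * L(s, lambda)``, Mantegna generator) that greedily
    replaces a randomly chosen nest if better; then a fraction ``pa`` of
    coordinates take a local walk ``x + N(0,1) * (x_j - x_k)`` over random
    permutations ``j, k`` of the nests, accepted greedily.

Hybrid CS-PSO (``interleaved`` strategy, the default)
    Each generation: (1) the PSO update; (2) a Levy-flight perturbation of
    every particle with greedy acceptance; (3) abandonment of the worst
    ``ceil(pa * P)`` particles, re-seeded by the local walk with velocities
    reset to zero. A ``sequential`` strategy (CS for the first half of the
    budget, PSO warm-started from the nests for the second) is available via
    ``OptimizerConfig.hybrid_strategy``.

Random-stream discipline: a stage that is switched off by its parameter
(``levy_alpha_scale = 0`` or ``pa = 0``) consumes no random numbers, so the
hybrid with both off reproduces plain PSO bit for bit.

Positions are always clipped to the box after every move; the best-so-far
fitness is nondecreasing by construction (personal-best memory).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .data import InvalidConfig, InvalidMethod, NonFiniteFitness

__all__ = [
    "SearchBounds",
    "OptimizerConfig",
    "SwarmState",
    "OptimizeResult",
    "init_state",
    "pso_step",
    "levy_samples",
    "levy_flight_step",
    "cs_local_walk",
    "cs_iteration",
    "hybrid_cspso_iteration",
    "optimize",
    "DEFAULT_SVM_BOUNDS",
]

FitnessFunction = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class SearchBounds:
    """Elementwise box ``lower < upper`` for the search space."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise InvalidConfig("bounds must be 1-D vectors of equal length")
        if not np.all(self.lower < self.upper):
            raise InvalidConfig("lower bounds must be strictly below upper bounds")

    @property
    def dim(self) -> int:
        return self.lower.shape[0]

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


#: Standard RBF-SVM search box: log2(C) in [-5, 15], log2(gamma) in [-15, 3].
DEFAULT_SVM_BOUNDS = SearchBounds(
    lower=np.array([-5.0, -15.0]), upper=np.array([15.0, 3.0])
)


@dataclass(frozen=True)
class OptimizerConfig:
    """Swarm settings; defaults are the reference operating point
    (population 18, 120 iterations, c1 = 1.3, c2 = 1.87, pa = 0.262)."""

    population: int = 18
    iterations: int = 120
    c1: float = 1.3
    c2: float = 1.87
    pa: float = 0.262
    levy_lambda: float = 1.5
    levy_alpha_scale: float = 0.01
    seed: int = 0
    velocity_clamp_fraction: float = 0.5
    inertia: float = 1.0
    hybrid_strategy: str = "interleaved"

    def __post_init__(self) -> None:
        if self.population < 1:
            raise InvalidConfig("population must be >= 1")
        if self.iterations < 0:
            raise InvalidConfig("iterations must be >= 0")
        if not 0.0 <= self.pa <= 1.0:
            raise InvalidConfig("pa must lie in [0, 1]")
        if not 1.0 < self.levy_lambda <= 2.0:
            raise InvalidConfig("levy_lambda must lie in (1, 2]")
        if self.levy_alpha_scale < 0:
            raise InvalidConfig("levy_alpha_scale must be >= 0")
        if self.c1 < 0 or self.c2 < 0:
            raise InvalidConfig("c1 and c2 must be nonnegative")
        if self.velocity_clamp_fraction <= 0:
            raise InvalidConfig("velocity_clamp_fraction must be > 0")
        if self.hybrid_strategy not in ("interleaved", "sequential"):
            raise InvalidConfig("hybrid_strategy must be interleaved|sequential")


@dataclass
class SwarmState:
    """Positions, velocities and best-so-far memory of one swarm."""

    positions: np.ndarray
    velocities: np.ndarray
    fitnesses: np.ndarray
    pbest_positions: np.ndarray
    pbest_fitnesses: np.ndarray
    gbest_position: np.ndarray
    gbest_fitness: float
    bounds: SearchBounds
    iteration: int = 0


def _evaluate(f: FitnessFunction, X: np.ndarray) -> np.ndarray:
    vals = np.array([float(f(x)) for x in np.atleast_2d(X)])
    if not np.all(np.isfinite(vals)):
        raise NonFiniteFitness("fitness returned a non-finite value")
    return vals


def _lex_smaller(a: np.ndarray, b: np.ndarray) -> bool:
    for ai, bi in zip(a, b):
        if ai != bi:
            return ai < bi
    return False


def _refresh_memory(state: SwarmState) -> None:
    """Update personal bests and the global best (ties broken toward the
    lexicographically smaller position, i.e. smaller C then smaller gamma)."""
    improved = state.fitnesses > state.pbest_fitnesses
    state.pbest_positions[improved] = state.positions[improved]
    state.pbest_fitnesses[improved] = state.fitnesses[improved]
    i = int(np.argmax(state.pbest_fitnesses))
    best, pos = state.pbest_fitnesses[i], state.pbest_positions[i]
    if best > state.gbest_fitness or (
        best == state.gbest_fitness and _lex_smaller(pos, state.gbest_position)
    ):
        state.gbest_fitness = float(best)
        state.gbest_position = pos.copy()


def init_state(
    bounds: SearchBounds,
    cfg: OptimizerConfig,
    f: FitnessFunction,
    rng: np.random.Generator,
) -> SwarmState:
    """Uniform random positions in the box; velocities uniform within the clamp."""
    P, D = cfg.population, bounds.dim
    vmax = cfg.velocity_clamp_fraction * bounds.range
    X = rng.uniform(bounds.lower, bounds.upper, size=(P, D))
    V = rng.uniform(-vmax, vmax, size=(P, D))
    fit = _evaluate(f, X)
    i = int(np.argmax(fit))
    return SwarmState(
        positions=X,
        velocities=V,
        fitnesses=fit,
        pbest_positions=X.copy(),
        pbest_fitnesses=fit.copy(),
        gbest_position=X[i].copy(),
        gbest_fitness=float(fit[i]),
        bounds=bounds,
        iteration=0,
    )


def pso_step(
    state: SwarmState,
    cfg: OptimizerConfig,
    f: FitnessFunction,
    rng: np.random.Generator,
) -> SwarmState:
    """One PSO generation: velocity and position update, then memory refresh."""
    P, D = state.positions.shape
    vmax = cfg.velocity_clamp_fraction * state.bounds.range
    r1 = rng.uniform(size=(P, D))
    r2 = rng.uniform(size=(P, D))
    state.velocities = (
        cfg.inertia * state.velocities
        + cfg.c1 * r1 * (state.pbest_positions - state.positions)
        + cfg.c2 * r2 * (state.gbest_position[None, :] - state.positions)
    )
    np.clip(state.velocities, -vmax, vmax, out=state.velocities)
    state.positions = state.bounds.clip(state.positions + state.velocities)
    state.fitnesses = _evaluate(f, state.positions)
    _refresh_memory(state)
    state.iteration += 1
    return state


# --------------------------------------------------------------------------
# Levy flights (Mantegna generator)

def levy_samples(
    shape: tuple[int, ...] | int, lam: float, rng: np.random.Generator
) -> np.ndarray:
    """Heavy-tailed Levy steps of index ``lam`` via Mantegna's algorithm:
    ``L = u / |v|^(1/lam)`` with ``u ~ N(0, sigma_u^2)``, ``v ~ N(0, 1)``.
    ``P(|L| > s)`` decays like ``s^-lam`` for large ``s``."""
    sigma_u = (
        math.gamma(1.0 + lam)
        * math.sin(math.pi * lam / 2.0)
        / (math.gamma((1.0 + lam) / 2.0) * lam * 2.0 ** ((lam - 1.0) / 2.0))
    ) ** (1.0 / lam)
    u = rng.normal(0.0, sigma_u, size=shape)
    v = rng.normal(0.0, 1.0, size=shape)
    return u / np.abs(v) ** (1.0 / lam)


def levy_flight_step(
    x: np.ndarray,
    bounds: SearchBounds,
    cfg: OptimizerConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Global random walk ``x + alpha * L``, clipped to the box.

    ``alpha`` scales with the box: ``levy_alpha_scale * (upper - lower)``
    per dimension. With ``levy_alpha_scale = 0`` the input is returned
    unchanged and no random numbers are consumed.
    """
    x = np.asarray(x, dtype=float)
    if cfg.levy_alpha_scale == 0.0:
        return x.copy()
    alpha = cfg.levy_alpha_scale * bounds.range
    L = levy_samples(x.shape, cfg.levy_lambda, rng)
    return bounds.clip(x + alpha * L)


def cs_local_walk(
    positions: np.ndarray,
    bounds: SearchBounds,
    cfg: OptimizerConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Abandonment walk: each coordinate is, with probability ``pa``,
    displaced by ``N(0,1) * (x_j - x_k)`` where ``j, k`` are random
    permutations of the swarm (offset so that ``j != k`` rowwise).

    With ``pa = 0`` positions are returned unchanged and no random numbers
    are consumed; with ``pa = 1`` every coordinate is perturbed.
    """
    X = np.asarray(positions, dtype=float)
    P, D = X.shape
    if cfg.pa == 0.0:
        return X.copy()
    if P < 2:
        return X.copy()
    gate = rng.uniform(size=(P, D)) < cfg.pa  # Heaviside(pa - eps)
    perm_j = rng.permutation(P)
    shift = int(rng.integers(1, P))
    perm_k = perm_j[(np.arange(P) + shift) % P]  # rowwise j != k, still uniform
    scale = rng.normal(size=(P, D))
    step = scale * (X[perm_j] - X[perm_k])
    return bounds.clip(X + gate * step)


def cs_iteration(
    state: SwarmState,
    cfg: OptimizerConfig,
    f: FitnessFunction,
    rng: np.random.Generator,
) -> SwarmState:
    """One cuckoo-search generation.

    Phase 1 (global walk): every nest emits a Levy-flight candidate that is
    compared against a *randomly chosen* nest and replaces it if strictly
    better. Phase 2 (local walk): the ``pa``-gated permutation walk, accepted
    nest-by-nest only when it improves. The best nest ever seen is retained
    in the state's memory.
    """
    P = state.positions.shape[0]
    candidates = levy_flight_step(state.positions, state.bounds, cfg, rng)
    cand_fit = _evaluate(f, candidates)
    targets = rng.integers(0, P, size=P)
    for i in range(P):
        j = int(targets[i])
        if cand_fit[i] > state.fitnesses[j]:
            state.positions[j] = candidates[i]
            state.fitnesses[j] = cand_fit[i]
    walked = cs_local_walk(state.positions, state.bounds, cfg, rng)
    changed = np.any(walked != state.positions, axis=1)
    if changed.any():
        new_fit = _evaluate(f, walked[changed])
        idx = np.flatnonzero(changed)
        better = new_fit > state.fitnesses[idx]
        state.positions[idx[better]] = walked[idx[better]]
        state.fitnesses[idx[better]] = new_fit[better]
    _refresh_memory(state)
    state.iteration += 1
    return state


def hybrid_cspso_iteration(
    state: SwarmState,
    cfg: OptimizerConfig,
    f: FitnessFunction,
    rng: np.random.Generator,
) -> SwarmState:
    """One interleaved hybrid generation: PSO update, then a greedy
    Levy-flight perturbation of each particle, then abandonment of the
    worst ``ceil(pa * P)`` particles (velocities reset to zero)."""
    pso_step(state, cfg, f, rng)
    P = state.positions.shape[0]
    if cfg.levy_alpha_scale > 0.0:
        candidates = levy_flight_step(state.positions, state.bounds, cfg, rng)
        cand_fit = _evaluate(f, candidates)
        better = cand_fit > state.fitnesses
        state.positions[better] = candidates[better]
        state.fitnesses[better] = cand_fit[better]
        _refresh_memory(state)
    n_abandon = math.ceil(cfg.pa * P) if cfg.pa > 0.0 else 0
    if n_abandon > 0 and P >= 2:
        worst = np.argsort(state.fitnesses, kind="stable")[:n_abandon]
        perm_j = rng.permutation(P)
        shift = int(rng.integers(1, P))
        perm_k = perm_j[(np.arange(P) + shift) % P]
        scale = rng.normal(size=(P, state.positions.shape[1]))
        fresh = state.bounds.clip(
            state.positions + scale * (state.positions[perm_j] - state.positions[perm_k])
        )
        state.positions[worst] = fresh[worst]
        state.velocities[worst] = 0.0
        state.fitnesses[worst] = _evaluate(f, state.positions[worst])
        _refresh_memory(state)
    return state


@dataclass
class OptimizeResult:
    """Best point found plus the per-generation convergence trace."""

    best_position: np.ndarray
    best_fitness: float
    history: list[dict] = field(default_factory=list)
    state: SwarmState | None = None


_STEPPERS = {
    "pso": pso_step,
    "cs": cs_iteration,
    "cspso": hybrid_cspso_iteration,
}


def optimize(
    method: str,
    f: FitnessFunction,
    bounds: SearchBounds,
    cfg: OptimizerConfig,
) -> OptimizeResult:
    """Run a full optimization: seeded initialization plus ``iterations``
    generations of the chosen method (``pso`` | ``cs`` | ``cspso``).

    The history records, per generation, the best fitness so far and the
    population's mean (current) fitness. With ``iterations = 0`` only the
    random initial population is evaluated.
    """
    if method not in _STEPPERS:
        raise InvalidMethod(f"method must be one of {sorted(_STEPPERS)}, got {method!r}")
    rng = np.random.default_rng(cfg.seed)
    state = init_state(bounds, cfg, f, rng)
    history = [
        {
            "iteration": 0,
            "best_fitness": state.gbest_fitness,
            "mean_fitness": float(state.fitnesses.mean()),
        }
    ]
    if method == "cspso" and cfg.hybrid_strategy == "sequential":
        n_cs = cfg.iterations // 2
        schedule = [cs_iteration] * n_cs + [pso_step] * (cfg.iterations - n_cs)
    else:
        schedule = [_STEPPERS[method]] * cfg.iterations
    for stepper in schedule:
        stepper(state, cfg, f, rng)
        history.append(
            {
                "iteration": state.iteration,
                "best_fitness": state.gbest_fitness,
                "mean_fitness": float(state.fitnesses.mean()),
            }
        )
    return OptimizeResult(
        best_position=state.gbest_position.copy(),
        best_fitness=state.gbest_fitness,
        history=history,
        state=state,
    )
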