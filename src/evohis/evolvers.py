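"""Population metaheuristics over a bounded real box: PSO, GSA and FA.

All three maximize a supplied fitness function.  The fitness callable may
return either a bare float or a ``(float, aux)`` tuple; the auxiliary
payload (e.g. an objective vector) is stored alongside each archived
evaluation.  Best-ever elitism is tracked outside the swarm state, so
``fitness_history`` is always nondecreasing even for the memoryless
algorithms (GSA, FA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EvaluationError

__all__ = [
    "ParameterSpec",
    "PSOSettings",
    "GSASettings",
    "FASettings",
    "EvolverConfig",
    "ArchiveEntry",
    "OptimizationResult",
    "clip_to_bounds",
    "gsa_masses",
    "pso_optimize",
    "gsa_optimize",
    "fa_optimize",
    "EVOLVERS",
]


@dataclass(frozen=True)
class ParameterSpec:
    """A named tunable with box bounds [lower, upper]."""

    name: str
    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError(f"{self.name}: lower {self.lower} > upper {self.upper}")


@dataclass(frozen=True)
class PSOSettings:
    inertia: float = 0.729
    c1: float = 1.49445
    c2: float = 1.49445


@dataclass(frozen=True)
class GSASettings:
    # G0 is scaled for unit-box search spaces; larger values saturate the
    # bound clamp and the slower decay keeps forces alive over short runs
    g0: float = 1.0
    decay_rate: float = 5.0
    epsilon: float = 1e-10
    kbest_final: int = 1


@dataclass(frozen=True)
class FASettings:
    beta0: float = 1.0
    gamma: float = 1.0
    alpha: float = 0.2
    exponent: float = 2.0


@dataclass(frozen=True)
class EvolverConfig:
    n_agents: int = 20
    n_iterations: int = 50
    seed: int = 0
    pso: PSOSettings = field(default_factory=PSOSettings)
    gsa: GSASettings = field(default_factory=GSASettings)
    fa: FASettings = field(default_factory=FASettings)
    #: optional positions injected into the initial population (e.g. a
    #: classifier's default parameter vector), clipped to bounds
    initial_positions: tuple = ()

    def __post_init__(self):
        if self.n_agents < 1 or self.n_iterations < 1:
            raise ValueError("n_agents and n_iterations must be positive")


@dataclass(frozen=True)
class ArchiveEntry:
    iteration: int
    agent: int
    position: np.ndarray
    fitness: float
    aux: object = None


@dataclass(frozen=True)
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    fitness_history: np.ndarray  # best-so-far after init and each iteration
    evaluation_archive: tuple  # of ArchiveEntry


def clip_to_bounds(position: np.ndarray, space) -> np.ndarray:
    """Componentwise clamp of a position into the box defined by ``space``."""
    lo = np.array([p.lower for p in space], dtype=float)
    hi = np.array([p.upper for p in space], dtype=float)
    return np.clip(np.asarray(position, dtype=float), lo, hi)


class _Tracker:
    """Evaluates fitness, archives every call, and tracks the best-ever."""

    def __init__(self, fitness):
        self._fitness = fitness
        self.archive = []
        self.best_position = None
        self.best_fitness = -math.inf
        self.history = []

    def evaluate(self, position, iteration, agent):
        out = self._fitness(np.asarray(position, dtype=float))
        if isinstance(out, tuple):
            fit, aux = out
        else:
            fit, aux = out, None
        fit = float(fit)
        if not math.isfinite(fit):
            raise EvaluationError(
                f"non-finite fitness {fit} at position {position}", position=position
            )
        self.archive.append(
            ArchiveEntry(iteration, agent, np.array(position, dtype=float), fit, aux)
        )
        if fit > self.best_fitness:
            self.best_fitness = fit
            self.best_position = np.array(position, dtype=float)
        return fit

    def checkpoint(self):
        self.history.append(self.best_fitness)

    def result(self) -> OptimizationResult:
        return OptimizationResult(
            best_position=self.best_position,
            best_fitness=self.best_fitness,
            fitness_history=np.array(self.history, dtype=float),
            evaluation_archive=tuple(self.archive),
        )


def _bounds(space):
    if not space:
        raise ValueError("search space must be nonempty")
    lo = np.array([p.lower for p in space], dtype=float)
    hi = np.array([p.upper for p in space], dtype=float)
    return lo, hi


def _init_positions(rng, space, cfg):
    lo, hi = _bounds(space)
    pos = lo + rng.random((cfg.n_agents, len(space))) * (hi - lo)
    for k, seeded in enumerate(cfg.initial_positions):
        if k >= cfg.n_agents:
            break
        pos[k] = np.clip(np.asarray(seeded, dtype=float), lo, hi)
    return pos


def gsa_masses(fits: np.ndarray) -> np.ndarray:
    """Normalized gravitational masses from fitnesses (maximization).

    q_i = (fit_i - worst) / (best - worst), M_i = q_i / sum(q); when all
    fitnesses are equal the masses are uniform.  Masses sum to 1.
    """
    fits = np.asarray(fits, dtype=float)
    best, worst = fits.max(), fits.min()
    if best == worst:
        q = np.ones_like(fits)
    else:
        q = (fits - worst) / (best - worst)
    return q / q.sum()


def pso_optimize(fitness, space, cfg: EvolverConfig) -> OptimizationResult:
    """Particle swarm: v <- w*v + c1*r1*(pBest - x) + c2*r2*(gBest - x)."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = _bounds(space)
    s = cfg.pso
    n, d = cfg.n_agents, len(space)
    tracker = _Tracker(fitness)

    x = _init_positions(rng, space, cfg)
    v = np.zeros((n, d))
    fits = np.array([tracker.evaluate(x[i], 0, i) for i in range(n)])
    pbest = x.copy()
    pbest_fit = fits.copy()
    g = int(np.argmax(pbest_fit))
    tracker.checkpoint()

    for t in range(1, cfg.n_iterations + 1):
        r1 = rng.random((n, d))
        r2 = rng.random((n, d))
        v = s.inertia * v + s.c1 * r1 * (pbest - x) + s.c2 * r2 * (pbest[g] - x)
        x = np.clip(x + v, lo, hi)
        for i in range(n):
            fit = tracker.evaluate(x[i], t, i)
            if fit > pbest_fit[i]:
                pbest_fit[i] = fit
                pbest[i] = x[i]
        g = int(np.argmax(pbest_fit))
        tracker.checkpoint()
    return tracker.result()


def gsa_optimize(fitness, space, cfg: EvolverConfig) -> OptimizationResult:
    """Gravitational search with decaying G and a shrinking kbest set.

    Oriented for maximization: best(t) = max fitness, worst(t) = min.
    Acceleration is computed with the agent's own mass cancelled
    (a_i = F_i / M_i), which keeps massless agents well defined.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = _bounds(space)
    s = cfg.gsa
    n, d = cfg.n_agents, len(space)
    T = cfg.n_iterations
    tracker = _Tracker(fitness)

    x = _init_positions(rng, space, cfg)
    v = np.zeros((n, d))
    fits = np.array([tracker.evaluate(x[i], 0, i) for i in range(n)])
    tracker.checkpoint()

    for t in range(1, T + 1):
        masses = gsa_masses(fits)

        g_const = s.g0 * math.exp(-s.decay_rate * t / T)
        if T > 1:
            kbest = int(round(n + (s.kbest_final - n) * (t - 1) / (T - 1)))
        else:
            kbest = n
        kbest = max(kbest, 1)
        heavy = np.argsort(masses)[::-1][:kbest]

        pair_rand = rng.random((n, n))
        accel = np.zeros((n, d))
        for j in heavy:
            diff = x[j] - x  # (n, d)
            dist = np.linalg.norm(diff, axis=1)  # R_ij, Euclidean
            coef = pair_rand[:, j] * g_const * masses[j] / (dist + s.epsilon)
            coef[j] = 0.0  # no self-force
            accel += coef[:, None] * diff

        v = rng.random(n)[:, None] * v + accel
        x = np.clip(x + v, lo, hi)
        fits = np.array([tracker.evaluate(x[i], t, i) for i in range(n)])
        tracker.checkpoint()
    return tracker.result()


def fa_optimize(fitness, space, cfg: EvolverConfig) -> OptimizationResult:
    """Firefly algorithm with sequential (in-sweep) position updates.

    Each firefly moves toward every brighter one by
    ``beta0 * exp(-gamma * r^m) * (x_j - x_i) + alpha * (rand - 0.5)``;
    a firefly with no brighter peer takes the pure random step.
    Brightness equals fitness (maximization).
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = _bounds(space)
    s = cfg.fa
    n, d = cfg.n_agents, len(space)
    tracker = _Tracker(fitness)

    x = _init_positions(rng, space, cfg)
    brightness = np.array([tracker.evaluate(x[i], 0, i) for i in range(n)])
    tracker.checkpoint()

    for t in range(1, cfg.n_iterations + 1):
        for i in range(n):
            moved = False
            for j in range(n):
                if brightness[j] > brightness[i]:
                    r = np.linalg.norm(x[i] - x[j])
                    beta = s.beta0 * math.exp(-s.gamma * r**s.exponent)
                    x[i] = x[i] + beta * (x[j] - x[i]) + s.alpha * (rng.random(d) - 0.5)
                    x[i] = np.clip(x[i], lo, hi)
                    moved = True
            if not moved:
                x[i] = np.clip(x[i] + s.alpha * (rng.random(d) - 0.5), lo, hi)
            brightness[i] = tracker.evaluate(x[i], t, i)
        tracker.checkpoint()
    return tracker.result()


EVOLVERS = {"pso": pso_optimize, "gsa": gsa_optimize, "fa": fa_optimize}
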