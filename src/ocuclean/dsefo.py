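"""Electric Fish Optimization (EFO) and its distance-sorted variant DS-EFO.

EFO is a population metaheuristic modelled on weakly electric fish.  Each
individual carries a *frequency* in [fr_min, fr_max] mapped linearly from its
fitness rank (best fish -> fr_max) and an *amplitude* that is an exponential
moving average of its frequency.  Fish either *actively* electrolocate —
a local random step whose radius is the amplitude-scaled search-box width —
or *passively* follow a reference point built as the amplitude-weighted mean
of a few active fish, an exploratory contraction toward good regions.
A small per-individual probability reinitializes one coordinate uniformly.

The two variants differ only in how the movement mode is selected:

* EFO: fish whose frequency exceeds a uniform draw electrolocate actively
  (higher frequency = closer to the optimum = local search).
* DS-EFO: fish whose distance to the current best is below the population
  mean distance, and that have at least one neighbor inside their active
  range, electrolocate actively; everyone else is passive.

Moves are greedy (accepted only if the objective improves) and the best
solution found is never lost, so the best-fitness trace is nonincreasing.
Minimization convention throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Individual",
    "EFOParams",
    "OptimizationTrace",
    "init_population",
    "update_frequencies",
    "update_amplitudes",
    "active_range",
    "distance",
    "active_move",
    "passive_move",
    "stochastic_reinit",
    "dsefo_select_mode",
    "optimize",
]

Objective = Callable[[np.ndarray], float]

#: number of active individuals averaged into the passive reference point
NK_DEFAULT = 3
_EPS = 1e-12


@dataclass
class Individual:
    position: np.ndarray
    fitness: float
    frequency: float = 0.0
    amplitude: float = 0.0


@dataclass
class EFOParams:
    bounds: np.ndarray  # (d, 2) per-dimension [min, max]
    pop_size: int = 10
    iterations: int = 100
    fr_min: float = 0.0
    fr_max: float = 1.0
    beta: float = 0.5  # amplitude memory weight
    reinit_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.bounds = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if self.bounds.shape[1] != 2:
            raise ValueError("bounds must be (d, 2)")
        if np.any(self.bounds[:, 1] < self.bounds[:, 0]):
            raise ValueError("each bound must satisfy min <= max")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not self.fr_min < self.fr_max:
            raise ValueError("fr_min must be < fr_max")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")

    @property
    def dim(self) -> int:
        return self.bounds.shape[0]

    @property
    def widths(self) -> np.ndarray:
        return self.bounds[:, 1] - self.bounds[:, 0]


@dataclass
class OptimizationTrace:
    best_position: list[np.ndarray] = field(default_factory=list)
    best_fitness: list[float] = field(default_factory=list)
    evaluations: int = 0

    def record(self, position: np.ndarray, fitness: float) -> None:
        self.best_position.append(position.copy())
        self.best_fitness.append(float(fitness))


def _clip(position: np.ndarray, params: EFOParams) -> np.ndarray:
    return np.clip(position, params.bounds[:, 0], params.bounds[:, 1])


def _evaluate(objective: Objective, position: np.ndarray, trace: OptimizationTrace) -> float:
    trace.evaluations += 1
    value = float(objective(position))
    return value


def init_population(
    params: EFOParams, objective: Objective, rng: np.random.Generator,
    trace: OptimizationTrace | None = None,
) -> list[Individual]:
    """Uniform seeding within the box: x = x_min + u * (x_max - x_min)."""
    trace = trace if trace is not None else OptimizationTrace()
    pop = []
    for _ in range(params.pop_size):
        u = rng.uniform(0.0, 1.0, size=params.dim)
        pos = params.bounds[:, 0] + u * params.widths
        pop.append(Individual(position=pos, fitness=_evaluate(objective, pos, trace)))
    return pop


def update_frequencies(population: Sequence[Individual], params: EFOParams) -> None:
    """Linear fitness-to-frequency map: best -> fr_max, worst -> fr_min.

    When all fitness values coincide every frequency is set to fr_max
    (all fish are equally close to the best known source).
    """
    fits = np.array([ind.fitness for ind in population])
    worst, best = fits.max(), fits.min()
    span = params.fr_max - params.fr_min
    if worst == best:
        for ind in population:
            ind.frequency = params.fr_max
        return
    for ind in population:
        ind.frequency = params.fr_min + (worst - ind.fitness) / (worst - best) * span


def update_amplitudes(
    population: Sequence[Individual], params: EFOParams, first: bool = False
) -> None:
    """EMA of the frequency: amp_t = beta * amp_{t-1} + (1 - beta) * fr_t."""
    for ind in population:
        if first:
            ind.amplitude = ind.frequency
        else:
            ind.amplitude = params.beta * ind.amplitude + (1 - params.beta) * ind.frequency


def active_range(ind: Individual, params: EFOParams) -> float:
    """Mean box width scaled by the individual's amplitude."""
    return float(np.mean(params.widths) * ind.amplitude)


def distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def active_move(
    ind: Individual,
    neighbors_in_range: Sequence[Individual],
    params: EFOParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Local probe around a sensed neighbor.

    A neighbor inside the active range is picked uniformly and each
    coordinate moves by ``U(-2, 2)`` times the separation along that
    coordinate — the fish probes the region up to twice the sensed
    separation, on either side, so the step size adapts to the local
    population spread (per-coordinate displacement is bounded by twice the
    active range).  Without any sensed neighbor the move degenerates to an
    isotropic random step of radius equal to the active range.
    """
    if len(neighbors_in_range) > 0:
        k = int(rng.integers(len(neighbors_in_range)))
        diff = neighbors_in_range[k].position - ind.position
        step = rng.uniform(-2.0, 2.0, size=params.dim) * diff
    else:
        ar = active_range(ind, params)
        step = rng.uniform(-1.0, 1.0, size=params.dim) * ar
    return _clip(ind.position + step, params)


def neighbors_within_range(
    ind: Individual, population: Sequence[Individual], params: EFOParams
) -> list[Individual]:
    """Other individuals within ``ind``'s active electrolocation range."""
    ar = active_range(ind, params)
    return [
        other
        for other in population
        if other is not ind and distance(ind.position, other.position) <= ar
    ]


def passive_move(
    ind: Individual,
    active_set: Sequence[Individual],
    params: EFOParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Step toward the amplitude-weighted reference of sensed active fish.

    Up to ``NK_DEFAULT`` active individuals are drawn with probability
    proportional to amplitude / distance; the reference is their
    amplitude-weighted mean position and the move interpolates toward it with
    per-coordinate U(0, 1) weights.  An empty active set falls back to an
    active move.
    """
    if len(active_set) == 0:
        return active_move(ind, [], params, rng)
    amps = np.array([a.amplitude for a in active_set])
    dists = np.array([distance(ind.position, a.position) for a in active_set])
    weights = amps / (dists + _EPS)
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    weights = weights / weights.sum()
    nk = min(NK_DEFAULT, len(active_set))
    chosen = rng.choice(len(active_set), size=nk, replace=False, p=weights)
    sel_amps = amps[chosen]
    sel_pos = np.array([active_set[i].position for i in chosen])
    denom = sel_amps.sum()
    if denom <= 0:
        reference = sel_pos.mean(axis=0)
    else:
        reference = (sel_amps[:, None] * sel_pos).sum(axis=0) / denom
    delta = rng.uniform(0.0, 1.0, size=params.dim)
    return _clip(ind.position + delta * (reference - ind.position), params)


def stochastic_reinit(
    position: np.ndarray, params: EFOParams, rng: np.random.Generator
) -> np.ndarray:
    """With probability ``reinit_prob``, resample one random coordinate."""
    pos = np.array(position, copy=True)
    if rng.uniform() <= params.reinit_prob:
        q = rng.integers(params.dim)
        pos[q] = params.bounds[q, 0] + rng.uniform() * params.widths[q]
    return pos


def dsefo_select_mode(
    ind: Individual,
    population: Sequence[Individual],
    best: Individual,
    params: EFOParams,
) -> str:
    """DS-EFO mode rule: close-to-best fish with a neighbor in range are active."""
    dists = np.array([distance(p.position, best.position) for p in population])
    mean_dist = dists.mean()
    d_ind = distance(ind.position, best.position)
    if d_ind < mean_dist and neighbors_within_range(ind, population, params):
        return "active"
    return "passive"


def _efo_select_mode(ind: Individual, rng: np.random.Generator) -> str:
    """Plain EFO: higher-frequency fish electrolocate actively."""
    return "active" if ind.frequency > rng.uniform() else "passive"


def optimize(
    objective: Objective,
    params: EFOParams,
    variant: str = "ds-efo",
    mode_override: str | None = None,
) -> tuple[np.ndarray, float, OptimizationTrace]:
    """Run EFO or DS-EFO on a bounded minimization problem.

    One candidate is evaluated per individual per iteration (greedy
    acceptance), so the evaluation budget is exactly
    ``pop_size + pop_size * iterations``.  Non-finite objective values reject
    the candidate with a warning.  ``mode_override`` forces every individual
    into one mode ("active"/"passive"); with "active" both variants follow
    the identical update law.
    """
    variant = variant.lower().replace("_", "-")
    if variant not in {"efo", "ds-efo"}:
        raise ValueError(f"unknown variant {variant!r}")
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    trace = OptimizationTrace()
    pop = init_population(params, objective, rng, trace)

    best = min(pop, key=lambda i: i.fitness)
    best_pos, best_fit = best.position.copy(), best.fitness
    trace.record(best_pos, best_fit)

    update_frequencies(pop, params)
    update_amplitudes(pop, params, first=True)

    for _ in range(params.iterations):
        current_best = min(pop, key=lambda i: i.fitness)
        active_set = []
        modes = []
        for ind in pop:
            if mode_override is not None:
                mode = mode_override
            elif variant == "ds-efo":
                mode = dsefo_select_mode(ind, pop, current_best, params)
            else:
                mode = _efo_select_mode(ind, rng)
            modes.append(mode)
            if mode == "active":
                active_set.append(ind)

        for ind, mode in zip(pop, modes):
            if mode == "active":
                candidate = active_move(
                    ind, neighbors_within_range(ind, pop, params), params, rng
                )
            else:
                candidate = passive_move(ind, active_set, params, rng)
            candidate = stochastic_reinit(candidate, params, rng)
            candidate = _clip(candidate, params)
            value = _evaluate(objective, candidate, trace)
            if not np.isfinite(value):
                warnings.warn("objective returned a non-finite value; candidate rejected")
                continue
            if value < ind.fitness:  # greedy acceptance
                ind.position = candidate
                ind.fitness = value
                if value < best_fit:
                    best_fit = value
                    best_pos = candidate.copy()

        update_frequencies(pop, params)
        update_amplitudes(pop, params)
        trace.record(best_pos, best_fit)

    return best_pos, best_fit, trace
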