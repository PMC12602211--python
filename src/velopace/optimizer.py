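"""Real-coded genetic algorithm for time-minimal speed allocation.

The chromosome is the per-segment speed vector. The objective is total
course time plus a linear exterior penalty for exceeding the above-recovery
energy budget (under-spending is never penalized; time minimization drives
spending toward the budget). Bounds come from the recovery speed (lower)
and the class/corner speed caps (upper); operators clip to bounds so box
violations only matter for externally supplied strategies.

Operators: binary tournament selection, extended-intermediate ("linear")
recombination with per-gene blending factor in [-0.25, 1.25], per-gene
Gaussian mutation scaled to the feasible interval, and elitism. The
constant-power budget-exhausting baseline is injected into the initial
population so a feasible member always exists and the returned best never
loses to it.

A brute-force grid search over the same bounds serves as an independent
test oracle for small courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .course import Course
from .energy import (
    BUDGET_TOL_J,
    CourseArrays,
    Strategy,
    batch_time_work,
    constant_power_baseline,
    course_arrays,
    simulate,
    speed_bounds,
)
from .errors import ValidationError
from .physics import Environment, Rider

BRUTE_FORCE_GUARD = 10_000_000


@dataclass(frozen=True)
class GAParams:
    """Hyperparameters; the defaults for population size, generations and
    operator probabilities follow the reference configuration (500 / 200 /
    p_c 0.8 / p_m 0.2)."""

    population_size: int = 500
    max_generations: int = 200
    crossover_prob: float = 0.8
    mutation_prob: float = 0.2
    penalty_weight: float = 0.01  # seconds charged per joule of overspend
    box_penalty_weight: float = 10.0  # seconds per m/s of bound violation
    seed: int = 0
    elitism: int = 1
    stagnation_patience: int = 30  # 0 disables early stopping
    mutation_scale: float = 0.1  # sigma as a fraction of the bound interval
    #: optional secondary objective weight on the variance of the speed
    #: profile (a smoothness preference); 0 disables it.
    variance_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        if not 0 <= self.crossover_prob <= 1:
            raise ValidationError("crossover_prob must be in [0, 1]")
        if not 0 <= self.mutation_prob <= 1:
            raise ValidationError("mutation_prob must be in [0, 1]")
        if self.penalty_weight < 0:
            raise ValidationError("penalty_weight must be >= 0")
        if self.max_generations < 1:
            raise ValidationError("max_generations must be >= 1")
        if not 0 <= self.elitism < self.population_size:
            raise ValidationError("elitism must be in [0, population_size)")


@dataclass(frozen=True)
class GAResult:
    best_strategy: Strategy
    best_time: float
    best_work: float
    best_objective: float
    history: np.ndarray  # best-so-far objective per generation
    n_evaluations: int
    termination: str  # "max_generations" | "stagnation"
    feasible: bool


def evaluate(
    strategy: Strategy,
    course: Course,
    rider: Rider,
    env: Environment,
    penalty_weight: float = 0.01,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    box_penalty_weight: float = 10.0,
) -> float:
    """Penalized objective (seconds); equals the simulated total time for
    feasible strategies."""
    res = simulate(strategy, course, rider, env)
    obj = res.total_time + penalty_weight * max(res.total_work - rider.energy_budget, 0.0)
    if bounds is not None:
        lower, upper = bounds
        violation = np.maximum(lower - strategy.speeds, 0.0) + np.maximum(
            strategy.speeds - upper, 0.0
        )
        obj += box_penalty_weight * float(violation.sum())
    return obj


def _batch_objective(arrays: CourseArrays, pop: np.ndarray, params: GAParams) -> np.ndarray:
    times, works = batch_time_work(arrays, pop)
    obj = times + params.penalty_weight * np.maximum(works - arrays.energy_budget, 0.0)
    if params.variance_weight > 0.0:
        obj = obj + params.variance_weight * pop.var(axis=-1)
    return obj


def init_population(
    bounds: tuple[np.ndarray, np.ndarray],
    n: int,
    rng: np.random.Generator,
    baseline: np.ndarray | None = None,
) -> np.ndarray:
    """Uniform random population within bounds; if given, the baseline
    strategy replaces member 0 (clipped to bounds)."""
    lower, upper = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    if np.any(lower > upper):
        raise ValidationError("empty bounds interval: lower > upper")
    if n < 2:
        raise ValidationError("population size must be >= 2")
    pop = rng.uniform(lower, upper, size=(n, lower.size))
    if baseline is not None:
        pop[0] = np.clip(np.asarray(baseline, float), lower, upper)
    return pop


def select(
    population: np.ndarray,
    objectives: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary tournament selection with replacement (lower objective wins,
    ties broken by a fair coin)."""
    m = len(population)
    if m != len(objectives):
        raise ValidationError("population and objectives lengths differ")
    a = rng.integers(0, m, size=n)
    b = rng.integers(0, m, size=n)
    coin = rng.random(n) < 0.5
    pick_a = np.where(
        objectives[a] < objectives[b], True, np.where(objectives[b] < objectives[a], False, coin)
    )
    return population[np.where(pick_a, a, b)]


def linear_recombination(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    rng: np.random.Generator,
    bounds: tuple[np.ndarray, np.ndarray],
    beta_range: tuple[float, float] = (-0.25, 1.25),
) -> tuple[np.ndarray, np.ndarray]:
    """Extended-intermediate recombination: per gene, offspring =
    a + beta*(b - a) with beta ~ U[beta_range], clipped to bounds."""
    a = np.asarray(parent_a, float)
    b = np.asarray(parent_b, float)
    if a.shape != b.shape:
        raise ValidationError("parents must have equal lengths")
    lower, upper = bounds
    beta = rng.uniform(beta_range[0], beta_range[1], size=(2,) + a.shape)
    child0 = np.clip(a + beta[0] * (b - a), lower, upper)
    child1 = np.clip(a + beta[1] * (b - a), lower, upper)
    return child0, child1


def real_mutation(
    strategy: np.ndarray,
    p_m: float,
    rng: np.random.Generator,
    bounds: tuple[np.ndarray, np.ndarray],
    scale: float = 0.1,
) -> np.ndarray:
    """Per-gene Gaussian mutation with sigma = scale*(upper - lower),
    applied independently with probability ``p_m``, clipped to bounds."""
    lower, upper = bounds
    x = np.asarray(strategy, float).copy()
    mask = rng.random(x.shape) < p_m
    noise = rng.normal(0.0, 1.0, size=x.shape) * scale * (np.asarray(upper) - np.asarray(lower))
    x[mask] += noise[mask]
    return np.clip(x, lower, upper)


def compute_bounds(
    course: Course, rider: Rider, env: Environment
) -> tuple[np.ndarray, np.ndarray]:
    """Optimization box: recovery/coasting speeds below, caps above."""
    lower, upper = speed_bounds(course, rider, env)
    bad = np.nonzero(lower > upper + 1e-9)[0]
    if bad.size:
        raise ValidationError(
            f"infeasible speed bounds on segment(s) {bad.tolist()}: "
            f"lower bound exceeds speed cap"
        )
    return lower, np.maximum(upper, lower)


def optimize(course: Course, rider: Rider, env: Environment, ga: GAParams) -> GAResult:
    """Run the generational GA and return the best-ever feasible strategy
    (or the best overall if no feasible strategy was seen)."""
    bounds = compute_bounds(course, rider, env)
    lower, upper = bounds
    arrays = course_arrays(course, rider, env)
    rng = np.random.default_rng(ga.seed)

    baseline = constant_power_baseline(course, rider, env)
    pop = init_population(bounds, ga.population_size, rng, baseline=baseline.strategy.speeds)
    obj = _batch_objective(arrays, pop, ga)
    n_evaluations = ga.population_size

    def feasible_mask(p: np.ndarray) -> np.ndarray:
        _, works = batch_time_work(arrays, p)
        return works <= arrays.energy_budget + BUDGET_TOL_J

    best_idx = int(np.argmin(obj))
    best_obj = float(obj[best_idx])
    best_x = pop[best_idx].copy()
    feas = feasible_mask(pop)
    best_feas_obj = np.inf
    best_feas_x = None
    if feas.any():
        i = int(np.flatnonzero(feas)[np.argmin(obj[feas])])
        best_feas_obj = float(obj[i])
        best_feas_x = pop[i].copy()

    history: list[float] = []
    stagnant = 0
    termination = "max_generations"
    for _ in range(ga.max_generations):
        n_children = ga.population_size - ga.elitism
        parents = select(pop, obj, 2 * ((n_children + 1) // 2), rng)
        children = []
        for j in range(0, len(parents), 2):
            pa, pb = parents[j], parents[j + 1]
            if rng.random() < ga.crossover_prob:
                c0, c1 = linear_recombination(pa, pb, rng, bounds)
            else:
                c0, c1 = pa.copy(), pb.copy()
            children.append(c0)
            children.append(c1)
        children = np.array(children[:n_children])
        children = np.array(
            [
                real_mutation(c, ga.mutation_prob, rng, bounds, scale=ga.mutation_scale)
                for c in children
            ]
        )
        if ga.elitism > 0:
            elites = pop[np.argsort(obj, kind="stable")[: ga.elitism]]
            pop = np.vstack([elites, children])
        else:
            pop = children
        obj = _batch_objective(arrays, pop, ga)
        n_evaluations += len(pop)

        gen_best = int(np.argmin(obj))
        improved = obj[gen_best] < best_obj - 1e-12
        if obj[gen_best] < best_obj:
            best_obj = float(obj[gen_best])
            best_x = pop[gen_best].copy()
        feas = feasible_mask(pop)
        if feas.any():
            i = int(np.flatnonzero(feas)[np.argmin(obj[feas])])
            if obj[i] < best_feas_obj:
                best_feas_obj = float(obj[i])
                best_feas_x = pop[i].copy()
        history.append(best_obj)

        stagnant = 0 if improved else stagnant + 1
        if ga.stagnation_patience > 0 and stagnant >= ga.stagnation_patience:
            termination = "stagnation"
            break

    if best_feas_x is not None:
        final_x, final_obj, feasible = best_feas_x, best_feas_obj, True
    else:
        final_x, final_obj, feasible = best_x, best_obj, False
    best_strategy = Strategy(speeds=final_x)
    res = simulate(best_strategy, course, rider, env)
    return GAResult(
        best_strategy=best_strategy,
        best_time=res.total_time,
        best_work=res.total_work,
        best_objective=final_obj,
        history=np.asarray(history),
        n_evaluations=n_evaluations,
        termination=termination,
        feasible=feasible,
    )


def brute_force_optimum(
    course: Course,
    rider: Rider,
    env: Environment,
    grid_points_per_segment: int = 11,
    chunk_size: int = 200_000,
) -> Strategy:
    """Exhaustive grid-search oracle: the feasible Cartesian grid point with
    minimal total time. Deterministic; refuses grids above 10^7 points."""
    if grid_points_per_segment < 2:
        raise ValidationError("grid_points_per_segment must be >= 2")
    lower, upper = compute_bounds(course, rider, env)
    n = len(course)
    total = grid_points_per_segment**n
    if total > BRUTE_FORCE_GUARD:
        raise ValidationError(
            f"grid of {grid_points_per_segment}^{n} = {total} points exceeds the "
            f"{BRUTE_FORCE_GUARD} guard"
        )
    axes = [np.linspace(lower[i], upper[i], grid_points_per_segment) for i in range(n)]
    arrays = course_arrays(course, rider, env)

    best_time = np.inf
    best_point = None
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, n)
    for start in range(0, total, chunk_size):
        block = mesh[start : start + chunk_size]
        times, works = batch_time_work(arrays, block)
        feasible = works <= arrays.energy_budget + BUDGET_TOL_J
        if not feasible.any():
            continue
        idx = np.flatnonzero(feasible)[np.argmin(times[feasible])]
        if times[idx] < best_time:
            best_time = float(times[idx])
            best_point = block[idx].copy()
    if best_point is None:
        raise ValidationError("no feasible grid point found (check bounds and budget)")
    return Strategy(speeds=best_point)
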