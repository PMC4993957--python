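"""Real-coded genetic algorithm over the 9-dimensional medium-composition box.

Chromosomes are real vectors ``[g1..g9]`` — the concentrations of glucose,
maltose, mannitol, corn powder, yeast extract, copper sulfate, sodium
chloride, ferrous sulfate and vitamin B1 — constrained to a per-gene
``[lower, upper]`` box.  The algorithm is the plain generational scheme:

1. evaluate fitness for the whole population;
2. copy the ``elitism`` best individuals unchanged;
3. fill the rest of the next generation by roulette-wheel parent selection,
   whole-arithmetic (blend) crossover and uniform reset mutation;
4. repeat for a fixed number of generations.

Roulette selection samples individual *i* with probability
``f_i / Σ_j f_j``, which requires non-negative fitness; fitness vectors
containing negatives are shifted by the generation minimum (plus a small
floor) before the wheel is built.  Blend crossover takes convex
combinations of the parents, so feasibility w.r.t. the box is preserved by
construction; mutation resamples a gene uniformly inside its own bounds.

Default bounds are the published search box for the fermentation problem
(in g/L): glucose 0–40, maltose 0–40, mannitol 0–40, corn powder 0–100,
yeast 0–100, copper sulfate 0–0.5, sodium chloride 0–10, ferrous sulfate
0–0.5, vitamin B1 0–0.1.  Note the training data violate several of these
bounds (copper sulfate, ferrous sulfate, vitamin B1); ``envelope_bounds``
widens each upper bound to also cover the training-data maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core_data import COMPONENTS, Dataset

__all__ = [
    "DEFAULT_BOUNDS",
    "GAConfig",
    "Individual",
    "OptimizationResult",
    "envelope_bounds",
    "init_population",
    "roulette_probabilities",
    "select_parents",
    "crossover",
    "mutate",
    "run_ga",
]

#: Published search box, one (lower, upper) pair per component, g/L.
DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = (
    (0.0, 40.0),   # glucose
    (0.0, 40.0),   # maltose
    (0.0, 40.0),   # mannitol
    (0.0, 100.0),  # corn powder
    (0.0, 100.0),  # yeast extract
    (0.0, 0.5),    # copper sulfate
    (0.0, 10.0),   # sodium chloride
    (0.0, 0.5),    # ferrous sulfate
    (0.0, 0.1),    # vitamin B1
)

_FITNESS_EPS = 1e-12


def envelope_bounds(data: Dataset) -> tuple[tuple[float, float], ...]:
    """Widen each default upper bound to cover the training-data maximum."""
    xmax = data.X.max(axis=0)
    return tuple(
        (lo, max(hi, float(m))) for (lo, hi), m in zip(DEFAULT_BOUNDS, xmax)
    )


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the generational GA.

    Defaults: population 300, 200 generations, crossover probability 0.8
    (valid range 0.6–1), per-gene mutation probability 0.05 (valid range
    0.01–0.1), one elite.
    """

    population_size: int = 300
    generations: int = 200
    crossover_prob: float = 0.8
    mutation_prob: float = 0.05
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.elitism < self.population_size:
            raise ValueError("elitism must lie in [0, population_size)")
        for j, (lo, hi) in enumerate(self.bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid bounds for gene {j}: ({lo}, {hi})")

    @property
    def n_genes(self) -> int:
        return len(self.bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([lo for lo, _ in self.bounds])

    @property
    def upper(self) -> np.ndarray:
        return np.array([hi for _, hi in self.bounds])


@dataclass
class Individual:
    """A chromosome (gene vector, canonical component order) and its fitness."""

    genes: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=float)

    def copy(self) -> "Individual":
        return Individual(self.genes.copy(), self.fitness)


@dataclass
class OptimizationResult:
    """Best-ever individual of a GA run plus its fitness trajectory."""

    best_individual: Individual
    best_fitness: float
    fitness_history: dict[str, list[float]]  # keys: "best", "mean"
    generations_run: int
    seed: int
    best_predicted_yield: float | None = None  # μg/mL, set by the pipeline


def init_population(
    config: GAConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """(population_size, n_genes) matrix, each gene uniform over its bounds."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    return rng.uniform(
        config.lower,
        config.upper,
        size=(config.population_size, config.n_genes),
    )


def roulette_probabilities(fitnesses: np.ndarray) -> np.ndarray:
    """Selection probabilities proportional to fitness: p_i = f_i / Σ f_j.

    Requires non-negative fitness (shift first if needed).  An all-zero
    fitness vector falls back to the uniform distribution with a warning.
    """
    f = np.asarray(fitnesses, dtype=float)
    if f.ndim != 1 or len(f) == 0:
        raise ValueError("fitnesses must be a non-empty 1-D vector")
    if not np.isfinite(f).all():
        raise ValueError("fitnesses must be finite")
    if (f < 0).any():
        raise ValueError(
            "roulette selection requires non-negative fitness; shift first"
        )
    total = f.sum()
    if total == 0.0:
        warnings.warn(
            "all fitnesses are zero; falling back to uniform selection",
            stacklevel=2,
        )
        return np.full(len(f), 1.0 / len(f))
    return f / total


def select_parents(
    population: np.ndarray,
    probabilities: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent categorical draws (with replacement) from the wheel."""
    idx = rng.choice(len(population), size=2, p=probabilities)
    return population[idx[0]].copy(), population[idx[1]].copy()


def crossover(
    a: np.ndarray,
    b: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Whole-arithmetic (blend) crossover with probability ``crossover_prob``.

    With one λ ~ U(0,1) per mating: child1 = λa + (1−λ)b and child2 the
    mirror combination; otherwise the children are copies of the parents.
    Convexity keeps offspring inside the bounds box.
    """
    if rng.random() < config.crossover_prob:
        lam = rng.random()
        return lam * a + (1.0 - lam) * b, (1.0 - lam) * a + lam * b
    return a.copy(), b.copy()


def mutate(
    genes: np.ndarray, config: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Uniform reset: each gene, independently with probability
    ``mutation_prob``, is resampled uniformly within its own bounds."""
    out = genes.copy()
    mask = rng.random(config.n_genes) < config.mutation_prob
    if mask.any():
        out[mask] = rng.uniform(config.lower[mask], config.upper[mask])
    return out


def _shift_nonnegative(f: np.ndarray) -> np.ndarray:
    """Shift a fitness vector so the wheel is well defined.

    Negative values are shifted by the generation minimum with a small
    floor so the worst individual retains a vanishing (not exactly zero)
    slice of the wheel.
    """
    fmin = f.min()
    if fmin < 0:
        return f - fmin + _FITNESS_EPS
    return f


def run_ga(
    fitness_fn: Callable[[np.ndarray], np.ndarray | float],
    config: GAConfig,
    vectorized: bool = False,
) -> OptimizationResult:
    """Maximize ``fitness_fn`` over the bounds box.

    ``fitness_fn`` maps a chromosome (1-D, length 9 by default) to a scalar;
    with ``vectorized=True`` it maps an (n, n_genes) matrix to an n-vector,
    which is much faster for surrogate objectives.  Fitness may be negative;
    the wheel sees a shifted copy.  Returns the best individual ever
    evaluated (with ``elitism >= 1`` this is also the final generation's
    best, and the per-generation best is non-decreasing).
    """
    rng = np.random.default_rng(config.seed)

    def evaluate(pop: np.ndarray) -> np.ndarray:
        if vectorized:
            f = np.asarray(fitness_fn(pop), dtype=float).ravel()
        else:
            f = np.array([float(fitness_fn(ind)) for ind in pop])
        if not np.isfinite(f).all():
            bad = pop[~np.isfinite(f)][0]
            raise FloatingPointError(
                f"fitness function returned a non-finite value at "
                f"chromosome {bad.tolist()}"
            )
        return f

    pop = init_population(config, rng)
    fit = evaluate(pop)
    best_idx = int(np.argmax(fit))
    best = Individual(pop[best_idx].copy(), float(fit[best_idx]))
    history: dict[str, list[float]] = {
        "best": [float(fit.max())],
        "mean": [float(fit.mean())],
    }

    for _ in range(config.generations):
        order = np.argsort(fit)[::-1]
        elites = pop[order[: config.elitism]].copy()
        wheel = roulette_probabilities(_shift_nonnegative(fit))
        children: list[np.ndarray] = []
        while len(children) < config.population_size - config.elitism:
            pa, pb = select_parents(pop, wheel, rng)
            c1, c2 = crossover(pa, pb, config, rng)
            children.append(mutate(c1, config, rng))
            if len(children) < config.population_size - config.elitism:
                children.append(mutate(c2, config, rng))
        pop = np.vstack([elites] + [np.asarray(children)]) if len(elites) else np.asarray(children)
        fit = evaluate(pop)
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best.fitness:
            best = Individual(pop[gen_best].copy(), float(fit[gen_best]))
        history["best"].append(float(fit.max()))
        history["mean"].append(float(fit.mean()))

    return OptimizationResult(
        best_individual=best,
        best_fitness=float(best.fitness),
        fitness_history=history,
        generations_run=config.generations,
        seed=config.seed,
    )
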