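"""Seeded genetic algorithm over binary or bounded-real chromosomes.

Tournament selection, one-point crossover (binary) or arithmetic blend
(real), per-gene mutation (bit flip / bounded Gaussian perturbation),
elitism, and dual stopping: a hard generation cap plus early stop after a
patience window without improvement.  Fitness is always MAXIMIZED; callers
minimizing an error pass its negation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["GAConfig", "Chromosome", "GAResult", "run_ga", "tournament_select"]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.02
    tournament_size: int = 3
    max_generations: int = 50
    elitism_count: int = 1
    seed: int = 0
    patience: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.crossover_rate <= 1.0 and 0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if self.tournament_size < 2:
            raise ValueError("tournament_size must be >= 2")
        if not 0 <= self.elitism_count < self.population_size:
            raise ValueError("require 0 <= elitism_count < population_size")


@dataclass(frozen=True)
class Chromosome:
    """A candidate solution: binary gene vector, or real genes with bounds."""

    kind: str  # "binary" | "real"
    genes: np.ndarray
    bounds: np.ndarray | None = None  # (n_genes, 2) for real kind

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", np.asarray(self.genes))
        if self.kind == "binary":
            if not np.isin(self.genes, (0, 1)).all():
                raise ValueError("binary genes must be 0/1")
        elif self.kind == "real":
            if self.bounds is None:
                raise ValueError("real chromosomes need bounds")
            object.__setattr__(self, "bounds", np.asarray(self.bounds, dtype=float))
            lo, hi = self.bounds[:, 0], self.bounds[:, 1]
            if ((self.genes < lo) | (self.genes > hi)).any():
                raise ValueError("real genes must lie within bounds")
        else:
            raise ValueError(f"unknown chromosome kind {self.kind!r}")


@dataclass
class GAResult:
    best: Chromosome
    best_fitness: float
    history: np.ndarray = field(default_factory=lambda: np.empty(0))
    generations_run: int = 0


def tournament_select(
    population: list[Chromosome],
    fitnesses: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> Chromosome:
    """Best of k members drawn uniformly with replacement; ties -> lowest index."""
    if len(population) == 0:
        raise ValueError("empty population")
    if k > len(population):
        raise ValueError("tournament size exceeds population")
    idx = rng.integers(0, len(population), size=k)
    idx_sorted = np.sort(idx)  # ties broken by lowest population index
    winner = idx_sorted[np.argmax(fitnesses[idx_sorted])]
    return population[int(winner)]


def _crossover(p1: Chromosome, p2: Chromosome, rng: np.random.Generator):
    g1, g2 = p1.genes.copy(), p2.genes.copy()
    n = len(g1)
    if p1.kind == "binary":
        if n > 1:
            point = int(rng.integers(1, n))
            g1[point:], g2[point:] = p2.genes[point:].copy(), p1.genes[point:].copy()
    else:
        alpha = rng.uniform()
        g1 = alpha * p1.genes + (1 - alpha) * p2.genes
        g2 = alpha * p2.genes + (1 - alpha) * p1.genes
    return (
        Chromosome(p1.kind, g1, p1.bounds),
        Chromosome(p1.kind, g2, p1.bounds),
    )


def _mutate(chrom: Chromosome, rate: float, rng: np.random.Generator) -> Chromosome:
    genes = chrom.genes.copy()
    flip = rng.uniform(size=len(genes)) < rate
    if not flip.any():
        return chrom
    if chrom.kind == "binary":
        genes[flip] = 1 - genes[flip]
    else:
        lo, hi = chrom.bounds[:, 0], chrom.bounds[:, 1]
        sd = 0.1 * (hi - lo)
        genes = np.where(flip, genes + rng.normal(0.0, 1.0, size=len(genes)) * sd, genes)
        genes = np.clip(genes, lo, hi)
    return Chromosome(chrom.kind, genes, chrom.bounds)


def run_ga(
    config: GAConfig,
    init: Callable[[np.random.Generator], Chromosome],
    fitness: Callable[[Chromosome], float],
) -> GAResult:
    """Run the GA and return the best chromosome with its fitness history.

    ``init`` draws one random chromosome from the caller's rng; ``fitness``
    must be deterministic given a chromosome (callers fix internal seeds).
    With ``elitism_count >= 1`` the best-fitness history is monotone
    non-decreasing; identical seeds give identical results.
    """
    rng = np.random.default_rng(config.seed)
    population = [init(rng) for _ in range(config.population_size)]

    def evaluate(pop: list[Chromosome], gen: int) -> np.ndarray:
        vals = np.array([fitness(c) for c in pop], dtype=float)
        if not np.isfinite(vals).all():
            bad = int(np.flatnonzero(~np.isfinite(vals))[0])
            raise ValueError(
                f"non-finite fitness at generation {gen}, chromosome {bad}: "
                f"genes={pop[bad].genes}"
            )
        return vals

    fitnesses = evaluate(population, 0)
    history: list[float] = []
    overall_best: Chromosome = population[int(np.argmax(fitnesses))]
    overall_best_fitness = -np.inf
    stagnant = 0

    for gen in range(config.max_generations):
        gen_best = float(fitnesses.max())
        history.append(gen_best)
        if gen_best > overall_best_fitness + 1e-15:
            stagnant = 0
        else:
            stagnant += 1
        if gen_best >= overall_best_fitness:
            overall_best_fitness = gen_best
            overall_best = population[int(np.argmax(fitnesses))]
        if stagnant >= config.patience or gen == config.max_generations - 1:
            break

        # elites: best chromosomes copied unchanged (ties -> lowest index)
        elite_idx = np.argsort(-fitnesses, kind="stable")[: config.elitism_count]
        next_pop = [population[int(i)] for i in elite_idx]

        while len(next_pop) < config.population_size:
            p1 = tournament_select(population, fitnesses, config.tournament_size, rng)
            p2 = tournament_select(population, fitnesses, config.tournament_size, rng)
            if rng.uniform() < config.crossover_rate:
                c1, c2 = _crossover(p1, p2, rng)
            else:
                c1, c2 = p1, p2
            next_pop.append(_mutate(c1, config.mutation_rate, rng))
            if len(next_pop) < config.population_size:
                next_pop.append(_mutate(c2, config.mutation_rate, rng))

        population = next_pop
        fitnesses = evaluate(population, gen + 1)

    return GAResult(
        best=overall_best,
        best_fitness=overall_best_fitness,
        history=np.asarray(history),
        generations_run=len(history),
    )
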