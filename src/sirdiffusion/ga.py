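"""Real-coded genetic-algorithm operators.

The operator set follows the classic recipes: Baker's linear-ranking
fitness, roulette-wheel selection, single-point crossover applied at gene
boundaries, and Muehlenbein/Schlierkamp-Voosen real-value mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAConfig",
    "rank_fitness",
    "roulette_select",
    "single_point_crossover",
    "real_value_mutation",
]

#: Mutation range as a fraction of the gene's bound width.
MUTATION_RANGE_FRACTION = 0.1
#: Mutation precision constant k in the step factor 2**(-u*k).
MUTATION_PRECISION = 16


@dataclass
class GAConfig:
    """Hyperparameters and feasible set F of the genetic algorithm.

    ``bounds`` holds one (lower, upper) pair per gene — for the SIR
    fitter the genes are (lambda0, beta, mu, S0, K) with
    lambda0 = alpha * S0; a pair with lower == upper freezes that gene
    at the common value (no mutation).
    ``selective_pressure`` in [1, 2] controls Baker's linear ranking:
    1 removes selection pressure entirely, 2 is maximal.
    """

    population_size: int = 100
    generations: int = 500
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    selective_pressure: float = 2.0
    bounds: list[tuple[float, float]] | None = None
    elitism_count: int = 1
    seed: int = 0
    local_polish: bool = True
    restart_after: int = 50
    restart_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not 1.0 <= self.selective_pressure <= 2.0:
            raise ValueError("selective_pressure must be in [1, 2]")
        if self.elitism_count < 0:
            raise ValueError("elitism_count must be >= 0")
        if self.restart_after < 0 or self.restart_tol < 0:
            raise ValueError("restart_after and restart_tol must be >= 0")
        if self.bounds is not None:
            for lo, hi in self.bounds:
                if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
                    raise ValueError(f"invalid gene bounds ({lo}, {hi})")


def rank_fitness(objectives: np.ndarray, selective_pressure: float) -> np.ndarray:
    """Baker linear-ranking fitness from raw objective values (lower = better).

    Individuals are ranked ascending by objective; the best gets rank N and
    fitness SP, the worst rank 1 and fitness 2 - SP, linearly interpolated:
    fitness(r) = 2 - SP + 2*(SP - 1)*(r - 1)/(N - 1).  Ties keep their
    original order (stable sort).  The fitness values always sum to N.
    """
    objectives = np.asarray(objectives, dtype=float)
    N = len(objectives)
    if N < 2:
        raise ValueError("ranking needs at least 2 individuals")
    if not 1.0 <= selective_pressure <= 2.0:
        raise ValueError("selective_pressure must be in [1, 2]")
    order = np.argsort(objectives, kind="stable")  # ascending: best first
    ranks = np.empty(N)
    ranks[order] = np.arange(N, 0, -1)  # best -> N, worst -> 1
    sp = selective_pressure
    return 2.0 - sp + 2.0 * (sp - 1.0) * (ranks - 1.0) / (N - 1.0)


def roulette_select(
    fitness: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``count`` indices with replacement, proportional to fitness."""
    fitness = np.asarray(fitness, dtype=float)
    if np.any(fitness < 0):
        raise ValueError("fitness values must be non-negative")
    total = fitness.sum()
    if total <= 0:
        raise ValueError("all-zero fitness: roulette wheel undefined")
    return rng.choice(len(fitness), size=count, p=fitness / total)


def crossover_at(
    parent_a: np.ndarray, parent_b: np.ndarray, cut: int
) -> tuple[np.ndarray, np.ndarray]:
    """Swap gene tails at a given cut point in {1, .., L-1}."""
    child_a = np.concatenate([parent_a[:cut], parent_b[cut:]])
    child_b = np.concatenate([parent_b[:cut], parent_a[cut:]])
    return child_a, child_b


def single_point_crossover(
    parent_a: np.ndarray, parent_b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Single-point crossover with a uniform cut point.

    The cut c is drawn uniformly from {1, .., L-1}; children exchange the
    gene tails beyond c and individual gene values are never altered, so
    the multiset of genes across the pair is conserved.
    """
    parent_a = np.asarray(parent_a, dtype=float)
    parent_b = np.asarray(parent_b, dtype=float)
    L = len(parent_a)
    if len(parent_b) != L:
        raise ValueError("parents must have equal length")
    if L < 2:
        raise ValueError("crossover needs at least 2 genes")
    cut = int(rng.integers(1, L))
    return crossover_at(parent_a, parent_b, cut)


def real_value_mutation(
    gene: float, bounds: tuple[float, float], rng: np.random.Generator
) -> float:
    """Muehlenbein/Schlierkamp-Voosen bounded real mutation of one gene.

    Returns gene + s*r*a with sign s = +-1 equiprobable, mutation range
    r = 0.1*(upper - lower), and step factor a = 2**(-u*k) for u ~ U[0, 1]
    and precision k = 16; the result is clipped into [lower, upper].  The
    step is at most r, and half the probability mass of a lies below
    2**(-k/2), giving fine-grained local search.
    """
    lower, upper = bounds
    if lower >= upper:
        raise ValueError(f"degenerate bounds ({lower}, {upper})")
    if not lower <= gene <= upper:
        raise ValueError(f"gene {gene} outside bounds ({lower}, {upper})")
    sign = 1.0 if rng.random() < 0.5 else -1.0
    r = MUTATION_RANGE_FRACTION * (upper - lower)
    a = 2.0 ** (-rng.random() * MUTATION_PRECISION)
    return float(np.clip(gene + sign * r * a, lower, upper))
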