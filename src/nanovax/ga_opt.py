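"""Real-coded genetic algorithm over the LNP formulation box.

Fitness is the surrogate-predicted delta-AUC (or any callable on rows in
the fixed feature order). The GA uses tournament selection, per-gene
arithmetic-blend crossover on the continuous genes with a swap on the
targeting bit, clipped Gaussian mutation (SD = 5% of each gene's range,
targeting flipped with probability 0.1 when an individual mutates), and
elitism, which makes the best-so-far fitness trace non-decreasing.

The reported top-k comes from a hall of fame accumulated over every
individual evaluated in the run, deduplicated on a rounded genome
(size to 0.1 nm, charge to 0.1 mV, PEG to 0.01 mol%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._seeds import stage_rng
from .lnp_space import BOUNDS, FEATURES
from .surrogate import SurrogateModel

__all__ = [
    "GAConfig",
    "Candidate",
    "GAResult",
    "init_population",
    "tournament_select",
    "crossover",
    "mutate",
    "run_ga",
]

_LO = np.array([BOUNDS["size_nm"][0], BOUNDS["charge_mV"][0], BOUNDS["peg_molpct"][0]])
_HI = np.array([BOUNDS["size_nm"][1], BOUNDS["charge_mV"][1], BOUNDS["peg_molpct"][1]])
_RANGE = _HI - _LO
_MUT_SD = 0.05 * _RANGE  # mutation SD: 5% of each continuous gene's range
_FLIP_P = 0.1  # targeting-bit flip probability given the individual mutates
_DEDUP_DECIMALS = np.array([1, 1, 2])  # size 0.1 nm, charge 0.1 mV, PEG 0.01


@dataclass
class GAConfig:
    pop_size: int = 50
    generations: int = 100
    p_crossover: float = 0.8
    p_mutation: float = 0.2
    tournament_size: int = 3
    elitism: int = 1
    top_k: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.p_crossover <= 1 and 0 <= self.p_mutation <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if not self.pop_size >= self.tournament_size >= 2:
            raise ValueError("require pop_size >= tournament_size >= 2")
        if self.elitism < 0 or self.elitism >= self.pop_size:
            raise ValueError("elitism must be in [0, pop_size)")
        if self.generations < 1 or self.top_k < 1:
            raise ValueError("generations and top_k must be >= 1")


@dataclass
class Candidate:
    """A formulation genome (size, charge, peg, targeting) and its fitness."""

    genome: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.genome = np.asarray(self.genome, dtype=float)
        if self.genome.shape != (4,):
            raise ValueError("genome must have 4 genes")
        if (self.genome[:3] < _LO).any() or (self.genome[:3] > _HI).any():
            raise ValueError("continuous genes out of bounds")
        if self.genome[3] not in (0.0, 1.0):
            raise ValueError("targeting gene must be 0 or 1")


@dataclass
class GAResult:
    trace: pd.DataFrame  # generation, best, mean, best_so_far
    final_population: list[Candidate]
    top_k: pd.DataFrame  # rank, size_nm, charge_mV, peg_molpct, targeting, predicted_delta_auc
    config: GAConfig = field(repr=False, default_factory=GAConfig)


def _clip(genome: np.ndarray) -> np.ndarray:
    out = genome.copy()
    out[:3] = np.clip(out[:3], _LO, _HI)
    return out


def init_population(config: GAConfig, rng: np.random.Generator | None = None) -> list[Candidate]:
    """Uniform random genomes over the box; targeting ~ Bernoulli(0.5)."""
    config.validate()
    if rng is None:
        rng = stage_rng(config.seed, "ga_opt/init")
    cont = rng.uniform(_LO, _HI, size=(config.pop_size, 3))
    targeting = rng.integers(0, 2, size=config.pop_size).astype(float)
    return [Candidate(np.append(cont[i], targeting[i])) for i in range(config.pop_size)]


def tournament_select(
    population: Sequence[Candidate], k: int, rng: np.random.Generator
) -> Candidate:
    """Draw k individuals without replacement; the fittest wins (ties: first drawn)."""
    if not population:
        raise ValueError("population is empty")
    if k > len(population):
        raise ValueError("tournament size exceeds population size")
    idx = rng.choice(len(population), size=k, replace=False)
    drawn = [population[i] for i in idx]
    best = int(np.argmax([c.fitness for c in drawn]))  # argmax takes the first maximum
    return drawn[best]


def crossover(
    a: Candidate, b: Candidate, p: float, rng: np.random.Generator
) -> tuple[Candidate, Candidate]:
    """Per-gene arithmetic blend of the continuous genes; targeting may swap.

    With probability p: each continuous gene pair is blended with its own
    beta ~ Uniform(0, 1) (child1 = beta*a + (1-beta)*b and the mirror), and
    the targeting bits are swapped with probability 0.5. Otherwise the
    parents are copied unchanged. Children are clipped to bounds.
    """
    g_a, g_b = a.genome.copy(), b.genome.copy()
    if rng.random() < p:
        beta = rng.random(3)
        c1 = beta * g_a[:3] + (1 - beta) * g_b[:3]
        c2 = beta * g_b[:3] + (1 - beta) * g_a[:3]
        t1, t2 = g_a[3], g_b[3]
        if rng.random() < 0.5:
            t1, t2 = t2, t1
        return (
            Candidate(_clip(np.append(c1, t1))),
            Candidate(_clip(np.append(c2, t2))),
        )
    return Candidate(g_a), Candidate(g_b)


def mutate(c: Candidate, p: float, rng: np.random.Generator) -> Candidate:
    """Clipped Gaussian perturbation of an individual, with probability p.

    When the individual mutates, every continuous gene gets Normal(0,
    (0.05*range)^2) noise and the targeting bit flips with probability 0.1.
    """
    genome = c.genome.copy()
    if rng.random() < p:
        genome[:3] = genome[:3] + rng.normal(0.0, _MUT_SD)
        if rng.random() < _FLIP_P:
            genome[3] = 1.0 - genome[3]
    return Candidate(_clip(genome))


def _evaluate(population: list[Candidate], fitness_fn) -> None:
    X = np.stack([c.genome for c in population])
    fit = np.asarray(fitness_fn(X), dtype=float)
    for c, f in zip(population, fit):
        c.fitness = float(f)


def _as_fitness_fn(surrogate) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(surrogate, SurrogateModel):
        return surrogate.predict
    if callable(surrogate):
        return surrogate
    raise TypeError("surrogate must be a SurrogateModel or a callable on genome rows")


def _dedup_top_k(hall: list[Candidate], top_k: int) -> pd.DataFrame:
    rows: dict[tuple, Candidate] = {}
    for c in sorted(hall, key=lambda c: -c.fitness):
        key = (
            round(c.genome[0], 1),
            round(c.genome[1], 1),
            round(c.genome[2], 2),
            int(c.genome[3]),
        )
        if key not in rows:
            rows[key] = c
        if len(rows) >= top_k:
            break
    table = pd.DataFrame(
        [
            {
                "rank": i + 1,
                "size_nm": c.genome[0],
                "charge_mV": c.genome[1],
                "peg_molpct": c.genome[2],
                "targeting": int(c.genome[3]),
                "predicted_delta_auc": c.fitness,
            }
            for i, c in enumerate(rows.values())
        ]
    )
    return table


def run_ga(surrogate, config: GAConfig | None = None) -> GAResult:
    """Full generational GA loop; returns trace, final population and top-k.

    ``surrogate`` is a fitted SurrogateModel or any callable mapping an
    (n, 4) array of genomes in feature order to fitness values.
    """
    if config is None:
        config = GAConfig()
    config.validate()
    fitness_fn = _as_fitness_fn(surrogate)
    rng = stage_rng(config.seed, "ga_opt/run")

    population = init_population(config, rng=rng)
    _evaluate(population, fitness_fn)
    hall: list[Candidate] = list(population)

    records = []
    best_so_far = max(c.fitness for c in population)

    def record(gen: int) -> None:
        nonlocal best_so_far
        fits = [c.fitness for c in population]
        best_so_far = max(best_so_far, max(fits))
        records.append(
            {
                "generation": gen,
                "best": max(fits),
                "mean": float(np.mean(fits)),
                "best_so_far": best_so_far,
            }
        )

    record(0)
    for gen in range(1, config.generations + 1):
        elites = sorted(population, key=lambda c: -c.fitness)[: config.elitism]
        offspring: list[Candidate] = [Candidate(e.genome.copy(), e.fitness) for e in elites]
        while len(offspring) < config.pop_size:
            pa = tournament_select(population, config.tournament_size, rng)
            pb = tournament_select(population, config.tournament_size, rng)
            c1, c2 = crossover(pa, pb, config.p_crossover, rng)
            offspring.append(mutate(c1, config.p_mutation, rng))
            if len(offspring) < config.pop_size:
                offspring.append(mutate(c2, config.p_mutation, rng))
        _evaluate(offspring, fitness_fn)
        population = offspring
        hall.extend(population)
        record(gen)

    trace = pd.DataFrame(records)
    return GAResult(
        trace=trace,
        final_population=population,
        top_k=_dedup_top_k(hall, config.top_k),
        config=config,
    )
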