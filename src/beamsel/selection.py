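"""Evolutionary beam-orientation selection (BOS).

A genome is an ordered list of K beam indices into the candidate node
set.  Fitness is the plan objective F after the inner pipeline (fluence
optimisation, sequencing, direct aperture optimisation) restricted to
the genome's unique beams — lower is fitter.  Each generation the
fittest tenth of the population (at least two individuals) forms the
parent pool; a full population of offspring is bred by per-gene
crossover (probability 0.4 of taking parent A's gene, else parent B's,
with one redraw on duplicates and acceptance on the second), per-gene
mutation (probability 0.05, uniform over candidates), and replaces the
population wholesale.  The returned optimum is the best individual
ever encountered in any generation (implicit elitism).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dose import DoseInfluenceMatrix
from .geometry import NodeSet, VoxelPhantom
from .objective import PlanObjective
from .planning import Plan, PlanConfig, optimize_plan

#: fitness_fn(genome, seed) -> fitness; the EA is agnostic of planning.
FitnessFn = Callable[[tuple[int, ...], int], float]


@dataclass
class Individual:
    genome: tuple[int, ...]
    fitness: float | None = None
    plan: Plan | None = None


@dataclass(frozen=True)
class EAConfig:
    population: int = 20
    generations: int = 20
    k_beams: int = 15
    crossover_ratio: float = 0.4    # P(gene from parent A); 0.6 from B
    mutation_prob: float = 0.05
    parent_fraction: float = 0.1    # fittest tenth, floor of 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.crossover_ratio <= 1.0):
            raise ValueError("crossover ratio must be in (0, 1]")
        if not (0.0 <= self.mutation_prob <= 1.0):
            raise ValueError("mutation probability must be in [0, 1]")
        if self.population < 2 or self.k_beams < 1:
            raise ValueError("population >= 2 and k_beams >= 1 required")

    @property
    def parent_pool_size(self) -> int:
        return max(2, math.ceil(self.population * self.parent_fraction))


@dataclass(frozen=True)
class GenerationStats:
    generation: int
    median: float
    q25: float
    q75: float
    minimum: float
    maximum: float


@dataclass
class EAResult:
    best: Individual
    stats: list[GenerationStats]
    fitness_history: list[np.ndarray] = field(default_factory=list)
    best_trace: list[float] = field(default_factory=list)

    def stats_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.stats])


def _fitness_seed(run_seed: int, generation: int, index: int) -> int:
    ss = np.random.SeedSequence([run_seed, generation, index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def init_population(cfg: EAConfig, n_candidates: int,
                    rng: np.random.Generator) -> list[Individual]:
    """Random genomes of K distinct indices, uniform without replacement."""
    if cfg.k_beams > n_candidates:
        raise ValueError("cannot select more beams than candidates")
    return [Individual(tuple(int(g) for g in
                             rng.choice(n_candidates, cfg.k_beams,
                                        replace=False)))
            for _ in range(cfg.population)]


def make_offspring(parents: tuple[Individual, Individual], cfg: EAConfig,
                   rng: np.random.Generator, n_candidates: int) -> Individual:
    """Per-gene crossover with one duplicate redraw, then mutation.

    Gene k comes from parent A with probability ``crossover_ratio``,
    else from parent B.  If the drawn index already occurs in the
    child, one more draw is made by the same rule; a second duplicate
    is accepted anyway.  Each placed gene then mutates with probability
    ``mutation_prob`` into a uniform random candidate index.
    """
    pa, pb = parents
    child: list[int] = []
    for k in range(cfg.k_beams):
        for _attempt in range(2):
            src = pa if rng.random() < cfg.crossover_ratio else pb
            gene = src.genome[k]
            if gene not in child:
                break
        if rng.random() < cfg.mutation_prob:
            gene = int(rng.integers(n_candidates))
        child.append(int(gene))
    return Individual(tuple(child))


def _stats(fits: np.ndarray, generation: int) -> GenerationStats:
    return GenerationStats(generation,
                           float(np.median(fits)),
                           float(np.percentile(fits, 25)),
                           float(np.percentile(fits, 75)),
                           float(fits.min()), float(fits.max()))


def run_ea(cfg: EAConfig, n_candidates: int,
           fitness_fn: FitnessFn) -> EAResult:
    """The generic EA loop over an arbitrary fitness function.

    Deterministic for a given config (seed included): population
    initialisation, parent picks, crossover and mutation all derive
    from one seeded generator, and each evaluation receives a seed
    derived from (run seed, generation, individual index).
    """
    rng = np.random.default_rng(cfg.seed)
    population = init_population(cfg, n_candidates, rng)
    result = EAResult(best=Individual((), fitness=math.inf), stats=[])

    def evaluate_all(pop: list[Individual], gen: int) -> None:
        for i, ind in enumerate(pop):
            if ind.fitness is None:
                ind.fitness = float(fitness_fn(
                    ind.genome, _fitness_seed(cfg.seed, gen, i)))
        fits = np.array([ind.fitness for ind in pop])
        result.stats.append(_stats(fits, gen))
        result.fitness_history.append(fits)
        gen_best = min(pop, key=lambda d: d.fitness)
        if gen_best.fitness < result.best.fitness:
            result.best = replace(gen_best)
        result.best_trace.append(result.best.fitness)

    evaluate_all(population, 0)
    for gen in range(1, cfg.generations + 1):
        pool = sorted(population, key=lambda d: d.fitness)
        pool = pool[:cfg.parent_pool_size]
        offspring = []
        for _ in range(cfg.population):
            ia, ib = rng.choice(len(pool), size=2, replace=False)
            offspring.append(make_offspring((pool[ia], pool[ib]), cfg,
                                            rng, n_candidates))
        population = offspring
        evaluate_all(population, gen)
    return result


def make_plan_fitness(dij: DoseInfluenceMatrix, obj: PlanObjective,
                      phantom: VoxelPhantom,
                      plan_cfg: PlanConfig,
                      keep_plans: bool = False):
    """Fitness function running the full inner pipeline, with caching.

    The pipeline is deterministic given the unique beam set, so
    evaluations are memoised on it; duplicate genes therefore score
    exactly as the deduplicated genome.
    """
    cache: dict[tuple[int, ...], float] = {}
    plans: dict[tuple[int, ...], Plan] = {}

    def fitness(genome: tuple[int, ...], seed: int) -> float:
        key = tuple(sorted(set(genome)))
        if key not in cache:
            plan = optimize_plan(dij, obj, phantom, key, plan_cfg)
            cache[key] = plan.objective_value
            if keep_plans:
                plans[key] = plan
        return cache[key]

    fitness.plans = plans  # type: ignore[attr-defined]
    return fitness


def run_bos(cfg: EAConfig, dij: DoseInfluenceMatrix, obj: PlanObjective,
            phantom: VoxelPhantom, candidates: NodeSet,
            plan_cfg: PlanConfig | None = None) -> tuple[EAResult, Plan]:
    """Beam-orientation selection over a candidate node set.

    Returns the EA result and the fully re-evaluated best plan.
    """
    plan_cfg = plan_cfg or PlanConfig(fluence_iterations=20,
                                      dao_iterations=20)
    fitness = make_plan_fitness(dij, obj, phantom, plan_cfg)
    result = run_ea(cfg, len(candidates), fitness)
    best_plan = optimize_plan(dij, obj, phantom,
                              sorted(set(result.best.genome)), plan_cfg)
    result.best.plan = best_plan
    return result, best_plan


def run_parameter_sweep(base: EAConfig, perturbations: Sequence[dict],
                        n_candidates: int, fitness_fn: FitnessFn,
                        ) -> pd.DataFrame:
    """EA sensitivity table: one row per parameter perturbation.

    Each perturbation is a dict of EAConfig field overrides, plus the
    optional keys ``name`` and ``repeats``.  For a single run the
    final-generation median and range are those of the individuals; for
    repeated runs (fresh seeds) they summarise the per-run final
    medians, and ``lowest`` is the best objective found in any run.
    """
    rows = []
    for pert in perturbations:
        pert = dict(pert)
        name = pert.pop("name", None)
        repeats = int(pert.pop("repeats", 1))
        cfg = replace(base, **pert)
        finals, lows = [], []
        last_stats = None
        for r in range(repeats):
            run_cfg = replace(cfg, seed=cfg.seed + r)
            res = run_ea(run_cfg, n_candidates, fitness_fn)
            finals.append(res.stats[-1].median)
            lows.append(res.best.fitness)
            last_stats = res.stats[-1]
        if repeats == 1:
            median, lo, hi = (last_stats.median, last_stats.minimum,
                              last_stats.maximum)
        else:
            median = float(np.median(finals))
            lo, hi = float(np.min(finals)), float(np.max(finals))
        rows.append({
            "name": name or f"run{len(rows) + 1}",
            "population": cfg.population,
            "generations": cfg.generations,
            "repeats": repeats,
            "crossover_ratio": cfg.crossover_ratio,
            "mutation_prob": cfg.mutation_prob,
            "final_median": median,
            "final_range_low": lo,
            "final_range_high": hi,
            "lowest": float(np.min(lows)),
        })
    return pd.DataFrame(rows)
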