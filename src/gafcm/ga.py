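"""Real-coded genetic algorithm over fuzzy C-means class centers.

Each chromosome is a vector of candidate cluster-center intensities in
[0, 255].  Its fitness is the fuzzy C-means cost J obtained after feeding
those centers through a short burst of FCM updates (one membership update
plus one centroid update by default), so the GA explores the cost landscape
that plain FCM would descend from each candidate initialisation.  Selection
is roulette-wheel on inverted cost, recombination is whole-arithmetic
crossover, mutation is clipped Gaussian perturbation, and a fixed elite
fraction is carried over unchanged — which makes the per-generation best
cost monotonically non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateClusterError, SelectionFailureError
from .fcm import FCMParams, FCMResult, fcm_run, fitness_burst, update_memberships

__all__ = [
    "Chromosome",
    "GAParams",
    "Population",
    "GAFCMResult",
    "init_population",
    "evaluate_fitness",
    "select_parent",
    "crossover",
    "mutate",
    "next_generation",
    "ga_fcm_optimize",
]

_ROULETTE_EPS = 1e-12  # keeps the worst finite member selectable


@dataclass
class Chromosome:
    """Candidate center vector with its cached cost (lower is better)."""

    genes: np.ndarray
    cost: float | None = None

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=float)


@dataclass(frozen=True)
class GAParams:
    """Genetic-operator settings.

    The three fractions describe the composition of each new generation
    (elite carry-over, crossover offspring, mutants) and must sum to 1;
    member counts are rounded and any remainder goes to the elites.
    Defaults: population 100, chromosome length 6, 40 generations,
    60% crossover / 30% mutation / 10% elitism, genes uniform on (0, 255).
    """

    pop_size: int = 100
    chrom_len: int = 6
    generations: int = 40
    crossover_frac: float = 0.60
    mutation_frac: float = 0.30
    elite_frac: float = 0.10
    gene_range: tuple[float, float] = (0.0, 255.0)
    mutation_scale: float = 25.5
    mutation_decay: float = 1.0
    inner_iterations: int = 1
    seed: int | None = None

    def __post_init__(self):
        if self.pop_size < 1:
            raise ValueError(f"pop_size must be >= 1, got {self.pop_size}")
        if self.chrom_len < 1:
            raise ValueError(f"chrom_len must be >= 1, got {self.chrom_len}")
        if self.generations < 0:
            raise ValueError(f"generations must be >= 0, got {self.generations}")
        for name in ("crossover_frac", "mutation_frac", "elite_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        total = self.crossover_frac + self.mutation_frac + self.elite_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"crossover+mutation+elite fractions must sum to 1, got {total}")
        if self.gene_range[0] > self.gene_range[1]:
            raise ValueError(f"invalid gene_range {self.gene_range}")
        if self.mutation_scale < 0:
            raise ValueError(f"mutation_scale must be >= 0, got {self.mutation_scale}")
        if not 0 < self.mutation_decay <= 1:
            raise ValueError(f"mutation_decay must lie in (0, 1], got {self.mutation_decay}")
        if self.inner_iterations < 1:
            raise ValueError(f"inner_iterations must be >= 1, got {self.inner_iterations}")

    def member_counts(self) -> tuple[int, int, int]:
        """(n_elite, n_crossover, n_mutation); remainder goes to elites."""
        n_cross = round(self.crossover_frac * self.pop_size)
        n_mut = round(self.mutation_frac * self.pop_size)
        n_elite = self.pop_size - n_cross - n_mut
        if n_elite < 0:
            n_mut += n_elite
            n_elite = 0
        return n_elite, n_cross, n_mut


@dataclass
class Population:
    members: list[Chromosome] = field(default_factory=list)
    generation_index: int = 0
    best_cost_trace: list[float] = field(default_factory=list)

    def sort(self) -> None:
        """Order members by cost, best (lowest) first; unevaluated last."""
        self.members.sort(key=lambda ch: np.inf if ch.cost is None else ch.cost)

    @property
    def best(self) -> Chromosome:
        return min(self.members, key=lambda ch: np.inf if ch.cost is None else ch.cost)


@dataclass
class GAFCMResult:
    """Best-ever chromosome, per-generation best-cost trace, final population,
    and the fully converged FCM state seeded from the best chromosome."""

    best: Chromosome
    best_cost_trace: np.ndarray
    population: Population
    refined: FCMResult


def init_population(params: GAParams, rng: np.random.Generator) -> Population:
    """Draw ``pop_size`` chromosomes with genes uniform on ``gene_range``."""
    lo, hi = params.gene_range
    genes = rng.uniform(lo, hi, size=(params.pop_size, params.chrom_len))
    return Population(members=[Chromosome(g) for g in genes])


def evaluate_fitness(
    chrom: Chromosome,
    image,
    fcm: FCMParams,
    inner_iterations: int = 1,
    refeed: bool = False,
) -> float:
    """FCM cost of the chromosome after a short burst of updates.

    Starting from the chromosome's centers, runs ``inner_iterations``
    membership+centroid update pairs and evaluates J on the updated state.
    A degenerate cluster yields cost +inf (the chromosome ranks last)
    instead of aborting the generation.  The cost is cached on the
    chromosome and returned.

    With ``refeed=True`` the FCM-updated centers are also written back
    into the chromosome (Lamarckian learning): the clustering result
    re-enters the gene pool, so every surviving lineage descends its cost
    basin while crossover and mutation keep exploring between basins.
    The generation loop evaluates with refeeding; a plain call leaves the
    genes untouched and is deterministic in the chromosome.
    """
    cost, new_centers = fitness_burst(image, chrom.genes, fcm.m, inner_iterations)
    if refeed and np.isfinite(cost):
        chrom.genes = new_centers
    chrom.cost = float(cost)
    return chrom.cost


def _evaluate_population(pop: Population, image, ga: GAParams, fcm: FCMParams) -> None:
    for ch in pop.members:
        if ch.cost is None:
            evaluate_fitness(ch, image, fcm, ga.inner_iterations, refeed=True)


def select_parent(pop: Population, rng: np.random.Generator) -> Chromosome:
    """Roulette-wheel selection with weight ``max_cost - cost + eps``.

    Lower cost means a proportionally larger slice of the wheel; the small
    epsilon keeps even the worst finite member selectable.  Members with
    infinite cost get zero weight.
    """
    costs = np.array(
        [np.inf if ch.cost is None else ch.cost for ch in pop.members], dtype=float
    )
    finite = np.isfinite(costs)
    if not finite.any():
        raise SelectionFailureError("no chromosome with finite cost to select from")
    weights = np.zeros_like(costs)
    weights[finite] = costs[finite].max() - costs[finite] + _ROULETTE_EPS
    idx = rng.choice(costs.size, p=weights / weights.sum())
    return pop.members[idx]


def crossover(
    a: Chromosome, b: Chromosome, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Whole-arithmetic crossover: convex mixes with a single alpha ~ U(0,1).

    Each child gene lies between the parental genes, so offspring never
    leave the gene range.
    """
    if a.genes.size != b.genes.size:
        raise ValueError("parents must have equal chromosome length")
    alpha = rng.uniform()
    c1 = alpha * a.genes + (1.0 - alpha) * b.genes
    c2 = (1.0 - alpha) * a.genes + alpha * b.genes
    return Chromosome(c1), Chromosome(c2)


def mutate(
    chrom: Chromosome,
    params: GAParams,
    rng: np.random.Generator,
    scale: float | None = None,
) -> Chromosome:
    """Perturb every gene with zero-mean Gaussian noise, clipped to range.

    ``scale`` overrides ``params.mutation_scale``; the generation loop
    passes the annealed scale ``mutation_scale * mutation_decay**g`` so
    early generations explore and late generations refine.
    """
    if scale is None:
        scale = params.mutation_scale
    genes = chrom.genes.copy()
    if scale > 0:
        genes = genes + rng.normal(0.0, scale, size=genes.size)
        genes = np.clip(genes, *params.gene_range)
    return Chromosome(genes)


def next_generation(
    pop: Population,
    image,
    ga: GAParams,
    fcm: FCMParams,
    rng: np.random.Generator,
) -> Population:
    """Produce and evaluate the next population.

    Composition: the top ``elite_frac`` members unchanged, then
    ``crossover_frac`` offspring of roulette-selected parent pairs, then
    ``mutation_frac`` mutants of selected parents.  Elitism guarantees the
    best cost never increases.
    """
    _evaluate_population(pop, image, ga, fcm)
    pop.sort()
    n_elite, n_cross, n_mut = ga.member_counts()

    members: list[Chromosome] = [
        replace(ch, genes=ch.genes.copy()) for ch in pop.members[:n_elite]
    ]
    offspring: list[Chromosome] = []
    while len(offspring) < n_cross:
        pa = select_parent(pop, rng)
        pb = select_parent(pop, rng)
        offspring.extend(crossover(pa, pb, rng))
    members.extend(offspring[:n_cross])
    scale = ga.mutation_scale * ga.mutation_decay**pop.generation_index
    for _ in range(n_mut):
        members.append(mutate(select_parent(pop, rng), ga, rng, scale=scale))

    nxt = Population(
        members=members,
        generation_index=pop.generation_index + 1,
        best_cost_trace=list(pop.best_cost_trace),
    )
    _evaluate_population(nxt, image, ga, fcm)
    nxt.sort()
    nxt.best_cost_trace.append(nxt.members[0].cost)
    return nxt


def ga_fcm_optimize(
    image,
    ga: GAParams,
    fcm: FCMParams,
    rng: np.random.Generator | None = None,
) -> GAFCMResult:
    """Evolve center vectors against the FCM cost, then polish with full FCM.

    Runs ``ga.generations`` generations from a uniform-random population,
    tracks the per-generation best cost (index 0 is the initial
    population), and finally refines the best-ever chromosome with a full
    alternating-update FCM run, returning that converged state alongside
    the GA history.
    """
    if ga.chrom_len != fcm.n_clusters:
        raise ValueError(
            f"chrom_len={ga.chrom_len} must equal fcm.n_clusters={fcm.n_clusters}"
        )
    if rng is None:
        rng = np.random.default_rng(ga.seed)

    pop = init_population(ga, rng)
    _evaluate_population(pop, image, ga, fcm)
    pop.sort()
    pop.best_cost_trace.append(pop.members[0].cost)

    best = replace(pop.members[0], genes=pop.members[0].genes.copy())
    for _ in range(ga.generations):
        pop = next_generation(pop, image, ga, fcm, rng)
        if pop.members[0].cost < best.cost:
            best = replace(pop.members[0], genes=pop.members[0].genes.copy())

    try:
        refined = fcm_run(image, best.genes, fcm, rng)
    except DegenerateClusterError:
        # degenerate input (e.g. a constant image): crisp assignment starves
        # every other cluster no matter how centers are re-seeded, so report
        # the best chromosome's own state instead of failing the run
        u = update_memberships(image, best.genes, fcm.m)
        refined = FCMResult(
            centers=best.genes.copy(),
            memberships=u,
            cost_trace=np.asarray([best.cost]),
            iterations_run=0,
        )
    return GAFCMResult(
        best=best,
        best_cost_trace=np.asarray(pop.best_cost_trace),
        population=pop,
        refined=refined,
    )
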