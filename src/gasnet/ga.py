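"""Elitist binary genetic algorithm over a seed's candidate genes.

A chromosome is a bit vector over the candidate list; the seed is always an
implicit member. The objective, minimized by the GA, is the negated mutual
information (bits) between the discretized subnetwork activity — the
per-sample mean of member genes' z-scored expression — and the binary
phenotype contrast. Each generation keeps the elite (smallest fitness)
unchanged and refills the population by rank-weighted parent sampling,
uniform crossover, and sparse mutation: a mutated bit becomes 1 with
probability ``1 / (zero_to_one_rate + 1)`` (5% at the default rate of 19),
the sparsity control inherited from binary-GA practice where a larger rate
leaves fewer genes selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .candidates import CandidateSet
from .datatypes import ExpressionMatrix, PhenotypeLabels, ValidationError

_OPTIMA_TOL = 1e-12


@dataclass
class GAConfig:
    """Search parameters.

    population_size : chromosomes per generation (default 200).
    generations : number of generations (default 500; improvements
        typically plateau well before that).
    mutation_rate : per-bit mutation probability (default 0.05).
    zero_to_one_rate : sparsity control; a bit set during initialization
        or mutation is 1 with probability 1/(rate+1) (default 19 -> 5%).
    elite_fraction : fraction of smallest-fitness chromosomes copied
        unchanged into the next generation (default 0.05).
    n_bins : bins for activity discretization, or "auto" for Sturges'
        rule ceil(log2(n_samples)) + 1.
    immigrant_fraction : fraction of each generation replaced by fresh
        random chromosomes (random immigrants). Counters premature
        convergence: the sparse mutation bias means a selected-out gene is
        otherwise very unlikely to re-enter the population.
    crossover : disable to make offspring plain parent copies.
    """

    population_size: int = 200
    generations: int = 500
    mutation_rate: float = 0.05
    zero_to_one_rate: float = 19
    elite_fraction: float = 0.05
    n_bins: Union[int, str] = "auto"
    immigrant_fraction: float = 0.05
    rng_seed: int = 0
    crossover: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.elite_fraction < 1:
            raise ValidationError("elite_fraction must be in (0, 1)")
        if self.population_size < 2 / self.elite_fraction:
            raise ValidationError(
                "population_size must be >= 2/elite_fraction so the elite "
                "holds at least two chromosomes"
            )
        if self.zero_to_one_rate < 1:
            raise ValidationError("zero_to_one_rate must be >= 1")
        if not 0 <= self.mutation_rate <= 1:
            raise ValidationError("mutation_rate must be in [0, 1]")
        if not 0 <= self.immigrant_fraction < 1:
            raise ValidationError("immigrant_fraction must be in [0, 1)")
        if self.generations < 0:
            raise ValidationError("generations must be >= 0")
        if self.n_bins != "auto" and int(self.n_bins) < 1:
            raise ValidationError("n_bins must be >= 1 or 'auto'")

    @property
    def one_probability(self) -> float:
        return 1.0 / (self.zero_to_one_rate + 1.0)

    @property
    def n_elite(self) -> int:
        return max(1, int(self.population_size * self.elite_fraction))


@dataclass
class SubnetworkChromosome:
    """Bit vector over a candidate set; the seed is implicitly selected."""

    candidate_set: CandidateSet
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (len(self.candidate_set),):
            raise ValidationError(
                f"bit vector length {self.bits.shape} does not match the "
                f"candidate list ({len(self.candidate_set)} genes)"
            )

    @property
    def members(self) -> frozenset:
        genes = self.candidate_set.genes
        sel = {genes[i] for i in np.flatnonzero(self.bits)}
        sel.add(self.candidate_set.seed)
        return frozenset(sel)


def subnetwork_activity(expr: ExpressionMatrix,
                        members: Iterable[str]) -> np.ndarray:
    """Per-sample subnetwork activity: mean over members of each gene's
    z-scored expression (a zero-variance gene contributes zeros)."""
    members = sorted(set(members))
    if not members:
        raise ValidationError("member set must be nonempty")
    x = expr.values.loc[members].to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return z.mean(axis=0)


def sturges_bins(n_samples: int) -> int:
    return int(math.ceil(math.log2(n_samples))) + 1


def discretize(values: Sequence[float],
               n_bins: Union[int, str] = "auto") -> np.ndarray:
    """Equal-width binning over [min, max]; a constant vector maps to a
    single bin labelled 0."""
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise ValidationError("values must be finite")
    if n_bins == "auto":
        n_bins = sturges_bins(v.size)
    n_bins = int(n_bins)
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    span = v.max() - v.min()
    if span == 0:
        return np.zeros(v.size, dtype=np.int64)
    idx = np.floor((v - v.min()) / span * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def mutual_information(bins_x: Sequence, labels_y: Sequence) -> float:
    """Plug-in mutual information (bits) of the joint empirical
    distribution of two discrete sequences."""
    x = np.asarray(bins_x)
    y = np.asarray(labels_y)
    if x.size != y.size:
        raise ValidationError("sequences must have equal length")
    if x.size < 2:
        raise ValidationError("need at least two observations")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])))


class FitnessEvaluator:
    """Precomputed machinery for scoring member sets and populations.

    Restricts the expression matrix to the labels' comparison samples,
    z-scores every gene across those samples once, and exposes vectorized
    fitness evaluation: fitness = -MI(discretized activity, phenotype).
    """

    def __init__(self, expr: ExpressionMatrix, labels: PhenotypeLabels,
                 n_bins: Union[int, str] = "auto"):
        labels.validate_against(expr)
        control_s, case_s = labels.comparison_samples()
        self.samples = control_s + case_s
        self.y = np.array([0] * len(control_s) + [1] * len(case_s))
        x = expr.values[self.samples].to_numpy(dtype=float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        self._z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        self._index = {g: i for i, g in enumerate(expr.gene_ids)}
        self.n_bins = (
            sturges_bins(len(self.samples)) if n_bins == "auto" else int(n_bins)
        )
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")

    # -- scalar interface ---------------------------------------------------

    def activity(self, members: Iterable[str]) -> np.ndarray:
        rows = [self._index[g] for g in sorted(set(members))]
        if not rows:
            raise ValidationError("member set must be nonempty")
        return self._z[rows].mean(axis=0)

    def fitness_of_members(self, members: Iterable[str]) -> float:
        bins = discretize(self.activity(members), self.n_bins)
        return -mutual_information(bins, self.y)

    # -- vectorized interface -----------------------------------------------

    def _candidate_rows(self, candidate_set: CandidateSet) -> tuple[np.ndarray, np.ndarray]:
        seed_row = self._z[self._index[candidate_set.seed]]
        cand = np.array(
            [self._index[g] for g in candidate_set.genes], dtype=np.int64
        )
        return seed_row, self._z[cand] if cand.size else self._z[:0]

    def population_activity(self, candidate_set: CandidateSet,
                            bits: np.ndarray) -> np.ndarray:
        seed_row, zc = self._candidate_rows(candidate_set)
        bits = np.asarray(bits, dtype=np.float64)
        sizes = bits.sum(axis=1) + 1.0
        return (seed_row[None, :] + bits @ zc) / sizes[:, None]

    def fitness_of_activities(self, act: np.ndarray,
                              y: Optional[np.ndarray] = None) -> np.ndarray:
        """Row-wise -MI(discretize(activity), phenotype); ``y`` overrides
        the phenotype vector (used by the label-permutation null)."""
        y = self.y if y is None else np.asarray(y)
        n_bins = self.n_bins
        vmin = act.min(axis=1, keepdims=True)
        span = act.max(axis=1, keepdims=True) - vmin
        safe = np.where(span > 0, span, 1.0)
        idx = np.floor((act - vmin) / safe * n_bins).astype(np.int64)
        np.clip(idx, 0, n_bins - 1, out=idx)
        idx[span[:, 0] == 0] = 0
        n_rows, n_samp = act.shape
        code = idx * 2 + y[None, :]
        flat = (np.arange(n_rows)[:, None] * (n_bins * 2) + code).ravel()
        cnt = np.bincount(flat, minlength=n_rows * n_bins * 2).reshape(
            n_rows, n_bins, 2
        )
        pxy = cnt / n_samp
        px = pxy.sum(axis=2, keepdims=True)
        py = pxy.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = pxy * np.log2(pxy / (px * py))
        return -np.nansum(terms, axis=(1, 2))

    def population_fitness(self, candidate_set: CandidateSet,
                           bits: np.ndarray) -> np.ndarray:
        return self.fitness_of_activities(
            self.population_activity(candidate_set, bits)
        )


def fitness(chromosome: SubnetworkChromosome, expr: ExpressionMatrix,
            labels: PhenotypeLabels,
            config: Optional[GAConfig] = None) -> float:
    """Fitness of one chromosome; lower (more negative) is better."""
    config = config or GAConfig()
    ev = FitnessEvaluator(expr, labels, n_bins=config.n_bins)
    return ev.fitness_of_members(chromosome.members)


def init_population(candidate_set: CandidateSet, config: GAConfig,
                    rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Initial population: each bit is 1 with probability
    ``1/(zero_to_one_rate + 1)``."""
    rng = rng or np.random.default_rng(config.rng_seed)
    shape = (config.population_size, len(candidate_set))
    return (rng.random(shape) < config.one_probability).astype(np.uint8)


@dataclass
class GARun:
    """Outcome of one GA search: the final evaluated population and the
    best-fitness trajectory (index 0 = initial population)."""

    candidate_set: CandidateSet
    population: np.ndarray
    fitnesses: np.ndarray
    best_per_generation: np.ndarray
    config: GAConfig
    mean_per_generation: Optional[np.ndarray] = None

    @property
    def best_fitness(self) -> float:
        return float(self.fitnesses.min())

    def optima(self, tol: float = _OPTIMA_TOL) -> list[frozenset]:
        return collect_optima(self, tol=tol)


def _sorted_order(pop: np.ndarray, fit: np.ndarray) -> list[int]:
    """Ascending fitness; ties broken by fewer selected genes, then by
    lexicographic bit pattern, so elitism is fully deterministic."""
    sizes = pop.sum(axis=1)
    return sorted(
        range(len(fit)),
        key=lambda i: (fit[i], sizes[i], pop[i].tobytes()),
    )


def evolve(candidate_set: CandidateSet, expr: ExpressionMatrix,
           labels: PhenotypeLabels, config: Optional[GAConfig] = None,
           evaluator: Optional[FitnessEvaluator] = None) -> GARun:
    """Run the elitist GA for ``config.generations`` generations.

    An empty candidate set degenerates to the seed-only subnetwork with no
    search (the case of seeds with no interacting genes).
    """
    config = config or GAConfig()
    ev = evaluator or FitnessEvaluator(expr, labels, n_bins=config.n_bins)
    L = len(candidate_set)
    rng = np.random.default_rng(config.rng_seed)

    if L == 0:
        f = ev.fitness_of_members({candidate_set.seed})
        return GARun(
            candidate_set=candidate_set,
            population=np.zeros((1, 0), dtype=np.uint8),
            fitnesses=np.array([f]),
            best_per_generation=np.full(config.generations + 1, f),
            config=config,
            mean_per_generation=np.full(config.generations + 1, f),
        )

    pop = init_population(candidate_set, config, rng)
    P = config.population_size
    n_elite = config.n_elite
    n_child = P - n_elite
    # rank-weighted parent probabilities over the rank-sorted population
    weights = np.arange(P, 0, -1, dtype=float)
    weights /= weights.sum()
    best_traj = np.empty(config.generations + 1)
    mean_traj = np.empty(config.generations + 1)

    fit = ev.population_fitness(candidate_set, pop)
    for gen in range(config.generations):
        order = _sorted_order(pop, fit)
        pop = pop[order]
        fit = fit[order]
        best_traj[gen] = fit[0]
        mean_traj[gen] = fit.mean()

        parents = rng.choice(P, size=(n_child, 2), p=weights)
        pa, pb = pop[parents[:, 0]], pop[parents[:, 1]]
        if config.crossover:
            take_a = rng.random((n_child, L)) < 0.5
            children = np.where(take_a, pa, pb)
        else:
            children = pa.copy()
        mut = rng.random((n_child, L)) < config.mutation_rate
        new_bits = (rng.random((n_child, L)) < config.one_probability)
        children = np.where(mut, new_bits, children).astype(np.uint8)
        n_imm = min(int(round(config.immigrant_fraction * P)), n_child)
        if n_imm:
            # immigrant density spans the sparse prior up to half-on, so
            # denser optima stay reachable despite the sparsity bias
            dens = rng.uniform(config.one_probability, 0.5, size=(n_imm, 1))
            children[n_child - n_imm:] = (
                rng.random((n_imm, L)) < dens
            ).astype(np.uint8)

        pop = np.vstack([pop[:n_elite], children])
        child_fit = ev.population_fitness(candidate_set, children)
        fit = np.concatenate([fit[:n_elite], child_fit])

    order = _sorted_order(pop, fit)
    pop = pop[order]
    fit = fit[order]
    best_traj[config.generations] = fit[0]
    mean_traj[config.generations] = fit.mean()
    return GARun(
        candidate_set=candidate_set,
        population=pop,
        fitnesses=fit,
        best_per_generation=best_traj,
        config=config,
        mean_per_generation=mean_traj,
    )


def collect_optima(run: GARun, tol: float = _OPTIMA_TOL) -> list[frozenset]:
    """Distinct member sets in the final population whose fitness equals
    the population minimum (within ``tol``)."""
    fmin = run.fitnesses.min()
    seen: set[frozenset] = set()
    out: list[frozenset] = []
    genes = run.candidate_set.genes
    for row, f in zip(run.population, run.fitnesses):
        if f - fmin <= tol:
            members = frozenset(
                {genes[i] for i in np.flatnonzero(row)}
                | {run.candidate_set.seed}
            )
            if members not in seen:
                seen.add(members)
                out.append(members)
    return sorted(out, key=lambda m: (len(m), sorted(m)))


def exhaustive_search(
    candidate_set: CandidateSet, expr: ExpressionMatrix,
    labels: PhenotypeLabels, n_bins: Union[int, str] = "auto",
    evaluator: Optional[FitnessEvaluator] = None, max_genes: int = 20,
) -> tuple[float, list[frozenset]]:
    """Enumerate every subset of the candidate genes and return the global
    minimum fitness with all member sets attaining it. Only feasible for
    small candidate sets (hard cap ``max_genes``)."""
    L = len(candidate_set)
    if L > max_genes:
        raise ValidationError(
            f"exhaustive search over {L} genes exceeds the cap {max_genes}"
        )
    ev = evaluator or FitnessEvaluator(expr, labels, n_bins=n_bins)
    if L == 0:
        f = ev.fitness_of_members({candidate_set.seed})
        return f, [frozenset({candidate_set.seed})]
    n = 1 << L
    codes = np.arange(n, dtype=np.uint32)
    bits = ((codes[:, None] >> np.arange(L)) & 1).astype(np.uint8)
    fits = np.empty(n)
    chunk = 1 << 14
    for start in range(0, n, chunk):
        fits[start:start + chunk] = ev.population_fitness(
            candidate_set, bits[start:start + chunk]
        )
    fmin = fits.min()
    best = np.flatnonzero(fits - fmin <= _OPTIMA_TOL)
    genes = candidate_set.genes
    sets = {
        frozenset({genes[i] for i in np.flatnonzero(bits[b])}
                  | {candidate_set.seed})
        for b in best
    }
    return float(fmin), sorted(sets, key=lambda m: (len(m), sorted(m)))
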