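"""Core-subnetwork extraction and empirical significance.

A seed's equally-optimal subnetworks are first filtered to those containing
at least one putative driver gene; each remaining gene is then voted on by
its frequency across those subnetworks, and genes at or above the 50%
cutoff form the core. Significance comes from two permutation nulls run
for the core's fitness: shuffled phenotype labels with the members fixed,
and random same-size member sets with the labels fixed. Both p-values use
the add-one estimator, so they can never be zero.
"""

from __future__ import annotations

import itertools
import logging
from math import comb
from typing import Iterable, Optional, Sequence

import numpy as np

from .datatypes import (
    CoreSubnetwork,
    ExpressionMatrix,
    InteractionGraph,
    PhenotypeLabels,
    ValidationError,
)
from .ga import FitnessEvaluator

logger = logging.getLogger(__name__)


def require_driver(subnetworks: Sequence[frozenset],
                   drivers: set[str]) -> list[frozenset]:
    """Keep only member sets containing at least one driver gene."""
    return [s for s in subnetworks if s & drivers]


def gene_frequency(subnetworks: Sequence[frozenset]) -> dict[str, float]:
    """Fraction of subnetworks each gene appears in."""
    if not subnetworks:
        raise ValidationError("cannot compute frequencies over zero subnetworks")
    n = len(subnetworks)
    freq: dict[str, float] = {}
    for s in subnetworks:
        for g in s:
            freq[g] = freq.get(g, 0.0) + 1.0
    return {g: c / n for g, c in freq.items()}


def build_core(
    frequencies: dict[str, float],
    seed: str,
    graph: InteractionGraph,
    drivers: set[str],
    cutoff: float = 0.5,
    n_optima: Optional[int] = None,
) -> Optional[CoreSubnetwork]:
    """Members = genes at or above the frequency cutoff, plus the seed.

    The cutoff is inclusive: the rule removes genes with LOW frequency, so
    a gene sitting exactly at 50% stays. Returns ``None`` when the surviving
    members contain no driver — such a seed yields no core.
    """
    members = {g for g, f in frequencies.items() if f >= cutoff}
    members.add(seed)
    core_drivers = members & drivers
    if not core_drivers:
        return None
    return CoreSubnetwork(
        seed=seed,
        members=frozenset(members),
        drivers=frozenset(core_drivers),
        edges=tuple(graph.induced_edges(members)),
        n_optima=n_optima,
    )


def _p_value(null: np.ndarray, observed: float) -> float:
    """Add-one empirical p; smaller fitness is better, so the extreme tail
    is null <= observed."""
    return float((1 + np.sum(null <= observed)) / (null.size + 1))


def label_permutation_test(
    core: CoreSubnetwork,
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    n_perm: int = 1000,
    rng_seed: int = 0,
    evaluator: Optional[FitnessEvaluator] = None,
) -> float:
    """Empirical p-value of the core's fitness against shuffled phenotype
    labels (members fixed).

    When fewer distinct label assignments than ``n_perm`` exist, the null
    is enumerated exhaustively instead and the p-value is the exact
    fraction of assignments at least as extreme (the identity assignment
    included, so p > 0).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    ev = evaluator or FitnessEvaluator(expr, labels)
    act = ev.activity(core.members)
    observed = ev.fitness_of_activities(act[None, :])[0]
    y = ev.y
    n = y.size
    n_case = int(y.sum())

    n_distinct = comb(n, n_case)
    if n_distinct <= n_perm:
        logger.info(
            "only %d distinct label assignments; enumerating exhaustively",
            n_distinct,
        )
        null = np.empty(n_distinct)
        for i, case_idx in enumerate(
            itertools.combinations(range(n), n_case)
        ):
            y_perm = np.zeros(n, dtype=int)
            y_perm[list(case_idx)] = 1
            null[i] = ev.fitness_of_activities(act[None, :], y=y_perm)[0]
        return float(np.sum(null <= observed) / n_distinct)

    rng = np.random.default_rng(rng_seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = y[rng.permutation(n)]
        null[i] = ev.fitness_of_activities(act[None, :], y=y_perm)[0]
    return _p_value(null, observed)


def random_members_test(
    core: CoreSubnetwork,
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    gene_universe: Iterable[str],
    n_perm: int = 1000,
    rng_seed: int = 0,
    evaluator: Optional[FitnessEvaluator] = None,
) -> float:
    """Empirical p-value of the core's fitness against random member sets
    of the same size drawn from the expressed-gene universe (labels fixed)."""
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    universe = sorted(set(gene_universe))
    k = len(core.members)
    if len(universe) <= k:
        raise ValidationError(
            f"gene universe ({len(universe)}) must exceed the core size ({k})"
        )
    ev = evaluator or FitnessEvaluator(expr, labels)
    observed = ev.fitness_of_members(core.members)
    rng = np.random.default_rng(rng_seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(len(universe), size=k, replace=False)
        null[i] = ev.fitness_of_members(universe[j] for j in draw)
    return _p_value(null, observed)
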