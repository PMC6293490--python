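"""Per-seed candidate gene sets.

For a coding/TF seed the candidate set is the breadth-first ball of radius
<= 3 around the seed, with every edge kind traversable in both directions.
For a lncRNA seed with no curated interactions, the radius-1 shell is the
top-ranked set of putative targets from a tree-ensemble regression of each
target's expression on the lncRNA (GENIE3-style importance), after which
graph expansion continues from those targets.

Unexpressed genes (median abundance below the FPKM threshold) are removed
from the candidate set after traversal; they do not block paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .datatypes import ExpressionMatrix, InteractionGraph, ValidationError


@dataclass(frozen=True)
class CandidateSet:
    """A seed's candidate gene list: the GA chromosome's index space.

    ``genes`` excludes the seed and is lexicographically ordered so that
    chromosome indexing is reproducible across runs and platforms.
    """

    seed: str
    genes: tuple
    radius_used: int

    def __post_init__(self) -> None:
        if self.seed in self.genes:
            raise ValidationError("candidate genes must exclude the seed")
        if list(self.genes) != sorted(set(self.genes)):
            raise ValidationError("candidate genes must be sorted and unique")

    def __len__(self) -> int:
        return len(self.genes)


def bounded_neighborhood(graph: InteractionGraph, seed: str,
                         radius: int = 3) -> set[str]:
    """All nodes within ``radius`` edges of the seed (seed excluded).

    A seed absent from the graph, or with no incident edges, yields the
    empty set.
    """
    if radius < 1:
        raise ValidationError(f"radius must be >= 1, got {radius}")
    if not graph.has_node(seed):
        return set()
    g = graph.to_networkx()
    dist = nx.single_source_shortest_path_length(g, seed, cutoff=radius)
    del dist[seed]
    return set(dist)


def neighborhood_shells(graph: InteractionGraph, seed: str,
                        radius: int = 3) -> dict[str, int]:
    """Like :func:`bounded_neighborhood` but mapping gene -> shell distance."""
    if radius < 1:
        raise ValidationError(f"radius must be >= 1, got {radius}")
    if not graph.has_node(seed):
        return {}
    g = graph.to_networkx()
    dist = nx.single_source_shortest_path_length(g, seed, cutoff=radius)
    del dist[seed]
    return dict(dist)


def rank_lncrna_targets(
    expr: ExpressionMatrix,
    lncrna: str,
    candidate_regulatees: set[str],
    top_k: int = 200,
    rng_seed: int = 0,
    n_coregulators: int = 50,
    n_estimators: int = 100,
) -> list[str]:
    """Rank candidate targets of a lncRNA by regulatory importance.

    Each candidate target's expression is regressed (random forest) on the
    lncRNA plus up to ``n_coregulators`` randomly drawn co-regulator genes;
    the target's score is the lncRNA's share of the forest's feature
    importance. Targets are returned in descending importance order
    (ties broken lexicographically), truncated to ``top_k``.
    """
    if lncrna not in expr.values.index:
        raise ValidationError(f"lncRNA {lncrna!r} absent from expression matrix")
    regulatees = sorted(set(candidate_regulatees) - {lncrna})
    if not regulatees:
        raise ValidationError("no candidate regulatees to rank")
    x_lnc = expr.values.loc[lncrna].to_numpy(dtype=float)
    if np.ptp(x_lnc) == 0:
        raise ValidationError(
            f"lncRNA {lncrna!r} has constant expression; cannot rank targets"
        )
    rng = np.random.default_rng(rng_seed)
    pool = [g for g in expr.gene_ids if g != lncrna]
    importances: dict[str, float] = {}
    for target in regulatees:
        others = [g for g in pool if g != target]
        k = min(n_coregulators, len(others))
        coreg = sorted(rng.choice(len(others), size=k, replace=False))
        features = [lncrna] + [others[i] for i in coreg]
        X = expr.values.loc[features].to_numpy(dtype=float).T
        y = expr.values.loc[target].to_numpy(dtype=float)
        forest = RandomForestRegressor(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(X, y)
        importances[target] = float(forest.feature_importances_[0])
    ranked = sorted(regulatees, key=lambda g: (-importances[g], g))
    return ranked[: min(top_k, len(ranked))]


def build_candidate_set(
    graph: InteractionGraph,
    expr: ExpressionMatrix,
    seed: str,
    radius: int = 3,
    fpkm_threshold: float = 1.0,
    top_k_lnc: int = 200,
    rng_seed: int = 0,
    expand_lnc_shell: bool = True,
    **lnc_kwargs,
) -> CandidateSet:
    """Assemble the candidate set for one seed.

    Coding/TF seeds use graph expansion only. A lncRNA seed without
    curated lnc_target edges gets its radius-1 shell from
    :func:`rank_lncrna_targets` over all expressed genes; expansion then
    continues from that shell through the graph for the remaining radius
    (switched off with ``expand_lnc_shell=False``).
    """
    med = expr.median_per_gene()
    if seed not in med.index or med[seed] < fpkm_threshold:
        raise ValidationError(
            f"seed {seed!r} is unexpressed (median below the FPKM threshold "
            f"{fpkm_threshold}); it would be removed by the expression filter"
        )
    expressed = set(med.index[med >= fpkm_threshold])
    is_lnc = graph.kind_of(seed) == "lncrna" if graph.has_node(seed) else False
    has_curated = bool(graph.out_edges_of_kind(seed, "lnc_target")) if is_lnc else False

    if is_lnc and not has_curated:
        regulatees = expressed - {seed}
        shell1 = set(
            rank_lncrna_targets(
                expr, seed, regulatees, top_k=top_k_lnc, rng_seed=rng_seed,
                **lnc_kwargs,
            )
        )
        ball = set(shell1)
        if expand_lnc_shell and radius > 1:
            for g in shell1:
                if graph.has_node(g):
                    ball |= bounded_neighborhood(graph, g, radius - 1)
        ball.discard(seed)
    else:
        ball = bounded_neighborhood(graph, seed, radius)

    genes = tuple(sorted((ball & expressed) - {seed}))
    return CandidateSet(seed=seed, genes=genes, radius_used=radius)
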