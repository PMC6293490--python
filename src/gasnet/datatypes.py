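"""Domain types for discriminative-subnetwork search.

The central objects are an expression matrix (genes x samples, FPKM-like
abundances), phenotype labels with a designated binary comparison, a typed
heterogeneous interaction graph (undirected protein-protein edges plus
directed TF->target and lncRNA->target edges), a per-gene driver-score table
(CHASM-style: score in [0, 1], empirical p-value), and the core subnetwork
produced for a seed gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NODE_KINDS = frozenset({"coding", "tf", "lncrna"})
EDGE_KINDS = frozenset({"ppi", "tf_target", "lnc_target"})


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of nonnegative abundances (FPKM-like).

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene id, columns by sample id. Finite, >= 0.
    raw_counts : pandas.DataFrame, optional
        Integer read counts aligned to the same gene/sample ordering.
    """

    values: pd.DataFrame
    raw_counts: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups[:5]}")
        if v.shape[1] == 0:
            raise ValidationError("expression matrix has no samples")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            raise ValidationError("expression values must be nonnegative")
        if self.raw_counts is not None:
            c = self.raw_counts
            if not (c.index.equals(v.index) and c.columns.equals(v.columns)):
                raise ValidationError(
                    "raw_counts must share the expression matrix's gene and "
                    "sample ordering"
                )
            carr = c.to_numpy()
            if (carr < 0).any():
                raise ValidationError("raw counts must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def median_per_gene(self) -> pd.Series:
        return self.values.median(axis=1)

    def expressed_genes(self, threshold: float = 1.0) -> list[str]:
        """Genes whose median abundance is >= ``threshold``.

        The complement of the "median FPKM < 1" removal rule, so a gene
        sitting exactly on the threshold is retained.
        """
        med = self.median_per_gene()
        return sorted(med.index[med >= threshold])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:5]}")
        counts = self.raw_counts.loc[list(genes)] if self.raw_counts is not None else None
        return ExpressionMatrix(self.values.loc[list(genes)], counts)


@dataclass
class PhenotypeLabels:
    """Sample -> class assignment plus the (control, case) contrast used
    for the mutual-information fitness."""

    assignments: pd.Series  # index: sample id, value: class label
    comparison: tuple[str, str]  # (control, case)

    def __post_init__(self) -> None:
        if self.assignments.index.has_duplicates:
            raise ValidationError("duplicate sample ids in labels")
        control, case = self.comparison
        counts = self.assignments.value_counts()
        for cls in (control, case):
            if counts.get(cls, 0) < 2:
                raise ValidationError(
                    f"comparison class {cls!r} needs >= 2 samples, "
                    f"got {counts.get(cls, 0)}"
                )

    @property
    def classes(self) -> list[str]:
        return sorted(self.assignments.unique())

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = set(self.assignments.index) - set(expr.sample_ids)
        if missing:
            raise ValidationError(
                f"labeled samples absent from matrix: {sorted(missing)[:5]}"
            )

    def comparison_samples(self) -> tuple[list[str], list[str]]:
        """(control sample ids, case sample ids), in label-file order."""
        control, case = self.comparison
        a = self.assignments
        return (
            list(a.index[a == control]),
            list(a.index[a == case]),
        )

    def samples_of(self, cls: str) -> list[str]:
        a = self.assignments
        return list(a.index[a == cls])


def _canonical_edge(u: str, v: str, kind: str) -> tuple[str, str, str]:
    if kind == "ppi" and v < u:
        return (v, u, kind)
    return (u, v, kind)


@dataclass(frozen=True)
class InteractionGraph:
    """Typed heterogeneous interaction graph.

    Protein-protein edges are undirected (stored with endpoints in
    lexicographic order); TF->target and lncRNA->target edges are directed.
    Neighborhood expansion treats every edge kind as traversable in both
    directions, which maximizes candidate recall around a seed.
    """

    node_kinds: Mapping[str, str]
    edges: frozenset  # of (u, v, kind)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, str]],
        node_kinds: Optional[Mapping[str, str]] = None,
    ) -> "InteractionGraph":
        kinds: dict[str, str] = dict(node_kinds or {})
        for n, k in kinds.items():
            if k not in NODE_KINDS:
                raise ValidationError(f"unknown node kind {k!r} for {n!r}")
        seen: set[tuple[str, str, str]] = set()
        for u, v, kind in edges:
            if kind not in EDGE_KINDS:
                raise ValidationError(f"unknown edge kind {kind!r} on ({u}, {v})")
            if u == v:
                logger.warning("dropping self-loop on %r", u)
                continue
            seen.add(_canonical_edge(u, v, kind))
            # infer node kinds from directed edge sources
            if kind == "tf_target":
                prev = kinds.get(u)
                if prev is not None and prev != "tf":
                    raise ValidationError(
                        f"node {u!r} is a tf_target source but declared {prev!r}"
                    )
                kinds[u] = "tf"
            elif kind == "lnc_target":
                prev = kinds.get(u)
                if prev is not None and prev != "lncrna":
                    raise ValidationError(
                        f"node {u!r} is a lnc_target source but declared {prev!r}"
                    )
                kinds[u] = "lncrna"
        for u, v, _ in seen:
            kinds.setdefault(u, "coding")
            kinds.setdefault(v, "coding")
        return cls(node_kinds=kinds, edges=frozenset(seen))

    @property
    def nodes(self) -> list[str]:
        return sorted(self.node_kinds)

    def kind_of(self, node: str) -> str:
        return self.node_kinds.get(node, "coding")

    def has_node(self, node: str) -> bool:
        return node in self.node_kinds

    def to_networkx(self) -> nx.Graph:
        """Undirected view with an ``kinds`` set attribute per edge
        (used for traversal and GraphML export)."""
        g = nx.Graph()
        for n, k in self.node_kinds.items():
            g.add_node(n, kind=k)
        for u, v, kind in sorted(self.edges):
            if g.has_edge(u, v):
                g[u][v]["kinds"] = ",".join(
                    sorted(set(g[u][v]["kinds"].split(",")) | {kind})
                )
            else:
                g.add_edge(u, v, kinds=kind)
        return g

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for u, v, _ in self.edges:
            if u == node:
                out.add(v)
            elif v == node:
                out.add(u)
        return out

    def out_edges_of_kind(self, node: str, kind: str) -> list[tuple[str, str, str]]:
        return [e for e in self.edges if e[0] == node and e[2] == kind]

    def induced_edges(self, members: Iterable[str]) -> list[tuple[str, str, str]]:
        m = set(members)
        return sorted(e for e in self.edges if e[0] in m and e[1] in m)


@dataclass
class DriverTable:
    """Per-gene driver score (0 = likely passenger, 1 = likely driver) and
    the empirical p-value that a passenger is misclassified as a driver."""

    table: pd.DataFrame  # index: gene, columns: score, p_value

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValidationError("duplicate genes in driver table")
        for col in ("score", "p_value"):
            if col not in t.columns:
                raise ValidationError(f"driver table missing column {col!r}")
        s = t["score"].to_numpy(dtype=float)
        p = t["p_value"].to_numpy(dtype=float)
        if ((s < 0) | (s > 1)).any():
            raise ValidationError("driver scores must lie in [0, 1]")
        if ((p <= 0) | (p > 1)).any():
            raise ValidationError("driver p-values must lie in (0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)


# Differential-expression results are carried as a DataFrame with one row
# per gene record and these columns.
DE_COLUMNS = ("gene", "log2_fc", "p_value", "fdr")


@dataclass(frozen=True)
class CoreSubnetwork:
    """A seed's consensus subnetwork after the driver filter and the
    gene-frequency vote, with its fitness (negated mutual information,
    bits; lower is better) and two empirical p-values."""

    seed: str
    members: frozenset
    drivers: frozenset
    fitness: Optional[float] = None
    p_label_perm: Optional[float] = None
    p_random_members: Optional[float] = None
    edges: tuple = ()
    n_optima: Optional[int] = None

    def __post_init__(self) -> None:
        if self.seed not in self.members:
            raise ValidationError("core must contain its seed")
        if not self.drivers <= self.members:
            raise ValidationError("core drivers must be members")

    @property
    def size(self) -> int:
        return len(self.members)

    def with_stats(self, **kw) -> "CoreSubnetwork":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "members": sorted(self.members),
            "drivers": sorted(self.drivers),
            "fitness": self.fitness,
            "p_label_perm": self.p_label_perm,
            "p_random_members": self.p_random_members,
            "edges": [list(e) for e in self.edges],
            "n_optima": self.n_optima,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoreSubnetwork":
        return cls(
            seed=d["seed"],
            members=frozenset(d["members"]),
            drivers=frozenset(d["drivers"]),
            fitness=d.get("fitness"),
            p_label_perm=d.get("p_label_perm"),
            p_random_members=d.get("p_random_members"),
            edges=tuple(tuple(e) for e in d.get("edges", [])),
            n_optima=d.get("n_optima"),
        )
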