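"""Readers and writers for the tool's plain-text interchange formats.

All artifacts are tab/whitespace-separated text with ``#`` comment lines,
so externally produced tables (edgeR differential-expression output,
CHASM driver scores) can be dropped in at the documented interfaces.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import pandas as pd

from .datatypes import (
    DE_COLUMNS,
    CoreSubnetwork,
    DriverTable,
    ExpressionMatrix,
    InteractionGraph,
    PhenotypeLabels,
    ValidationError,
)


class ParseError(ValueError):
    """Raised when a text artifact cannot be parsed."""


def _read_table(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", **kw)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty or comment-only file") from exc


def read_expression(path, counts_path=None) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids).

    Raises :class:`ParseError` naming the offending row/column on a
    malformed numeric cell, and :class:`ValidationError` on duplicate ids.
    """
    df = _read_table(path, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns")
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = bad.index[bad.to_numpy().argmax()]
            raise ParseError(
                f"{path}: malformed numeric cell at gene {gene!r}, "
                f"sample {col!r}: {df.loc[gene, col]!r}"
            )
        out[col] = converted
    values = pd.DataFrame(out, index=df.index)
    counts = None
    if counts_path is not None:
        counts = _read_table(counts_path, index_col=0).astype(float)
        counts = counts.loc[values.index, values.columns]
    return ExpressionMatrix(values, counts)


def write_expression(expr: ExpressionMatrix, path, counts_path=None,
                     header_comments: Sequence[str] = ()) -> None:
    _write_tsv(expr.values, path, header_comments, index_label="gene")
    if counts_path is not None and expr.raw_counts is not None:
        _write_tsv(expr.raw_counts, counts_path, header_comments,
                   index_label="gene")


def read_labels(path, comparison: Optional[tuple[str, str]] = None) -> PhenotypeLabels:
    """Read a 2-column (sample, class) TSV.

    If ``comparison`` is not given, the first two distinct class labels in
    file order become (control, case).
    """
    df = _read_table(path, header=0, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected 2 columns (sample, class)")
    assignments = pd.Series(
        df.iloc[:, 1].to_numpy(), index=pd.Index(df.iloc[:, 0], name="sample")
    )
    if comparison is None:
        distinct = list(dict.fromkeys(assignments))
        if len(distinct) < 2:
            raise ValidationError(f"{path}: need >= 2 classes")
        comparison = (distinct[0], distinct[1])
    return PhenotypeLabels(assignments, comparison)


def write_labels(labels: PhenotypeLabels, path,
                 header_comments: Sequence[str] = ()) -> None:
    df = labels.assignments.rename("class").rename_axis("sample").reset_index()
    _write_tsv(df, path, header_comments, index=False)


def read_graph(path, node_kinds=None) -> InteractionGraph:
    """Read a 3-column (u, v, kind) edge list.

    Whitespace- or tab-separated; ``#`` starts a comment. Reversed
    duplicate PPI lines collapse onto one undirected edge; self-loops are
    dropped with a warning.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 fields (u, v, kind), "
                    f"got {len(parts)}"
                )
            edges.append(tuple(parts))
    return InteractionGraph.from_edges(edges, node_kinds=node_kinds)


def write_graph(graph: InteractionGraph, path,
                header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        for u, v, kind in sorted(graph.edges):
            fh.write(f"{u}\t{v}\t{kind}\n")


def export_graphml(graph: InteractionGraph, path) -> None:
    """GraphML export of the undirected view, for network viewers."""
    nx.write_graphml(graph.to_networkx(), path)


def read_drivers(path) -> DriverTable:
    df = _read_table(path, header=0, dtype={0: str})
    if df.shape[1] < 3:
        raise ParseError(f"{path}: expected 3 columns (gene, score, p)")
    df = df.iloc[:, :3]
    df.columns = ["gene", "score", "p_value"]
    return DriverTable(df.set_index("gene").astype(float))


def write_drivers(drivers: DriverTable, path,
                  header_comments: Sequence[str] = ()) -> None:
    _write_tsv(drivers.table, path, header_comments, index_label="gene")


def read_de_table(path) -> pd.DataFrame:
    df = _read_table(path, header=0, dtype={0: str})
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing DE columns {sorted(missing)}")
    return df[list(DE_COLUMNS)]


def write_de_table(de: pd.DataFrame, path,
                   header_comments: Sequence[str] = ()) -> None:
    _write_tsv(de[list(DE_COLUMNS)], path, header_comments, index=False)


def core_summary_frame(cores: Sequence[CoreSubnetwork]) -> pd.DataFrame:
    rows = []
    for c in cores:
        rows.append(
            {
                "seed": c.seed,
                "size": c.size,
                "n_optima": c.n_optima,
                "fitness": c.fitness,
                "p_label_perm": c.p_label_perm,
                "p_random_members": c.p_random_members,
                "drivers": ",".join(sorted(c.drivers)),
                "members": ",".join(sorted(c.members)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "seed", "size", "n_optima", "fitness",
            "p_label_perm", "p_random_members", "drivers", "members",
        ],
    )


def write_subnetworks(cores: Sequence[CoreSubnetwork], out_dir,
                      header_comments: Sequence[str] = ()) -> None:
    """Write per-core edge lists, a summary table, and a JSON dump that
    round-trips losslessly through :func:`read_subnetworks`."""
    if not cores:
        raise ValidationError("no core subnetworks to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for c in cores:
        with open(out_dir / f"core_{c.seed}.edges.tsv", "w") as fh:
            for comment in header_comments:
                fh.write(f"# {comment}\n")
            fh.write(f"# seed: {c.seed}\n")
            for u, v, kind in c.edges:
                fh.write(f"{u}\t{v}\t{kind}\n")
    _write_tsv(core_summary_frame(cores), out_dir / "core_summary.tsv",
               header_comments, index=False)
    with open(out_dir / "cores.json", "w") as fh:
        json.dump([c.to_dict() for c in cores], fh, indent=1)


def read_subnetworks(out_dir) -> list[CoreSubnetwork]:
    with open(Path(out_dir) / "cores.json") as fh:
        return [CoreSubnetwork.from_dict(d) for d in json.load(fh)]


def _write_tsv(df: pd.DataFrame, path, header_comments: Sequence[str] = (),
               index: bool = True, index_label=None) -> None:
    os.makedirs(Path(path).parent, exist_ok=True)
    with open(path, "w") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)
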