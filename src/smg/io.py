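"""Reading and writing tables, matrices, graphs and reports.

Abundance tables are delimited text with taxa as rows: the first column
holds taxon identifiers and the header row holds sample identifiers.
Distance matrices are square TSV with taxon identifiers on both axes.
Graphs are written as edge-list TSV (and optionally GraphML); graph
differences as edge-list TSV plus a one-line JSON summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .core import validate_table
from .graph import GraphDiff, canonical_edge, connected_components

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_edge_list",
    "write_graphml",
    "write_components",
    "write_graph_diff",
]

_SEPS = {".tsv": "\t", ".tab": "\t", ".txt": "\t", ".csv": ","}


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return {"tsv": "\t", "csv": ","}[fmt]
    return _SEPS.get(path.suffix.lower(), "\t")


def read_abundance_table(
    path, fmt: str | None = None, transpose: bool = False
) -> pd.DataFrame:
    """Read a taxa x samples abundance table from TSV/CSV.

    Parameters
    ----------
    path : path-like
        Input file; the delimiter is inferred from the extension
        (``.csv`` -> comma, otherwise tab) unless ``fmt`` is given.
    fmt : {'tsv', 'csv'}, optional
        Explicit delimiter choice.
    transpose : bool, default False
        Set when the file stores samples as rows instead of taxa.

    Raises
    ------
    ValueError
        On duplicate taxon identifiers, missing cells or negative values
        (the offending taxon/sample is named).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path, fmt), index_col=0)
    except Exception as exc:  # surface parser context with the filename
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return validate_table(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_abundance_table(table: pd.DataFrame, path, fmt: str | None = None) -> None:
    path = Path(path)
    table.to_csv(path, sep=_sep_for(path, fmt), index_label="taxon")


def write_distance_matrix(dm: pd.DataFrame, path) -> None:
    """Write a square distance matrix as TSV with taxon ids on both axes."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dm.to_csv(path, sep="\t", index_label="taxon")


def read_distance_matrix(path) -> pd.DataFrame:
    dm = pd.read_csv(path, sep="\t", index_col=0)
    dm.index = dm.index.astype(str)
    dm.columns = dm.columns.astype(str)
    return dm


def write_edge_list(g: nx.Graph, path) -> None:
    """Edge-list TSV: taxonA, taxonB, distance (lexicographic edge order)."""
    rows = []
    for u, v, data in g.edges(data=True):
        a, b = canonical_edge(u, v)
        rows.append((a, b, data.get("distance", "")))
    rows.sort(key=lambda r: (str(r[0]), str(r[1])))
    with open(path, "w") as fh:
        fh.write("taxonA\ttaxonB\tdistance\n")
        for a, b, d in rows:
            fh.write(f"{a}\t{b}\t{d}\n")


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def write_components(g: nx.Graph, path) -> None:
    """Component membership TSV: taxon, component_id."""
    with open(path, "w") as fh:
        fh.write("taxon\tcomponent_id\n")
        for k, comp in enumerate(connected_components(g)):
            for taxon in sorted(comp, key=str):
                fh.write(f"{taxon}\t{k}\n")


def write_graph_diff(diff: GraphDiff, edge_path, summary_path) -> None:
    """Changed-edge TSV plus a one-line JSON summary {magnitude, n_vertices}."""
    with open(edge_path, "w") as fh:
        fh.write("taxonA\ttaxonB\n")
        for a, b in sorted(diff.changed_edges, key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{a}\t{b}\n")
    with open(summary_path, "w") as fh:
        json.dump({"magnitude": diff.magnitude, "n_vertices": len(diff.vertices)}, fh)
        fh.write("\n")
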