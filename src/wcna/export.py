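"""Edge-list and matrix export in Cytoscape-friendly formats."""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError
from .modules import GREY, ModuleAssignment
from .network import AdjacencyMatrix, TOMMatrix

__all__ = ["edge_table", "export_edge_list", "write_matrix_tsv", "read_matrix_tsv"]

FORMATS = ("tsv", "sif", "graphml")


def edge_table(
    m: TOMMatrix | AdjacencyMatrix, threshold: float = 0.10
) -> pd.DataFrame:
    """One row per unordered pair with weight >= threshold, full precision."""
    ids = list(m.feature_ids)
    vals = m.values
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            w = float(vals[i, j])
            if w >= threshold:
                rows.append({"source": ids[i], "target": ids[j], "weight": w})
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


def export_edge_list(
    m: TOMMatrix | AdjacencyMatrix,
    path: str | Path,
    threshold: float = 0.10,
    fmt: str = "tsv",
    assign: ModuleAssignment | None = None,
) -> pd.DataFrame:
    """Write the thresholded edge list; returns the edge table.

    ``tsv``: source/target/weight columns plus a ``<path>.nodes.tsv``
    companion with module colors.  ``sif``: Cytoscape SIF plus the same
    node-attribute companion.  ``graphml``: single file with ``module``
    node attributes and ``weight`` edge attributes.
    """
    if fmt not in FORMATS:
        raise InputError(f"unknown edge format {fmt!r}; choose from {FORMATS}")
    path = Path(path)
    edges = edge_table(m, threshold)
    colors = {
        f: (assign.labels.get(f, GREY) if assign is not None else GREY)
        for f in m.feature_ids
    }
    if fmt == "tsv":
        edges.to_csv(path, sep="\t", index=False, float_format="%.17g")
        _write_nodes(path, colors)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for _, row in edges.iterrows():
                fh.write(f"{row['source']}\tco\t{row['target']}\n")
        _write_nodes(path, colors)
    else:  # graphml
        g = nx.Graph()
        for f in m.feature_ids:
            g.add_node(f, module=colors[f])
        for _, row in edges.iterrows():
            g.add_edge(row["source"], row["target"], weight=float(row["weight"]))
        nx.write_graphml(g, path)
    return edges


def _write_nodes(edge_path: Path, colors: dict[str, str]) -> None:
    node_path = edge_path.with_suffix(edge_path.suffix + ".nodes.tsv")
    pd.Series(colors, name="module").rename_axis("feature").to_csv(
        node_path, sep="\t"
    )


def write_matrix_tsv(m, path: str | Path) -> None:
    """Labeled square matrix at full precision (exact text round-trip)."""
    m.to_frame().to_csv(path, sep="\t", float_format="%.17g", index_label="feature")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if frame.shape[0] != frame.shape[1]:
        raise InputError(f"{path} is not a square labeled matrix")
    return frame
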