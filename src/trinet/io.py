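"""Reading and writing expression matrices and networks.

Expression input is a delimited text table with gene identifiers in the
first column and sample identifiers in the header row.  Networks are written
as a two-column edge list, SIF (``source<TAB>regulates<TAB>target``; isolated
nodes as bare lines) or GraphML.  Edge-list and SIF output is sorted
lexicographically by (source, target) so diffs are reproducible.

No delimiter guessing is performed: the delimiter is an explicit argument.
"""

from __future__ import annotations

import os
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .core import DirectedNetwork, ExpressionMatrix
from .errors import FormatError, ValidationError

__all__ = [
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "NETWORK_FORMATS",
]

NETWORK_FORMATS = ("edge-list", "sif", "graphml")

_SIF_RELATION = "regulates"


def read_expression(path: str, delimiter: str = "\t") -> ExpressionMatrix:
    """Load a genes x samples table.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValidationError
        On duplicate gene ids (named in the message) or non-numeric /
        missing cells (with row and column coordinates).
    """
    raw = pd.read_csv(path, sep=delimiter, index_col=0, header=0, dtype=str)
    gene_ids = [str(g) for g in raw.index]
    dupes = raw.index[raw.index.duplicated()]
    if len(dupes):
        raise ValidationError(f"duplicate gene id {str(dupes[0])!r} in {path}")
    values = np.empty(raw.shape, dtype=float)
    cols = [str(c) for c in raw.columns]
    cells = raw.to_numpy(dtype=object)
    for j, col in enumerate(cols):
        for i, gene in enumerate(gene_ids):
            cell = cells[i, j]
            # float() rather than pandas' fast parser: correctly rounded,
            # so write_expression -> read_expression is exact
            try:
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    raise ValueError("missing")
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-numeric or missing cell at gene {gene!r}, "
                    f"sample {col!r} (value {cell!r}) in {path}"
                ) from None
    return ExpressionMatrix(gene_ids, values, cols)


def write_expression(
    matrix: ExpressionMatrix, path: str, delimiter: str = "\t"
) -> None:
    """Write a matrix so that :func:`read_expression` recovers it exactly."""
    frame = matrix.to_frame()
    frame.to_csv(path, sep=delimiter, index_label="gene", float_format="%.17g")


def write_network(net: DirectedNetwork, path: str, format: str = "sif") -> None:
    """Write ``net`` in one of the supported formats.

    ``edge-list`` keeps edges only; ``sif`` and ``graphml`` also preserve
    isolated nodes.  Reading the file back yields an equal edge set.
    """
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise FormatError(
            f"unknown network format {format!r}; choose from {NETWORK_FORMATS}"
        )
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
        return
    lines = []
    if fmt == "sif":
        linked = {u for e in net.edges for u in e}
        for u, v in net.sorted_edges():
            lines.append(f"{u}\t{_SIF_RELATION}\t{v}")
        for node in net.nodes:
            if node not in linked:
                lines.append(node)
    else:  # edge-list
        for u, v in net.sorted_edges():
            lines.append(f"{u}\t{v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
        if lines:
            fh.write("\n")


def read_network(path: str, format: Optional[str] = None) -> DirectedNetwork:
    """Read a network written by :func:`write_network`.

    If ``format`` is None it is inferred from the file extension
    (``.sif``, ``.graphml``; anything else is treated as an edge list).
    The returned network permits cycles (``acyclic_required=False``).
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".sif": "sif", ".graphml": "graphml"}.get(ext, "edge-list")
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise FormatError(
            f"unknown network format {format!r}; choose from {NETWORK_FORMATS}"
        )
    if fmt == "graphml":
        g = nx.read_graphml(path)
        return DirectedNetwork(
            (str(n) for n in g.nodes()),
            ((str(u), str(v)) for u, v in g.edges()),
            acyclic_required=False,
        )
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []

    def _add_node(name: str) -> None:
        if name not in seen:
            seen.add(name)
            nodes.append(name)

    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if fmt == "sif":
                if len(parts) == 1:
                    _add_node(parts[0])
                    continue
                if len(parts) != 3:
                    raise FormatError(
                        f"{path}:{lineno}: expected 1 or 3 tab-separated "
                        f"fields in SIF, got {len(parts)}"
                    )
                u, _, v = parts
            else:
                if len(parts) != 2:
                    raise FormatError(
                        f"{path}:{lineno}: expected 2 tab-separated fields "
                        f"in edge list, got {len(parts)}"
                    )
                u, v = parts
            _add_node(u)
            _add_node(v)
            edges.append((u, v))
    return DirectedNetwork(nodes, edges, acyclic_required=False)
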