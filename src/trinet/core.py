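"""Core containers: expression matrices and directed gene networks.

An :class:`ExpressionMatrix` holds continuous expression values for
``n_genes`` genes across ``n_samples`` independent samples (time points are
treated as i.i.d. observations).  A :class:`DirectedNetwork` is a set of
genes plus directed regulatory edges; during Bayesian scoring the structure
must be acyclic, while the final united network may contain cycles, so
acyclicity is a per-instance flag rather than a class property.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CyclicNetworkError, UnknownGeneError, ValidationError

__all__ = ["ExpressionMatrix", "DirectedNetwork", "is_acyclic"]


def is_acyclic(nodes: Sequence[str], edges: Iterable[tuple[str, str]]) -> bool:
    """Kahn's algorithm: True iff the directed graph has no cycle."""
    indeg = {v: 0 for v in nodes}
    children: dict[str, list[str]] = {v: [] for v in nodes}
    n_edges = 0
    for u, v in edges:
        children[u].append(v)
        indeg[v] += 1
        n_edges += 1
    queue = deque(v for v in nodes if indeg[v] == 0)
    seen = 0
    while queue:
        u = queue.popleft()
        seen += 1
        for w in children[u]:
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
    return seen == len(indeg)


@dataclass(frozen=True)
class DirectedNetwork:
    """A directed network over named genes.

    Parameters
    ----------
    nodes
        Ordered gene identifiers; the order fixes pair indexing everywhere.
    edges
        Ordered ``(source, target)`` pairs.  At most one entry per ordered
        pair (enforced by the set representation); self-loops are rejected.
    acyclic_required
        If True (the default, suitable for Bayesian scoring) the edge set
        must be acyclic; construction fails otherwise.  The united output
        network sets this to False because edge-wise voting can produce
        directed cycles.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    acyclic_required: bool = True

    def __init__(
        self,
        nodes: Iterable[str],
        edges: Iterable[tuple[str, str]] = (),
        acyclic_required: bool = True,
    ):
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(
            self, "edges", frozenset((str(u), str(v)) for u, v in edges)
        )
        object.__setattr__(self, "acyclic_required", bool(acyclic_required))
        self._validate()

    def _validate(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("duplicate node identifiers")
        node_set = set(self.nodes)
        for u, v in self.edges:
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            if u not in node_set or v not in node_set:
                raise ValidationError(f"edge ({u!r}, {v!r}) uses unknown node")
        if self.acyclic_required and not is_acyclic(self.nodes, self.edges):
            raise CyclicNetworkError(
                "edge set contains a directed cycle but acyclic_required=True"
            )

    # -- convenience -------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, source: str, target: str) -> bool:
        return (source, target) in self.edges

    def parents(self, node: str) -> frozenset[str]:
        return frozenset(u for u, v in self.edges if v == node)

    def sorted_edges(self) -> list[tuple[str, str]]:
        """Edges sorted lexicographically by (source, target)."""
        return sorted(self.edges)

    def is_acyclic(self) -> bool:
        return is_acyclic(self.nodes, self.edges)

    def relabel(self, mapping: Mapping[str, str]) -> "DirectedNetwork":
        """Consistently rename genes; the mapping must cover every node."""
        return DirectedNetwork(
            (mapping[v] for v in self.nodes),
            ((mapping[u], mapping[v]) for u, v in self.edges),
            acyclic_required=self.acyclic_required,
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.sorted_edges())
        return g


class ExpressionMatrix:
    """Continuous gene-expression values, genes in rows, samples in columns.

    All values must be finite; at least two samples are required because the
    Gaussian score needs a non-degenerate scatter matrix.
    """

    def __init__(
        self,
        gene_ids: Iterable[str],
        values: np.ndarray,
        sample_ids: Iterable[str],
    ):
        self.gene_ids: tuple[str, ...] = tuple(str(g) for g in gene_ids)
        self.sample_ids: tuple[str, ...] = tuple(str(s) for s in sample_ids)
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        if arr.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {arr.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValidationError(f"duplicate gene id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample id {dup!r}")
        if len(self.sample_ids) < 2:
            raise ValidationError("at least two samples are required")
        if not np.all(np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        arr = arr.copy()
        arr.setflags(write=False)
        self.values: np.ndarray = arr
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self._index[gene]]
        except KeyError:
            raise UnknownGeneError(gene) from None

    def subset(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Rows for ``genes`` in the given order (samples unchanged)."""
        try:
            idx = [self._index[g] for g in genes]
        except KeyError as exc:
            raise UnknownGeneError(exc.args[0]) from None
        return ExpressionMatrix(genes, self.values[idx], self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            (str(g) for g in frame.index),
            frame.to_numpy(dtype=float),
            (str(s) for s in frame.columns),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return (
            f"ExpressionMatrix(n_genes={self.n_genes}, "
            f"n_samples={self.n_samples})"
        )


def _trusted_network(
    nodes: tuple[str, ...],
    edges: frozenset[tuple[str, str]],
    acyclic_required: bool,
) -> DirectedNetwork:
    """Internal constructor skipping validation for networks whose
    invariants are guaranteed by construction (e.g. enumeration output)."""
    net = object.__new__(DirectedNetwork)
    object.__setattr__(net, "nodes", nodes)
    object.__setattr__(net, "edges", edges)
    object.__setattr__(net, "acyclic_required", acyclic_required)
    return net


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""
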