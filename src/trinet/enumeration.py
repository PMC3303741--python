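"""Exhaustive enumeration and ranking of candidate networks on small gene sets.

Every unordered gene pair (i, j), i < j in node order, takes one of three
edge states — forward (i -> j), backward (j -> i) or absent — so a set of n
genes admits ``3 ** C(n, 2)`` candidate configurations (27 for a triplet,
59049 for five genes).  Configurations are enumerated in a fixed
lexicographic order (pair index major; state order forward < backward <
absent) so that ranks are bit-reproducible.  Cyclic configurations are
enumerated, to keep the candidate-space counts honest, but only the acyclic
subset is scoreable and rankable (25 of 27 triplet configurations; 29281 of
59049 five-gene configurations).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import IntEnum
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np

from .core import DirectedNetwork, ExpressionMatrix, _trusted_network
from .errors import ValidationError
from .scoring import BGeScorer, ScoreParams

__all__ = [
    "EdgeState",
    "ScoredNetwork",
    "enumerate_configurations",
    "enumerate_dags",
    "rank_candidates",
    "n_configurations",
    "n_dags",
    "MIN_NODES",
    "MAX_NODES",
]

MIN_NODES = 2
MAX_NODES = 6


class EdgeState(IntEnum):
    """State of an unordered gene pair (i, j) with i < j in node order."""

    FORWARD = 0   # i -> j
    BACKWARD = 1  # j -> i
    ABSENT = 2


@dataclass(frozen=True)
class ScoredNetwork:
    """The tuple (network, score, rank) produced by exhaustive search.

    ``log_score`` is the log network score; ``rank`` is 1-based, rank 1
    holding the maximal score, ties broken by enumeration order.
    """

    network: DirectedNetwork
    log_score: float
    rank: int


@lru_cache(maxsize=None)
def _pairs(n: int) -> tuple[tuple[int, int], ...]:
    return tuple(itertools.combinations(range(n), 2))


def _check_n(n: int) -> None:
    if not MIN_NODES <= n <= MAX_NODES:
        raise ValidationError(
            f"enumeration supports {MIN_NODES}..{MAX_NODES} nodes, got {n}"
        )


def n_configurations(n: int) -> int:
    """Number of candidate configurations on n nodes: 3 ** C(n, 2)."""
    _check_n(n)
    return 3 ** (n * (n - 1) // 2)


@lru_cache(maxsize=3)
def _dag_table(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(config_states, dag_config_indices, dag_parent_masks) for n <= 5.

    config_states: (3**P, P) uint8 states in enumeration order.
    dag_config_indices: indices of acyclic configurations.
    dag_parent_masks: (n_dags, n) int16 parent bitmasks.
    """
    pairs = _pairs(n)
    P = len(pairs)
    states = np.array(
        list(itertools.product((0, 1, 2), repeat=P)), dtype=np.uint8
    )
    n_cfg = states.shape[0]
    adj = np.zeros((n_cfg, n, n), dtype=np.uint8)
    parent_masks = np.zeros((n_cfg, n), dtype=np.int16)
    for p, (i, j) in enumerate(pairs):
        fwd = states[:, p] == EdgeState.FORWARD
        bwd = states[:, p] == EdgeState.BACKWARD
        adj[fwd, i, j] = 1
        adj[bwd, j, i] = 1
        parent_masks[fwd, j] |= 1 << i
        parent_masks[bwd, i] |= 1 << j
    # reachability closure: (I + A)^(n-1); a graph is cyclic iff two distinct
    # nodes reach each other
    reach = adj.astype(np.int64) + np.eye(n, dtype=np.int64)
    closure = np.broadcast_to(np.eye(n, dtype=np.int64), reach.shape).copy()
    for _ in range(n - 1):
        closure = np.minimum(closure @ reach, 1)
    mutual = closure & closure.transpose(0, 2, 1)
    off_diag = ~np.eye(n, dtype=bool)
    acyclic = ~(mutual[:, off_diag].any(axis=1))
    dag_idx = np.flatnonzero(acyclic)
    return states, dag_idx, parent_masks[dag_idx]


def n_dags(n: int) -> int:
    """Number of acyclic configurations (labeled DAGs) on n nodes."""
    _check_n(n)
    if n <= 5:
        return len(_dag_table(n)[1])
    return sum(1 for _ in enumerate_dags([str(i) for i in range(n)]))


def _network_from_states(
    nodes: Sequence[str],
    pairs: Sequence[tuple[int, int]],
    states: Sequence[int],
    acyclic_required: bool,
    trusted: bool = False,
) -> DirectedNetwork:
    edges = []
    for (i, j), s in zip(pairs, states):
        if s == 0:  # forward
            edges.append((nodes[i], nodes[j]))
        elif s == 1:  # backward
            edges.append((nodes[j], nodes[i]))
    if trusted:
        # enumeration guarantees the invariants; skip re-validation
        return _trusted_network(tuple(nodes), frozenset(edges), acyclic_required)
    return DirectedNetwork(nodes, edges, acyclic_required=acyclic_required)


def enumerate_configurations(nodes: Sequence[str]) -> Iterator[DirectedNetwork]:
    """Yield all 3**C(n,2) candidate networks, cyclic ones included."""
    nodes = list(nodes)
    _check_n(len(nodes))
    pairs = _pairs(len(nodes))
    for states in itertools.product(
        (EdgeState.FORWARD, EdgeState.BACKWARD, EdgeState.ABSENT),
        repeat=len(pairs),
    ):
        yield _network_from_states(nodes, pairs, states, acyclic_required=False)


def enumerate_dags(nodes: Sequence[str]) -> Iterator[DirectedNetwork]:
    """Yield exactly the acyclic configurations, in enumeration order."""
    for net in enumerate_configurations(nodes):
        if net.is_acyclic():
            yield DirectedNetwork(net.nodes, net.edges, acyclic_required=True)


def rank_candidates(
    nodes: Sequence[str],
    data: ExpressionMatrix,
    params: ScoreParams | None = None,
) -> list[ScoredNetwork]:
    """Score every DAG on ``nodes`` and rank them by descending log score.

    The scoring scope is exactly ``nodes`` (the matrix is subset first, so
    hyperparameter defaults resolve against the candidate gene set).  Ties
    are broken by enumeration order; the result is a permutation of
    :func:`enumerate_dags`.
    """
    nodes = list(nodes)
    n = len(nodes)
    _check_n(n)
    scorer = BGeScorer(data.subset(nodes), params)
    pairs = _pairs(n)

    if n <= 5:
        states, dag_idx, parent_masks = _dag_table(n)
        table = np.full((n, 1 << n), np.nan)
        for v in range(n):
            for mask in range(1 << n):
                if not mask >> v & 1:
                    table[v, mask] = scorer.node_score_masked(v, mask)
        scores = np.zeros(len(dag_idx))
        for v in range(n):
            scores += table[v, parent_masks[:, v]]
        order = np.argsort(-scores, kind="stable")
        out = []
        node_tuple = tuple(nodes)
        for r, pos in enumerate(order, start=1):
            net = _network_from_states(
                node_tuple,
                pairs,
                states[dag_idx[pos]],
                acyclic_required=True,
                trusted=True,
            )
            out.append(ScoredNetwork(net, float(scores[pos]), r))
        return out

    # n == 6: enumerate lazily (3^15 configurations) and score the DAGs
    scored: list[tuple[float, int, DirectedNetwork]] = []
    for idx, net in enumerate(enumerate_dags(nodes)):
        scored.append((scorer.network_score(net), idx, net))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [
        ScoredNetwork(net, s, r)
        for r, (s, _, net) in enumerate(scored, start=1)
    ]


def pair_state(net: DirectedNetwork, i: int, j: int) -> EdgeState:
    """Edge state of the unordered pair (nodes[i], nodes[j]), i < j."""
    u, v = net.nodes[i], net.nodes[j]
    if net.has_edge(u, v):
        return EdgeState.FORWARD
    if net.has_edge(v, u):
        return EdgeState.BACKWARD
    return EdgeState.ABSENT
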