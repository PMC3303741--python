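"""Greedy hill-climbing (GHC) baseline for Bayesian network structure search.

Starting from a random DAG, the search repeatedly evaluates every neighbor
reachable by a single edge action — adding an edge between an unconnected
pair, deleting an edge, or reversing an edge — keeping only moves that leave
the graph acyclic, and takes the strictly best score improvement.  It stops
when no move improves the score or when the action budget (a cap on
*accepted* moves) is spent.  With ``restarts = r`` the climb is repeated
from r + 1 independent random initial DAGs and the best result returned.
The default budget is 50 actions and 0 restarts.

Thanks to score decomposability, a move's score delta touches only the
target node (add/delete) or both endpoints (reverse), and node contributions
are cached in the shared :class:`~trinet.scoring.BGeScorer`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import DirectedNetwork, ExpressionMatrix, is_acyclic
from .enumeration import MAX_NODES, _dag_table, _network_from_states, _pairs
from .errors import ValidationError
from .scoring import BGeScorer, ScoreParams

__all__ = ["GHCParams", "GHCResult", "random_initial_dag", "ghc_search"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GHCParams:
    """Search budget: cap on accepted edge actions and number of restarts."""

    max_actions: int = 50
    restarts: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.max_actions < 0 or self.restarts < 0:
            raise ValidationError("max_actions and restarts must be >= 0")


@dataclass(frozen=True)
class GHCResult:
    """Best network over all starts plus per-start bookkeeping."""

    network: DirectedNetwork
    log_score: float
    start_scores: tuple[float, ...]
    start_networks: tuple[DirectedNetwork, ...]
    trajectories: tuple[tuple[float, ...], ...]
    n_actions: tuple[int, ...]


def random_permutation_dag(
    genes: Sequence[str], rng: np.random.Generator, edge_prob: float = 0.5
) -> DirectedNetwork:
    """Random DAG: uniform topological order, each forward edge with
    probability ``edge_prob``.  Covers every DAG with positive probability
    but is not uniform over DAGs."""
    genes = list(genes)
    order = rng.permutation(len(genes))
    position = np.empty(len(genes), dtype=int)
    position[order] = np.arange(len(genes))
    edges = []
    for i, j in _pairs(len(genes)):
        if rng.random() < edge_prob:
            if position[i] < position[j]:
                edges.append((genes[i], genes[j]))
            else:
                edges.append((genes[j], genes[i]))
    return DirectedNetwork(genes, edges, acyclic_required=True)


def random_initial_dag(genes: Sequence[str], seed: int) -> DirectedNetwork:
    """Random initial DAG for the search, reproducible from ``seed``.

    For up to 5 genes the DAG is drawn uniformly from the exhaustively
    enumerated DAG set; beyond that, uniform enumeration is impractical and
    a random-topological-order scheme (edge probability 1/2) is used, which
    still reaches every DAG with positive probability.
    """
    genes = list(genes)
    if len(genes) == 0:
        raise ValidationError("at least one gene is required")
    rng = np.random.default_rng(seed)
    if len(genes) == 1:
        return DirectedNetwork(genes, (), acyclic_required=True)
    if len(genes) <= 5:
        states, dag_idx, _ = _dag_table(len(genes))
        pick = dag_idx[rng.integers(len(dag_idx))]
        return _network_from_states(
            genes, _pairs(len(genes)), states[pick], acyclic_required=True
        )
    return random_permutation_dag(genes, rng)


def _climb(
    start: DirectedNetwork,
    scorer: BGeScorer,
    max_actions: int,
) -> tuple[DirectedNetwork, float, list[float], int]:
    genes = list(start.nodes)
    n = len(genes)
    idx = {g: i for i, g in enumerate(genes)}
    edges: set[tuple[int, int]] = {(idx[u], idx[v]) for u, v in start.edges}

    def node_score(v: int, parent_mask: int) -> float:
        return scorer.node_score_masked(idx2scope[v], scope_mask(parent_mask, v))

    # map local gene indices onto the scorer's scope indices
    idx2scope = [scorer._gene_index[g] for g in genes]

    def scope_mask(local_mask: int, _v: int) -> int:
        m = 0
        for i in range(n):
            if local_mask >> i & 1:
                m |= 1 << idx2scope[i]
        return m

    parent_masks = [0] * n
    for u, v in edges:
        parent_masks[v] |= 1 << u
    contrib = [node_score(v, parent_masks[v]) for v in range(n)]
    score = float(sum(contrib))
    trajectory = [score]

    def acyclic_with(new_edges: set[tuple[int, int]]) -> bool:
        return is_acyclic(range(n), new_edges)

    actions = 0
    while actions < max_actions:
        best_delta = 0.0
        best_move = None  # (kind, u, v, delta-details)
        # additions (pair unconnected in either direction), lexicographic
        for u in range(n):
            for v in range(n):
                if u == v or (u, v) in edges or (v, u) in edges:
                    continue
                if not acyclic_with(edges | {(u, v)}):
                    continue
                new_v = node_score(v, parent_masks[v] | (1 << u))
                delta = new_v - contrib[v]
                if delta > best_delta:
                    best_delta, best_move = delta, ("add", u, v, new_v, None)
        # deletions
        for u, v in sorted(edges):
            new_v = node_score(v, parent_masks[v] & ~(1 << u))
            delta = new_v - contrib[v]
            if delta > best_delta:
                best_delta, best_move = delta, ("del", u, v, new_v, None)
        # reversals
        for u, v in sorted(edges):
            if not acyclic_with((edges - {(u, v)}) | {(v, u)}):
                continue
            new_v = node_score(v, parent_masks[v] & ~(1 << u))
            new_u = node_score(u, parent_masks[u] | (1 << v))
            delta = (new_v - contrib[v]) + (new_u - contrib[u])
            if delta > best_delta:
                best_delta, best_move = delta, ("rev", u, v, new_v, new_u)
        if best_move is None:
            break
        kind, u, v, new_v, new_u = best_move
        if kind == "add":
            edges.add((u, v))
            parent_masks[v] |= 1 << u
            contrib[v] = new_v
        elif kind == "del":
            edges.remove((u, v))
            parent_masks[v] &= ~(1 << u)
            contrib[v] = new_v
        else:
            edges.remove((u, v))
            edges.add((v, u))
            parent_masks[v] &= ~(1 << u)
            parent_masks[u] |= 1 << v
            contrib[v] = new_v
            contrib[u] = new_u
        score += best_delta
        trajectory.append(score)
        actions += 1

    net = DirectedNetwork(
        genes, ((genes[u], genes[v]) for u, v in edges), acyclic_required=True
    )
    return net, score, trajectory, actions


def ghc_search(
    data: ExpressionMatrix,
    genes: Sequence[str],
    params: GHCParams | None = None,
    score_params: ScoreParams | None = None,
    full_output: bool = False,
):
    """Greedy hill climbing over DAGs on ``genes``.

    Returns ``(network, log_score)`` of the best start, or a
    :class:`GHCResult` with per-start details when ``full_output=True``.
    Deterministic given ``params.seed``.
    """
    params = params or GHCParams()
    genes = list(genes)
    scorer = BGeScorer(data.subset(genes), score_params)
    rng = np.random.default_rng(params.seed)
    start_seeds = rng.integers(0, 2**31, size=params.restarts + 1)

    nets, scores, trajs, n_actions = [], [], [], []
    for s in start_seeds:
        d0 = random_initial_dag(genes, int(s))
        net, score, traj, acts = _climb(d0, scorer, params.max_actions)
        nets.append(net)
        scores.append(score)
        trajs.append(tuple(traj))
        n_actions.append(acts)
        logger.debug("GHC start: %d actions, final score %.6f", acts, score)

    best = int(np.argmax(scores))
    if full_output:
        return GHCResult(
            nets[best],
            scores[best],
            tuple(scores),
            tuple(nets),
            tuple(trajs),
            tuple(n_actions),
        )
    return nets[best], scores[best]
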