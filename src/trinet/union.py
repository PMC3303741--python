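"""Divide-and-unite inference: triplet decomposition and edge-type voting.

The whole-gene problem is divided into all C(n, 3) three-gene subproblems
(triplets).  Each triplet's 25 candidate DAGs are scored exhaustively and
stored, with their within-triplet rank, in a tuple store Z.  The union step
then decides, for every unordered gene pair, one of three edge types
(forward, backward, absent) by summing the weights of the rank-1 network of
every triplet containing the pair, grouped by the state that network assigns
the pair, and choosing the strictly largest total.  Ties escalate: first to
the rank-i networks of triplets whose third gene is already connected to the
pair in the partially built output, then to rank i+1 for a fresh vote.
Because each pair is decided independently, the united network may contain
directed cycles — it is returned with ``acyclic_required=False``.

Two aggregation weights are supported.  The default (``raw_scores=True``)
sums the raw marginal scores ``p(D, d)`` themselves, carried in log space
via log-sum-exp so nothing underflows: the triplet that explains its data
best dominates each pair's vote, which in particular lets the one triplet
containing the mediator of an indirect dependency out-vote the triplets
that see only the marginal (shortcut) association.
``raw_scores=False`` instead converts each triplet's candidate log scores
into normalized posterior weights (softmax over the triplet's full DAG
set), putting all triplets on a common [0, 1] scale.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .core import DirectedNetwork, ExpressionMatrix
from .enumeration import EdgeState, ScoredNetwork, rank_candidates
from .errors import ValidationError
from .scoring import ScoreParams

__all__ = [
    "make_triplets",
    "TripletEntry",
    "TupleStore",
    "build_tuple_store",
    "EdgeDecision",
    "edge_type_totals",
    "unite",
    "unite_audit",
    "FULL_TRIPLET_RANKS",
]

logger = logging.getLogger(__name__)

FULL_TRIPLET_RANKS = 25  # acyclic configurations of a triplet
TRIPLET_CANDIDATE_SLOTS = 27  # all configurations, cyclic ones included


def make_triplets(genes: Sequence[str]) -> Iterator[tuple[str, str, str]]:
    """Yield every 3-gene subset once, in lexicographic index order."""
    genes = list(genes)
    if len(genes) < 3:
        raise ValidationError("at least 3 genes are required to form triplets")
    return itertools.combinations(genes, 3)


def _state_of_pair(net: DirectedNetwork, x: str, y: str) -> EdgeState:
    """Edge state of the unordered pair (x, y), x preceding y in store order."""
    if net.has_edge(x, y):
        return EdgeState.FORWARD
    if net.has_edge(y, x):
        return EdgeState.BACKWARD
    return EdgeState.ABSENT


@dataclass(frozen=True)
class TripletEntry:
    """The stored tuples of one triplet: ranks 1..max_rank with weights.

    ``weights[r-1]`` is the normalized posterior weight of the rank-r
    network within its triplet (softmax over the triplet's full candidate
    DAG set); ``networks[r-1].log_score`` carries the raw log score.
    """

    genes: tuple[str, str, str]
    networks: tuple[ScoredNetwork, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        if len(self.networks) != len(self.weights):
            raise ValidationError("one weight per stored network is required")
        for r, sn in enumerate(self.networks, start=1):
            if sn.rank != r:
                raise ValidationError(
                    f"triplet {self.genes}: stored ranks must be 1..K in "
                    f"order, found rank {sn.rank} at position {r}"
                )
            if set(sn.network.nodes) != set(self.genes):
                raise ValidationError(
                    f"triplet {self.genes}: network nodes {sn.network.nodes} "
                    "do not match the triplet"
                )


class TupleStore:
    """The set Z of (network, score, rank) tuples across all triplets."""

    def __init__(
        self,
        genes: Sequence[str],
        entries: dict[tuple[str, str, str], TripletEntry],
        max_rank: int,
    ):
        self.genes = tuple(genes)
        self.max_rank = int(max_rank)
        self.entries = dict(entries)
        expected = set(make_triplets(self.genes))
        if set(self.entries) != expected:
            missing = sorted(expected - set(self.entries))[:3]
            raise ValidationError(
                f"tuple store must cover every triplet; missing e.g. {missing}"
            )
        for trip, entry in self.entries.items():
            if entry.genes != trip:
                raise ValidationError(f"entry key {trip} mismatches {entry.genes}")
            if len(entry.networks) != self.max_rank:
                raise ValidationError(
                    f"triplet {trip}: expected ranks 1..{self.max_rank}, "
                    f"got {len(entry.networks)}"
                )
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    # -- statistics ---------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_triplets(self) -> int:
        return len(self.entries)

    @property
    def n_scored_entries(self) -> int:
        """Stored (DAG, score, rank) tuples: C(n,3) * max_rank."""
        return sum(len(e.networks) for e in self.entries.values())

    @property
    def n_candidate_slots(self) -> int:
        """Candidate-configuration slots: C(n,3) * 27 (cyclic ones included)."""
        return self.n_triplets * TRIPLET_CANDIDATE_SLOTS

    def ordered_pair(self, a: str, b: str) -> tuple[str, str]:
        ia, ib = self._gene_index[a], self._gene_index[b]
        if ia == ib:
            raise ValidationError("a pair needs two distinct genes")
        return (a, b) if ia < ib else (b, a)

    def pairs(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.genes, 2))

    def triplets_with_pair(
        self, pair: tuple[str, str]
    ) -> list[tuple[str, str, str]]:
        x, y = pair
        if x not in self._gene_index or y not in self._gene_index:
            raise ValidationError(f"pair {pair} not covered by this store")
        out = []
        for trip in self.entries:
            if x in trip and y in trip:
                out.append(trip)
        return out


def build_tuple_store(
    genes: Sequence[str],
    data: ExpressionMatrix,
    params: ScoreParams | None = None,
    max_rank: int = FULL_TRIPLET_RANKS,
) -> TupleStore:
    """Exhaustively score every triplet and store ranks 1..max_rank.

    Weights are normalized over each triplet's *full* 25-DAG candidate set
    before truncation to ``max_rank``, so they remain true posterior
    probabilities of the candidates.
    """
    if not 1 <= max_rank <= FULL_TRIPLET_RANKS:
        raise ValidationError(
            f"max_rank must be in 1..{FULL_TRIPLET_RANKS}, got {max_rank}"
        )
    genes = list(genes)
    entries: dict[tuple[str, str, str], TripletEntry] = {}
    for trip in make_triplets(genes):
        try:
            ranked = rank_candidates(list(trip), data, params)
        except Exception as exc:
            raise type(exc)(f"while scoring triplet {trip}: {exc}") from exc
        log_scores = np.array([sn.log_score for sn in ranked])
        weights = np.exp(log_scores - logsumexp(log_scores))
        entries[trip] = TripletEntry(
            trip,
            tuple(ranked[:max_rank]),
            tuple(float(w) for w in weights[:max_rank]),
        )
    return TupleStore(genes, entries, max_rank)


@dataclass
class EdgeDecision:
    """Vote outcome for one unordered gene pair.

    ``totals`` maps each edge state to its aggregated weight (or log-sum of
    raw scores, -inf for states with no votes, in raw mode).  ``chosen`` is
    the strict maximizer or None on a tie; ``decided_at_rank`` records the
    rank level at which the pair was finally decided (None if the pair fell
    through to the conservative absent fallback).
    """

    pair: tuple[str, str]
    totals: dict[EdgeState, float]
    chosen: Optional[EdgeState]
    decided_at_rank: Optional[int] = None


def _strict_argmax(totals: dict[EdgeState, float]) -> Optional[EdgeState]:
    best = max(totals.values())
    winners = [s for s, t in totals.items() if t == best]
    return winners[0] if len(winners) == 1 else None


def edge_type_totals(
    pair: tuple[str, str],
    store: TupleStore,
    rank: int,
    raw_scores: bool = True,
) -> EdgeDecision:
    """Sum the rank-level votes of every triplet containing ``pair``.

    Each of the pair's n-2 triplets contributes its rank-``rank`` network's
    weight to the bucket of the edge state that network assigns the pair.
    """
    if not 1 <= rank <= store.max_rank:
        raise ValidationError(
            f"rank {rank} outside the stored range 1..{store.max_rank}"
        )
    x, y = store.ordered_pair(*pair)
    if raw_scores:
        votes: dict[EdgeState, list[float]] = {s: [] for s in EdgeState}
        for trip in store.triplets_with_pair((x, y)):
            entry = store.entries[trip]
            sn = entry.networks[rank - 1]
            votes[_state_of_pair(sn.network, x, y)].append(sn.log_score)
        totals = {
            s: (float(logsumexp(v)) if v else -math.inf)
            for s, v in votes.items()
        }
    else:
        totals = {s: 0.0 for s in EdgeState}
        for trip in store.triplets_with_pair((x, y)):
            entry = store.entries[trip]
            sn = entry.networks[rank - 1]
            totals[_state_of_pair(sn.network, x, y)] += entry.weights[rank - 1]
    chosen = _strict_argmax(totals)
    return EdgeDecision(
        (x, y),
        totals,
        chosen,
        decided_at_rank=rank if chosen is not None else None,
    )


def _tiebreak(
    pair: tuple[str, str],
    store: TupleStore,
    rank: int,
    decided_edges: set[tuple[str, str]],
    raw_scores: bool,
) -> Optional[EdgeState]:
    """Rank-level tie break using triplets anchored to the partial output.

    Considers triplets {x, y, w} whose third gene w already has an edge (in
    either direction) with x or y among the edges decided so far; among
    those triplets' rank-``rank`` networks, adopts the pair state of the
    single highest-weighted one.  Returns None if no triplet qualifies or
    the maximum is not unique.
    """
    x, y = pair
    candidates: list[tuple[float, EdgeState]] = []
    for trip in store.triplets_with_pair(pair):
        w = next(g for g in trip if g not in (x, y))
        touches = any(
            (w, g) in decided_edges or (g, w) in decided_edges for g in (x, y)
        )
        if not touches:
            continue
        entry = store.entries[trip]
        sn = entry.networks[rank - 1]
        weight = sn.log_score if raw_scores else entry.weights[rank - 1]
        candidates.append((weight, _state_of_pair(sn.network, x, y)))
    if not candidates:
        return None
    best = max(w for w, _ in candidates)
    winners = [s for w, s in candidates if w == best]
    if len(winners) != 1:
        return None
    return winners[0]


def unite_audit(
    store: TupleStore, raw_scores: bool = True
) -> tuple[DirectedNetwork, dict[tuple[str, str], EdgeDecision]]:
    """Unite the triplet winners into one network, returning the full audit.

    Pairs are processed in lexicographic order of the store's gene order; a
    decision takes effect immediately, so later tie breaks within the same
    sweep can anchor on it.  Pairs still tied after the rank-level tie break
    are re-voted at the next rank; pairs undecided beyond the deepest stored
    rank are conservatively set to absent (with a warning).
    """
    decisions: dict[tuple[str, str], EdgeDecision] = {}
    edges: set[tuple[str, str]] = set()
    undecided = store.pairs()
    rank = 1
    while undecided and rank <= store.max_rank:
        still: list[tuple[str, str]] = []
        for pair in undecided:
            dec = edge_type_totals(pair, store, rank, raw_scores=raw_scores)
            if dec.chosen is None:
                state = _tiebreak(pair, store, rank, edges, raw_scores)
                if state is not None:
                    dec = EdgeDecision(dec.pair, dec.totals, state, rank)
            if dec.chosen is None:
                still.append(pair)
                continue
            decisions[dec.pair] = dec
            x, y = dec.pair
            if dec.chosen == EdgeState.FORWARD:
                edges.add((x, y))
            elif dec.chosen == EdgeState.BACKWARD:
                edges.add((y, x))
        undecided = still
        rank += 1
    for pair in undecided:
        logger.warning(
            "pair %s still tied beyond rank %d; defaulting to absent",
            pair,
            store.max_rank,
        )
        dec = edge_type_totals(
            pair, store, store.max_rank, raw_scores=raw_scores
        )
        decisions[pair] = EdgeDecision(
            dec.pair, dec.totals, EdgeState.ABSENT, None
        )
    network = DirectedNetwork(store.genes, edges, acyclic_required=False)
    return network, decisions


def unite(store: TupleStore, raw_scores: bool = True) -> DirectedNetwork:
    """The united whole-gene network G_V (cycles permitted)."""
    return unite_audit(store, raw_scores=raw_scores)[0]
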