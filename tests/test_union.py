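import math

import numpy as np
import pytest

from trinet import (
    DirectedNetwork,
    EdgeState,
    ScoredNetwork,
    ValidationError,
    build_tuple_store,
    edge_type_totals,
    make_triplets,
    rank_candidates,
    random_planted_model,
    simulate_expression,
    unite,
    unite_audit,
)
from trinet.union import TripletEntry, TupleStore

from conftest import make_chain_data


def entry(genes, rank_specs):
    """TripletEntry from [(edges, weight), ...] ordered by rank.

    Log scores are set to log(weight) so the fixture behaves identically
    under raw-score and normalized-weight aggregation.
    """
    networks, weights = [], []
    for r, (edges, w) in enumerate(rank_specs, start=1):
        net = DirectedNetwork(genes, edges)
        networks.append(ScoredNetwork(net, math.log(w), r))
        weights.append(w)
    return TripletEntry(tuple(genes), tuple(networks), tuple(weights))


class TestMakeTriplets:
    @pytest.mark.parametrize("n, expected", [(3, 1), (5, 10), (10, 120)])
    def test_counts(self, n, expected):
        genes = [f"g{i}" for i in range(n)]
        trips = list(make_triplets(genes))
        assert len(trips) == expected
        assert trips == sorted(trips, key=lambda t: [genes.index(g) for g in t])

    def test_requires_three_genes(self):
        with pytest.raises(ValidationError):
            make_triplets(["a", "b"])


class TestTupleStore:
    def test_five_gene_store_statistics(self):
        model = random_planted_model(5, seed=1)
        data = simulate_expression(model)
        store = build_tuple_store(data.gene_ids, data)
        assert store.n_triplets == 10
        assert store.n_candidate_slots == 270
        assert store.n_scored_entries == 250
        for pair in store.pairs():
            assert len(store.triplets_with_pair(pair)) == store.n_genes - 2

    def test_three_gene_rank_one_store(self):
        model = random_planted_model(3, seed=2)
        data = simulate_expression(model)
        store = build_tuple_store(data.gene_ids, data, max_rank=1)
        assert store.n_scored_entries == 1

    def test_weights_are_triplet_posteriors(self):
        model = random_planted_model(4, seed=3)
        data = simulate_expression(model)
        store = build_tuple_store(data.gene_ids, data)
        for e in store.entries.values():
            assert np.isclose(sum(e.weights), 1.0)
            assert list(e.weights) == sorted(e.weights, reverse=True)

    def test_incomplete_store_rejected(self):
        genes = ["a", "b", "c", "d"]
        one = entry(["a", "b", "c"], [([("a", "b")], 1.0)])
        with pytest.raises(ValidationError, match="every triplet"):
            TupleStore(genes, {("a", "b", "c"): one}, max_rank=1)


def four_gene_store(specs, genes=("a", "b", "c", "d"), max_rank=1):
    entries = {}
    for trip in make_triplets(list(genes)):
        entries[trip] = entry(list(trip), specs[trip])
    return TupleStore(list(genes), entries, max_rank)


class TestEdgeTypeTotals:
    def test_single_triplet_reproduces_rank_one_states(self):
        model = random_planted_model(3, seed=4)
        data = simulate_expression(model)
        store = build_tuple_store(data.gene_ids, data)
        top = store.entries[tuple(data.gene_ids)].networks[0].network
        for raw in (True, False):
            for pair in store.pairs():
                dec = edge_type_totals(pair, store, 1, raw_scores=raw)
                x, y = dec.pair
                if top.has_edge(x, y):
                    assert dec.chosen == EdgeState.FORWARD
                elif top.has_edge(y, x):
                    assert dec.chosen == EdgeState.BACKWARD
                else:
                    assert dec.chosen == EdgeState.ABSENT

    def test_two_triplet_vote_totals(self):
        """Forward weight 0.6 in one triplet, absent 0.3 in the other."""
        specs = {
            ("a", "b", "c"): [([("a", "b")], 0.6)],
            ("a", "b", "d"): [([], 0.3)],
            ("a", "c", "d"): [([], 0.5)],
            ("b", "c", "d"): [([], 0.5)],
        }
        store = four_gene_store(specs)
        dec = edge_type_totals(("a", "b"), store, 1, raw_scores=False)
        assert dec.totals == {
            EdgeState.FORWARD: 0.6,
            EdgeState.BACKWARD: 0.0,
            EdgeState.ABSENT: 0.3,
        }
        assert dec.chosen == EdgeState.FORWARD
        assert dec.decided_at_rank == 1

    def test_exact_tie_is_undecided(self):
        specs = {
            ("a", "b", "c"): [([("a", "b")], 0.5)],
            ("a", "b", "d"): [([("b", "a")], 0.5)],
            ("a", "c", "d"): [([], 0.5)],
            ("b", "c", "d"): [([], 0.5)],
        }
        store = four_gene_store(specs)
        dec = edge_type_totals(("a", "b"), store, 1, raw_scores=False)
        assert dec.chosen is None
        assert dec.decided_at_rank is None


class TestUnite:
    def test_three_genes_equals_exhaustive_winner(self):
        for seed in range(5):
            model = random_planted_model(3, seed=seed)
            data = simulate_expression(model)
            store = build_tuple_store(data.gene_ids, data)
            top1 = rank_candidates(data.gene_ids, data)[0].network
            assert unite(store).edges == top1.edges

    def test_pure_function_of_store(self):
        model = random_planted_model(5, seed=9)
        data = simulate_expression(model)
        store = build_tuple_store(data.gene_ids, data)
        assert unite(store).edges == unite(store).edges

    def test_each_pair_gets_one_state(self):
        model = random_planted_model(6, seed=10)
        data = simulate_expression(model)
        store = build_tuple_store(data.gene_ids, data)
        net, decisions = unite_audit(store)
        assert len(decisions) == len(store.pairs())
        for u, v in net.edges:
            assert (v, u) not in net.edges

    def test_skeleton_recovery_on_diamond(self):
        truth = DirectedNetwork(
            list("abcd"), [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")]
        )
        from trinet import PlantedModel

        model = PlantedModel(
            truth, {e: 1.0 for e in truth.edges}, 0.5, 300, seed=7
        )
        data = simulate_expression(model)
        store = build_tuple_store(data.gene_ids, data)
        net = unite(store)
        skeleton = {frozenset(e) for e in net.edges}
        true_skel = {frozenset(e) for e in truth.edges}
        assert len(skeleton & true_skel) >= 3

    def test_relabeling_equivariance(self):
        model = random_planted_model(4, seed=12)
        data = simulate_expression(model)
        mapping = dict(zip(data.gene_ids, ["w", "x", "y", "z"]))
        renamed = type(data)(
            [mapping[g] for g in data.gene_ids], data.values, data.sample_ids
        )
        net1 = unite(build_tuple_store(data.gene_ids, data))
        net2 = unite(build_tuple_store(renamed.gene_ids, renamed))
        assert {(mapping[u], mapping[v]) for u, v in net1.edges} == set(net2.edges)

    def test_cyclic_output_from_consistent_winners(self):
        """Per-triplet winners a->b, b->c, c->a in different triplets give a
        directed 3-cycle in the united network."""
        specs = {
            ("a", "b", "c"): [([("a", "b"), ("b", "c")], 0.4)],
            ("a", "b", "d"): [([("a", "b")], 0.4)],
            ("a", "c", "d"): [([("c", "a")], 0.5)],
            ("b", "c", "d"): [([("b", "c")], 0.5)],
        }
        store = four_gene_store(specs)
        net = unite(store)
        assert {("a", "b"), ("b", "c"), ("c", "a")} <= set(net.edges)
        assert not net.is_acyclic()

    def test_tie_broken_by_rank_escalation(self):
        """A rank-1 tie for (x, y) resolves at rank 2 via the triplet whose
        third gene is already linked to x in the partial network."""
        genes = ("x", "y", "w", "z")
        specs = {
            ("x", "y", "w"): [
                ([("x", "y")], 0.3),
                ([("x", "y"), ("x", "w")], 0.2),
            ],
            ("x", "y", "z"): [([("y", "x")], 0.3), ([("y", "x")], 0.2)],
            ("x", "w", "z"): [([("x", "w")], 0.5), ([], 0.1)],
            ("y", "w", "z"): [([], 0.5), ([], 0.1)],
        }
        store = four_gene_store(specs, genes=genes, max_rank=2)
        net, decisions = unite_audit(store, raw_scores=False)
        dec = decisions[("x", "y")]
        assert dec.chosen == EdgeState.FORWARD
        assert dec.decided_at_rank == 2
        assert ("x", "y") in net.edges
        assert decisions[("x", "w")].decided_at_rank == 1

    def test_persistent_tie_falls_back_to_absent(self):
        """Ties surviving every stored rank default conservatively to no edge."""
        specs = {
            ("a", "b", "c"): [([("a", "b")], 0.5)],
            ("a", "b", "d"): [([("b", "a")], 0.5)],
            ("a", "c", "d"): [([], 0.5)],
            ("b", "c", "d"): [([], 0.5)],
        }
        store = four_gene_store(specs)
        net, decisions = unite_audit(store, raw_scores=False)
        dec = decisions[("a", "b")]
        assert dec.chosen == EdgeState.ABSENT
        assert dec.decided_at_rank is None
        assert ("a", "b") not in net.edges and ("b", "a") not in net.edges
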