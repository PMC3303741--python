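import itertools

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import gamma, norm

from trinet import (
    BGeScorer,
    CyclicNetworkError,
    DirectedNetwork,
    ExpressionMatrix,
    ScoreParams,
    UnknownGeneError,
    ValidationError,
    enumerate_dags,
    log_network_score,
    log_node_score,
)

from conftest import make_chain_data


def equivalence_key(net):
    """Markov-equivalence class of a DAG: skeleton plus v-structures."""
    skel = frozenset(frozenset(e) for e in net.edges)
    vstructs = set()
    for v in net.nodes:
        pa = sorted(net.parents(v))
        for a, b in itertools.combinations(pa, 2):
            if not (net.has_edge(a, b) or net.has_edge(b, a)):
                vstructs.add((a, b, v))
    return skel, frozenset(vstructs)


class TestNodeScore:
    def test_parentless_matches_quadrature(self, rng):
        """The closed-form marginal equals direct numerical integration of
        the Gaussian likelihood against the normal-gamma prior."""
        obs = rng.normal(size=6)
        obs = (obs - obs.mean()) / obs.std()
        data = ExpressionMatrix(
            ["g"], obs[None, :], [f"s{i}" for i in range(6)]
        )
        scorer = BGeScorer(data)
        am, aw, t = scorer.am, scorer.aw, scorer.T[0, 0]
        nu = obs.mean()

        def integrand(mu, w):
            lik = np.prod(norm.pdf(obs, mu, 1 / np.sqrt(w)))
            return (
                lik
                * norm.pdf(mu, nu, 1 / np.sqrt(am * w))
                * gamma.pdf(w, a=aw / 2, scale=2 / t)
            )

        val, err = integrate.dblquad(
            integrand, 1e-9, 60, -12, 12, epsabs=1e-13, epsrel=1e-9
        )
        assert abs(np.log(val) - scorer.node_score("g", [])) < 1e-4

    def test_score_equivalence_two_genes(self, rng):
        x = rng.normal(size=(2, 40))
        x[1] += 0.7 * x[0]
        data = ExpressionMatrix(["a", "b"], x, [f"s{i}" for i in range(40)])
        fwd = log_node_score("a", {"b"}, data) + log_node_score("b", set(), data)
        bwd = log_node_score("b", {"a"}, data) + log_node_score("a", set(), data)
        assert fwd == pytest.approx(bwd, rel=1e-12)

    def test_sample_permutation_invariance(self, rng):
        x = rng.normal(size=(2, 20))
        data = ExpressionMatrix(["a", "b"], x, [f"s{i}" for i in range(20)])
        perm = rng.permutation(20)
        shuffled = ExpressionMatrix(
            ["a", "b"], x[:, perm], [f"s{i}" for i in range(20)]
        )
        assert log_node_score("b", {"a"}, data) == pytest.approx(
            log_node_score("b", {"a"}, shuffled), rel=1e-12
        )

    def test_locality(self, rng):
        """The node term ignores genes outside the node-parent family."""
        x = rng.normal(size=(3, 25))
        base = ExpressionMatrix(["a", "b", "c"], x, [f"s{i}" for i in range(25)])
        x2 = x.copy()
        x2[2] = rng.normal(size=25) * 5  # perturb an unrelated gene
        pert = ExpressionMatrix(["a", "b", "c"], x2, [f"s{i}" for i in range(25)])
        assert log_node_score("b", {"a"}, base) == pytest.approx(
            log_node_score("b", {"a"}, pert), rel=1e-12
        )

    def test_errors(self, small_matrix):
        with pytest.raises(UnknownGeneError):
            log_node_score("nope", set(), small_matrix)
        with pytest.raises(ValidationError):
            log_node_score("geneA", {"geneA"}, small_matrix)


class TestNetworkScore:
    def test_empty_network_is_sum_of_parentless_terms(self, small_matrix):
        net = DirectedNetwork(list(small_matrix.gene_ids), [])
        total = log_network_score(net, small_matrix)
        parts = sum(
            log_node_score(g, set(), small_matrix)
            for g in small_matrix.gene_ids
        )
        assert total == pytest.approx(parts, rel=1e-12)

    def test_cyclic_input_rejected(self, small_matrix):
        net = DirectedNetwork(
            list(small_matrix.gene_ids),
            [("geneA", "geneB"), ("geneB", "geneA")],
            acyclic_required=False,
        )
        with pytest.raises(CyclicNetworkError):
            log_network_score(net, small_matrix)

    def test_decomposability(self, rng):
        """Changing one node's parent set changes only that node's term."""
        x = rng.normal(size=(4, 30))
        data = ExpressionMatrix(
            ["a", "b", "c", "d"], x, [f"s{i}" for i in range(30)]
        )
        genes = list(data.gene_ids)
        n1 = DirectedNetwork(genes, [("a", "c"), ("b", "d")])
        n2 = DirectedNetwork(genes, [("a", "c"), ("b", "d"), ("a", "d")])
        diff = log_network_score(n2, data) - log_network_score(n1, data)
        node_diff = log_node_score("d", {"a", "b"}, data) - log_node_score(
            "d", {"b"}, data
        )
        assert diff == pytest.approx(node_diff, rel=1e-9)

    def test_markov_equivalent_dags_score_identically(self, rng):
        """All 25 three-gene DAGs: equal scores exactly within each
        equivalence class (skeleton + v-structures) and, as a sanity check,
        distinct scores across classes."""
        x = rng.normal(size=(3, 50))
        x[1] += 0.8 * x[0]
        x[2] += -0.6 * x[1]
        data = ExpressionMatrix(["a", "b", "c"], x, [f"s{i}" for i in range(50)])
        scores = {}
        for net in enumerate_dags(["a", "b", "c"]):
            scores.setdefault(equivalence_key(net), []).append(
                log_network_score(net, data)
            )
        assert len(scores) == 11  # equivalence classes on 3 labeled nodes
        for vals in scores.values():
            ref = vals[0]
            for v in vals[1:]:
                assert v == pytest.approx(ref, rel=1e-9)

    def test_true_edge_outscores_empty(self):
        data = make_chain_data([1.0], noise_sd=0.3, n_samples=200, seed=5,
                               gene_names=["a", "b"])
        edge = DirectedNetwork(["a", "b"], [("a", "b")])
        empty = DirectedNetwork(["a", "b"], [])
        assert log_network_score(edge, data) > log_network_score(empty, data)

    def test_irrelevant_parent_usually_penalized(self):
        """Adding an independent parent lowers the score in most replicates."""
        worse = 0
        n_rep = 50
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            x = r.normal(size=(2, 300))
            data = ExpressionMatrix(["a", "b"], x, [f"s{i}" for i in range(300)])
            with_parent = log_node_score("b", {"a"}, data)
            without = log_node_score("b", set(), data)
            worse += with_parent < without
        assert worse > n_rep // 2


class TestScoreParams:
    def test_aw_lower_bound(self, small_matrix):
        with pytest.raises(ValidationError):
            BGeScorer(small_matrix, ScoreParams(aw=1.0))

    def test_prior_scale_must_be_spd(self, small_matrix):
        bad = ScoreParams(prior_scale=np.diag([1.0, -1.0, 1.0]))
        with pytest.raises(ValidationError):
            BGeScorer(small_matrix, bad)

    def test_config_round_trip(self):
        p = ScoreParams(am=2.0, aw=7.5)
        q = ScoreParams.from_config(p.to_config())
        assert (q.am, q.aw, q.structure_prior) == (2.0, 7.5, "uniform")
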