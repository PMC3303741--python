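"""Decomposable Gaussian (BGe) network score.

The score of a DAG ``D`` given data ``d`` is the log of the relative
posterior probability ``p(D, d) = p(d | D) p(D)``.  With continuous data and
a conjugate normal-Wishart prior the marginal likelihood factorizes over
nodes, and each node's factor is a ratio of multivariate-Gaussian marginal
likelihoods over the node-plus-parents and parents-only gene subsets:

    log p(x_v | x_pa(v)) = L({v} u pa(v)) - L(pa(v))

where, for a subset ``Y`` of size ``l`` drawn from a scoring scope of ``n``
genes observed on ``N`` samples,

    L(Y) = -lN/2 log(pi) + l/2 log(am / (am + N))
           + log Gamma_l((N + aw - n + l) / 2) - log Gamma_l((aw - n + l) / 2)
           + (aw - n + l)/2 log|T_YY| - (N + aw - n + l)/2 log|R_YY|,

with ``R = T + S_N + (N am / (N + am)) (nu - xbar)(nu - xbar)^T`` the
posterior scale matrix (``S_N`` the centered scatter of the data) and
``Gamma_l`` the multivariate gamma function.  This family is decomposable
and score equivalent: Markov-equivalent DAGs receive identical scores under
the uniform structure prior, so rankings are well defined on equivalence
classes.

Hyperparameter defaults follow common practice for the BGe score: prior
precision ``am = 1``; degrees of freedom ``aw = n + 2``; prior mean ``nu`` =
per-gene sample mean; prior scale ``T = am (aw - n - 1) / (am + 1) * I``.
The scoring *scope* is the gene set of the matrix handed to the scorer
(callers subset the matrix first), so the same hyperparameters apply to all
candidate structures being compared.

All computation is in log space.  The uniform structure prior contributes a
constant that cancels in every ranking and is therefore dropped (log p(D)
taken as 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import multigammaln

from .core import DirectedNetwork, ExpressionMatrix
from .errors import (
    CyclicNetworkError,
    ScoreNumericalError,
    UnknownGeneError,
    ValidationError,
)

__all__ = ["ScoreParams", "BGeScorer", "log_node_score", "log_network_score"]


@dataclass(frozen=True, eq=False)
class ScoreParams:
    """Hyperparameters of the BGe score.

    ``None`` fields are resolved against the scoring scope when a
    :class:`BGeScorer` is built: ``aw -> n_vars + 2``, ``prior_mean ->``
    per-gene sample mean, ``prior_scale -> am (aw - n_vars - 1)/(am + 1) I``.
    """

    am: float = 1.0
    aw: Optional[float] = None
    prior_mean: Optional[np.ndarray] = None
    prior_scale: Optional[np.ndarray] = None
    structure_prior: str = "uniform"

    def __post_init__(self):
        if self.am <= 0:
            raise ValidationError("am must be positive")
        if self.structure_prior != "uniform":
            raise ValidationError(
                f"unsupported structure prior {self.structure_prior!r}"
            )

    # -- flat key=value config round-trip ----------------------------------

    def to_config(self) -> dict[str, str]:
        cfg = {"am": repr(self.am), "structure_prior": self.structure_prior}
        if self.aw is not None:
            cfg["aw"] = repr(self.aw)
        return cfg

    @classmethod
    def from_config(cls, cfg: dict[str, str]) -> "ScoreParams":
        kwargs: dict = {}
        if "am" in cfg:
            kwargs["am"] = float(cfg["am"])
        if "aw" in cfg:
            kwargs["aw"] = float(cfg["aw"])
        if "structure_prior" in cfg:
            kwargs["structure_prior"] = cfg["structure_prior"]
        return cls(**kwargs)


class BGeScorer:
    """Caches subset marginal likelihoods for one matrix and one scope.

    The scope is the full gene set of ``data``; parent sets are encoded as
    bitmasks over that gene order, which lets every module (exhaustive
    ranking, hill climbing, triplet scoring) share one cache.
    """

    def __init__(self, data: ExpressionMatrix, params: ScoreParams | None = None):
        params = params or ScoreParams()
        self.data = data
        self.genes = data.gene_ids
        self.n = data.n_genes
        self.N = data.n_samples
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

        X = data.values  # n x N
        xbar = X.mean(axis=1)

        am = float(params.am)
        aw = float(params.aw) if params.aw is not None else self.n + 2.0
        if not aw > self.n - 1:
            raise ValidationError(
                f"aw must exceed n_vars - 1 = {self.n - 1}, got {aw}"
            )
        if params.prior_mean is not None:
            nu = np.asarray(params.prior_mean, dtype=float)
            if nu.shape != (self.n,):
                raise ValidationError("prior_mean has wrong length for scope")
        else:
            nu = xbar
        if params.prior_scale is not None:
            T = np.asarray(params.prior_scale, dtype=float)
            if T.shape != (self.n, self.n):
                raise ValidationError("prior_scale has wrong shape for scope")
        else:
            factor = am * (aw - self.n - 1.0) / (am + 1.0)
            if factor <= 0:
                raise ValidationError(
                    "default prior_scale requires aw > n_vars + 1; "
                    "supply prior_scale explicitly for smaller aw"
                )
            T = factor * np.eye(self.n)
        if not np.allclose(T, T.T):
            raise ValidationError("prior_scale must be symmetric")
        try:
            np.linalg.cholesky(T)
        except np.linalg.LinAlgError:
            raise ValidationError("prior_scale must be positive definite") from None

        centered = X - xbar[:, None]
        scatter = centered @ centered.T
        diff = nu - xbar
        R = T + scatter + (self.N * am / (self.N + am)) * np.outer(diff, diff)

        self.am, self.aw, self.T, self.R = am, aw, T, R
        self.params = params
        self._marginal_cache: dict[int, float] = {0: 0.0}
        self._node_cache: dict[tuple[int, int], float] = {}

    # -- bitmask helpers ----------------------------------------------------

    def gene_mask(self, genes: Iterable[str]) -> int:
        mask = 0
        for g in genes:
            try:
                mask |= 1 << self._gene_index[g]
            except KeyError:
                raise UnknownGeneError(g) from None
        return mask

    def _mask_genes(self, mask: int) -> list[str]:
        return [self.genes[i] for i in range(self.n) if mask >> i & 1]

    def _logdet(self, M: np.ndarray, mask: int, name: str) -> float:
        sign, logdet = np.linalg.slogdet(M)
        if sign <= 0 or not np.isfinite(logdet):
            raise ScoreNumericalError(
                f"{name} submatrix for genes {self._mask_genes(mask)} is "
                "singular or indefinite"
            )
        return logdet

    def log_marginal(self, mask: int) -> float:
        """Log marginal likelihood L(Y) of the gene subset encoded by mask."""
        cached = self._marginal_cache.get(mask)
        if cached is not None:
            return cached
        idx = [i for i in range(self.n) if mask >> i & 1]
        l = len(idx)
        N, am, aw, n = self.N, self.am, self.aw, self.n
        dof = aw - n + l
        logdet_T = self._logdet(self.T[np.ix_(idx, idx)], mask, "prior scale")
        logdet_R = self._logdet(self.R[np.ix_(idx, idx)], mask, "posterior scale")
        out = (
            -0.5 * l * N * np.log(np.pi)
            + 0.5 * l * (np.log(am) - np.log(am + N))
            + multigammaln(0.5 * (N + dof), l)
            - multigammaln(0.5 * dof, l)
            + 0.5 * dof * logdet_T
            - 0.5 * (N + dof) * logdet_R
        )
        self._marginal_cache[mask] = out
        return out

    def node_score_masked(self, node_idx: int, parent_mask: int) -> float:
        """Per-node log factor for node index and parent bitmask."""
        key = (node_idx, parent_mask)
        cached = self._node_cache.get(key)
        if cached is not None:
            return cached
        if parent_mask >> node_idx & 1:
            raise ValidationError("node cannot be its own parent")
        family = parent_mask | (1 << node_idx)
        out = self.log_marginal(family) - self.log_marginal(parent_mask)
        self._node_cache[key] = out
        return out

    def node_score(self, node: str, parents: Iterable[str]) -> float:
        parents = list(parents)
        if node in parents:
            raise ValidationError(f"node {node!r} cannot be its own parent")
        try:
            node_idx = self._gene_index[node]
        except KeyError:
            raise UnknownGeneError(node) from None
        return self.node_score_masked(node_idx, self.gene_mask(parents))

    def network_score(self, net: DirectedNetwork) -> float:
        if not net.is_acyclic():
            raise CyclicNetworkError(
                "the Bayesian network score is defined for DAGs only"
            )
        parent_masks = [0] * self.n
        for u, v in net.edges:
            iu, iv = self._gene_index[u], self._gene_index[v]
            parent_masks[iv] |= 1 << iu
        total = 0.0
        for g in net.nodes:
            i = self._gene_index[g]
            total += self.node_score_masked(i, parent_masks[i])
        return total  # + log p(D) = 0 under the uniform prior


def log_node_score(
    node: str,
    parents: Iterable[str],
    data: ExpressionMatrix,
    params: ScoreParams | None = None,
) -> float:
    """Log marginal-likelihood contribution of one node given its parents.

    The scoring scope (which fixes the hyperparameter defaults) is the full
    gene set of ``data``; it depends on the data only through the columns of
    ``{node} | parents``.
    """
    return BGeScorer(data, params).node_score(node, parents)


def log_network_score(
    net: DirectedNetwork,
    data: ExpressionMatrix,
    params: ScoreParams | None = None,
) -> float:
    """Log network score N(D) = sum of node contributions + log p(D).

    Decomposable: changing one node's parent set changes only that node's
    term.  Raises :class:`CyclicNetworkError` on cyclic input.
    """
    scoped = data.subset(net.nodes)
    return BGeScorer(scoped, params).network_score(net)
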