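# trinet — gene regulatory network inference from gene triplets

`trinet` infers a directed gene regulatory network from a continuous
expression matrix (genes × samples) with a divide-and-unite Bayesian-network
strategy:

1. **Divide.** The gene set *V* is split into all C(n, 3) three-gene subsets
   (*triplets*).
2. **Score exhaustively.** For each triplet, every candidate directed
   network — one of {i→j, j→i, no edge} per gene pair, 3³ = 27
   configurations of which 25 are acyclic — is scored with a decomposable,
   score-equivalent Gaussian (BGe) marginal likelihood
   N(D) = log p(D, d) = log p(d | D) + log p(D), and stored as a tuple
   (D, S_D, R_D) of network, score and within-triplet rank in a store *Z*.
3. **Unite.** For each unordered gene pair, the rank-1 networks of all
   triplets containing the pair vote with their scores for one of the three
   edge types; the strictly largest total wins.  Ties escalate first to
   triplets already anchored to the partially built network, then to deeper
   ranks.  Because pairs are decided independently, the united network
   **may contain directed cycles** — something no single Bayesian network
   can represent.

The cost is O(n³) triplet scorings instead of a search over the
super-exponential DAG space, and the whole pipeline is deterministic given
the data.  The package also ships the classical greedy hill-climbing (GHC)
baseline (add/delete/reverse one edge, best strict improvement, action
budget 50, restarts 0 by default), an exhaustive-search oracle for up to six
genes, and a synthetic linear-Gaussian benchmark, so the method's claims can
be tested end to end without any external dataset.

## Worked example

Simulate data from a planted 8-gene linear-Gaussian network, infer the
united network, and evaluate it against the planted truth:

```bash
trinet simulate --n-genes 8 --seed 7 --out-prefix demo
# simulated 8 genes x 100 samples, 7 true edges -> demo.*
trinet infer --input demo.expr.tsv --output demo.net.sif --audit demo.audit.tsv
# united network: 9 edges over 8 genes -> demo.net.sif
trinet evaluate --estimated demo.net.sif --truth demo.truth.sif --output demo.eval.tsv
# sensitivity 28.6%, selectivity 22.2% -> demo.eval.tsv
```

`demo.net.sif` lists directed edges (`g1 regulates g7`, ...), and the audit
table records, per gene pair, the log-score totals of the three edge types,
the chosen type and the rank at which the decision fell:

```
gene_a  gene_b  total_forward  total_backward  total_absent  chosen  decided_at_rank
g1      g2      -inf           -inf            -302.66       absent  1
```

Single replicates are noisy (on this seed the union misorients several
edges); the replicated comparison is the meaningful view.  `trinet compare`
simulates many datasets and runs the union method and GHC on identical data:

```bash
printf 'n_genes = 5\nn_replicates = 20\nseed = 1\n' > compare.cfg
trinet compare --config compare.cfg --output-prefix cmp
```

which prints (abridged):

```
metric                    mean         sem  median   n
union_sensitivity     0.523333    0.076504    0.55  20
union_selectivity     0.480357    0.069010    0.50  20
ghc_sensitivity       0.528333    0.069133    0.50  20
ghc_selectivity       0.449167    0.068703    0.50  20
union_rank         1276.600000  636.196508    2.50  20
ghc_rank             86.350000   37.322018    6.50  20
```

`union_rank`/`ghc_rank` locate each estimate in the exhaustive score ranking
of all 29,281 five-gene DAGs (1 = the global score optimum): here the union
method's median rank (2.5) beats default GHC's (6.5), while the means are
dominated by a few replicates where either method lands far down the
ranking.

Other commands: `trinet exhaustive` (full ranked DAG table for ≤ 6 genes)
and `trinet ghc` (the baseline search).  All commands accept a flat
`key = value` config file; explicit flags win, and the resolved
configuration is written next to each output for provenance.

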