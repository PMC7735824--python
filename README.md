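# pmdne

Bipartite network embedding for miRNA–disease association prediction.

Curated databases record which miRNAs are implicated in which diseases,
but the catalogue is incomplete.  `pmdne` ranks unobserved (miRNA,
disease) pairs by learning a d-dimensional vector for every node of the
association network and scoring candidate pairs with a supervised
classifier.  The embedding jointly optimizes

```
maximize  L = α·log O2 + β·log O3 − γ·O1
```

where `O1 = −Σ_{(i,j)∈E} w_ij log σ(u_i·v_j)` is an explicit first-order
proximity term over the bipartite edges, and `O2`, `O3` are skip-gram
negative-sampling likelihoods over random-walk corpora generated on the
two *homogeneous projections*

```
W(i,j) = Σ_k w_ik·w_jk + coeff · sim(i,j)
```

(shared opposite-partition neighbors plus an optional intra-partition
similarity matrix weighted by `c` on the disease side and `e` on the
miRNA side).  Walks have variable length — each walk stops with
probability 0.15 per step, capped at 32 nodes — and walk budgets are
allocated by node importance (weighted degree or HITS).  Everything is
deterministic given a seed.

The library also ships a synthetic-data generator (planted block structure
plus block-correlated similarity matrices) so the entire pipeline can be
exercised and tested without any external download.

## Worked example

```
$ pmdne simulate --n-u 60 --n-v 60 --blocks 2 --p-in 0.3 --p-out 0.02 --seed 7 --out-dir data
wrote 580 edges, 1330 + 1321 similarity entries to data

$ pmdne train --edges data/edges.tsv --sim-u data/sim_u.tsv --sim-v data/sim_v.tsv \
      --dim 32 --epochs 20 --seed 7 --out emb.txt
wrote 120 node vectors (d=32) to emb.txt

$ pmdne evaluate --edges data/edges.tsv --sim-u data/sim_u.tsv --sim-v data/sim_v.tsv \
      --dim 32 --epochs 20 --seed 7 --k 5 --report report.json
metric     mean      sd
roc_auc    0.8703    0.0306
pr_auc     0.8221    0.0506
precision  0.7537    0.0322
accuracy   0.8026    0.0344
f1         0.8202    0.0308
recall     0.9000    0.0359
```

`simulate` writes a planted two-block bipartite network (60+60 nodes, 580
associations) with block-correlated similarity matrices.  `train` learns
one 32-dimensional vector per node (word2vec text format, ids namespaced
`u:`/`v:`).  `evaluate` balances the 580 positives with 580 sampled
non-edges, featurizes each pair (Hadamard product of the endpoint
vectors), and reports five-fold cross-validated metrics for a random
forest: here the planted structure is recovered with ROC-AUC ≈ 0.87,
and recall 0.90 at the 0.5 probability threshold.  Adding `--ablation`
re-runs the evaluation with both / neither / one similarity network.

The same pipeline is available as a library:

```python
from pmdne import Hyperparams, cross_validate, make_synthetic

data = make_synthetic(seed=1)                    # 100+100 nodes, 2 blocks
hp = Hyperparams(d=32, epochs=20, seed=1)
report = cross_validate(data.network, (data.sim_u, data.sim_v), hp, k=5,
                        classifier="RF", rng_seed=1)
print(report.mean["roc_auc"])                    # ~0.84
```

Real data plugs in the same way: a tab-separated edge list
(`miRNA  disease  [weight]`) and optional similarity matrices (sparse
triples or a square labelled matrix; partial coverage is fine — uncovered
pairs contribute similarity 0).

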