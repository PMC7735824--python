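"""Joint embedding of the bipartite network.

The model learns one d-dimensional vector per node by maximizing

    L = alpha * log O2 + beta * log O3 - gamma * O1

where O1 is an explicit first-order term over the bipartite edges — the KL
divergence between edge-weight proportions and the sigmoid of embedded dot
products, optimized in its proportional form
``-sum_ij w_ij log sigma(u_i . v_j)`` — and O2/O3 are skip-gram
with-negative-sampling likelihoods over random-walk corpora on the miRNA-
and disease-side homogeneous projections.  All three terms are optimized by
stochastic gradient descent with a constant learning rate; the per-sample
update rules are closed-form and implemented exactly as derived (within one
update call all gradients use the pre-update vectors).

Context ("output") vectors theta / vartheta are kept separately per
partition, word2vec style, and start at zero; node vectors start uniform in
[-0.5/d, 0.5/d].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .net_io import BipartiteNetwork, SimilarityNetwork
from .projection import project_homogeneous
from .walker import WalkCorpus, allocate_walks, generate_walks, node_importance

__all__ = [
    "Hyperparams",
    "EmbeddingModel",
    "joint_proximity",
    "embedded_proximity",
    "explicit_loss",
    "sgd_update_explicit",
    "sample_negatives",
    "sgd_update_skipgram",
    "train",
    "sweep",
    "embed_network",
]

_CLIP = 50.0


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_CLIP, _CLIP)))


@dataclass(frozen=True)
class Hyperparams:
    """Training configuration.

    alpha, beta, gamma weight the miRNA-side skip-gram term, the
    disease-side skip-gram term and the explicit first-order term
    respectively (defaults 1e-4, 1e-2, 0.1); c and e weight the disease and
    miRNA similarity networks inside the homogeneous projections (default
    0.5 each).  Walks stop with probability ``stop_prob`` per step once
    ``min_t`` nodes long and are capped at ``max_t`` nodes.
    """

    d: int = 128
    ws: int = 5
    ns: int = 5
    alpha: float = 1e-4
    beta: float = 1e-2
    gamma: float = 0.1
    lam: float = 1.0
    epochs: int = 50
    tol: float = 1e-4
    seed: int = 7
    c: float = 0.5
    e: float = 0.5
    max_t: int = 32
    min_t: int = 1
    stop_prob: float = 0.15
    walks_per_node: int = 10
    importance: str = "degree"
    weighted_transitions: bool = True

    def __post_init__(self) -> None:
        if self.d < 1 or self.ws < 1 or self.ns < 0:
            raise ValueError("require d >= 1, ws >= 1, ns >= 0")
        if min(self.alpha, self.beta, self.gamma, self.c, self.e) < 0:
            raise ValueError("objective and similarity coefficients must be >= 0")
        if self.lam <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class EmbeddingModel:
    """Node and context vectors for both partitions.

    ``u_emb``/``v_emb`` hold the node vectors (rows follow ``u_ids`` /
    ``v_ids``); ``u_ctx``/``v_ctx`` the skip-gram context vectors.
    ``loss_history`` records (O1, O2, O3, L) per epoch, where O2/O3 are the
    sampled skip-gram log-likelihoods of that epoch's pass.
    """

    u_ids: list[str]
    v_ids: list[str]
    u_emb: np.ndarray
    v_emb: np.ndarray
    u_ctx: np.ndarray
    v_ctx: np.ndarray
    loss_history: list[tuple[float, float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.u_index = {n: i for i, n in enumerate(self.u_ids)}
        self.v_index = {n: i for i, n in enumerate(self.v_ids)}

    @property
    def d(self) -> int:
        return self.u_emb.shape[1] if self.u_emb.size else self.v_emb.shape[1]

    @property
    def n_nodes(self) -> int:
        return len(self.u_ids) + len(self.v_ids)

    @property
    def u_vec(self) -> dict[str, np.ndarray]:
        return {n: self.u_emb[i] for n, i in self.u_index.items()}

    @property
    def v_vec(self) -> dict[str, np.ndarray]:
        return {n: self.v_emb[i] for n, i in self.v_index.items()}

    def vector(self, side: str, node: str) -> np.ndarray:
        if side == "U":
            return self.u_emb[self.u_index[node]]
        if side == "V":
            return self.v_emb[self.v_index[node]]
        raise ValueError(f"side must be 'U' or 'V', got {side!r}")

    def iter_vectors(self):
        """Yield (namespaced id, node vector) across both partitions."""
        for n, i in self.u_index.items():
            yield "u:" + n, self.u_emb[i]
        for n, i in self.v_index.items():
            yield "v:" + n, self.v_emb[i]

    @classmethod
    def initialize(cls, u_ids: list[str], v_ids: list[str], d: int, seed) -> "EmbeddingModel":
        """Seeded initialization: node vectors uniform with per-dimension
        variance 1/d (half-width sqrt(3/d)), so every node starts with a
        distinguishable unit-scale random signature; context vectors zero.
        """
        rng = np.random.default_rng(seed)
        a = np.sqrt(3.0 / d)
        return cls(
            u_ids=list(u_ids),
            v_ids=list(v_ids),
            u_emb=(rng.random((len(u_ids), d)) - 0.5) * 2.0 * a,
            v_emb=(rng.random((len(v_ids), d)) - 0.5) * 2.0 * a,
            u_ctx=np.zeros((len(u_ids), d)),
            v_ctx=np.zeros((len(v_ids), d)),
        )


# ---------------------------------------------------------------------------
# first-order (explicit) term


def joint_proximity(bn: BipartiteNetwork) -> dict[tuple[str, str], float]:
    """Empirical co-occurrence probability of each edge: w_ij / sum of all
    edge weights."""
    if not bn.edges:
        raise ValueError("network has no edges")
    total = sum(bn.edges.values())
    return {e: w / total for e, w in bn.edges.items()}


def embedded_proximity(u: np.ndarray, v: np.ndarray) -> float:
    """sigma(u . v): the modelled probability that two nodes co-occur."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    return float(_sigmoid(u @ v))


def explicit_loss(bn: BipartiteNetwork, model: EmbeddingModel) -> float:
    """O1 in its minimized proportional form: -sum_ij w_ij log sigma(u_i . v_j)."""
    loss = 0.0
    for (u, v), w in bn.edges.items():
        loss -= w * np.log(_sigmoid(model.u_emb[model.u_index[u]] @ model.v_emb[model.v_index[v]]))
    return float(loss)


def sgd_update_explicit(
    model: EmbeddingModel,
    edge: tuple[str, str, float],
    lam: float,
    gamma: float,
) -> EmbeddingModel:
    """One stochastic step on the explicit term for a single edge:

        u_i += lam * gamma * w_ij * (1 - sigma(u_i . v_j)) * v_j
        v_j += lam * gamma * w_ij * (1 - sigma(u_i . v_j)) * u_i

    both computed from the pre-update vectors.  Updates in place and
    returns the model.
    """
    u, v, w = edge
    i, j = model.u_index[u], model.v_index[v]
    ui = model.u_emb[i].copy()
    vj = model.v_emb[j].copy()
    g = lam * gamma * w * (1.0 - _sigmoid(ui @ vj))
    model.u_emb[i] = ui + g * vj
    model.v_emb[j] = vj + g * ui
    return model


# ---------------------------------------------------------------------------
# second-order (skip-gram) terms


def sample_negatives(
    vocab_freq: dict[str, int],
    center: str,
    window_context,
    ns: int,
    rng: np.random.Generator,
) -> list[str]:
    """Draw ``ns`` negatives from the smoothed unigram distribution
    (frequency ** 0.75, renormalized), rejecting the center and the window
    context."""
    if not vocab_freq:
        raise ValueError("empty vocabulary")
    excluded = set(window_context) | {center}
    if not any(f > 0 for n, f in vocab_freq.items() if n not in excluded):
        raise ValueError("vocabulary minus exclusions is empty")
    if ns == 0:
        return []
    tokens = list(vocab_freq)
    probs = np.array([vocab_freq[t] for t in tokens], dtype=float) ** 0.75
    cdf = np.cumsum(probs / probs.sum())
    out: list[str] = []
    while len(out) < ns:
        draws = np.searchsorted(cdf, rng.random(ns - len(out)), side="right")
        for k in draws:
            tok = tokens[min(int(k), len(tokens) - 1)]
            if tok not in excluded:
                out.append(tok)
                if len(out) == ns:
                    break
    return out


def sgd_update_skipgram(
    model: EmbeddingModel,
    partition: str,
    center: str,
    window_context,
    negatives,
    lam: float,
    coef: float,
) -> EmbeddingModel:
    """One skip-gram-with-negative-sampling step for a single center node.

    For each z in the window context (indicator I = 1) and each sampled
    negative (I = 0):

        center_vec += lam * coef * (I - sigma(center_vec . ctx_z)) * ctx_z
        ctx_z      += lam * coef * (I - sigma(center_vec . ctx_z)) * center_vec

    with all gradients taken at the pre-update vectors.  ``coef`` is alpha
    on partition U, beta on partition V.
    """
    if partition == "U":
        emb, ctx, index = model.u_emb, model.u_ctx, model.u_index
    elif partition == "V":
        emb, ctx, index = model.v_emb, model.v_ctx, model.v_index
    else:
        raise ValueError(f"partition must be 'U' or 'V', got {partition!r}")
    try:
        c = index[center]
        z_idx = np.array([index[z] for z in list(window_context) + list(negatives)], dtype=int)
    except KeyError as err:
        raise KeyError(f"node {err.args[0]!r} missing from model") from None
    if z_idx.size == 0:
        return model
    indicator = np.concatenate(
        [np.ones(len(list(window_context))), np.zeros(len(list(negatives)))]
    )
    center_vec = emb[c].copy()
    m = ctx[z_idx]  # (n_z, d) copy of pre-update context vectors
    g = lam * coef * (indicator - _sigmoid(m @ center_vec))
    emb[c] = center_vec + g @ m
    np.add.at(ctx, z_idx, g[:, None] * center_vec)
    return model


class _CorpusArrays:
    """Integer-encoded corpus with the smoothed unigram sampler state."""

    def __init__(self, corpus: WalkCorpus, index: dict[str, int], n_nodes: int):
        self.walks = [np.array([index[t] for t in w], dtype=np.int64) for w in corpus.walks]
        counts = np.zeros(n_nodes)
        for w in self.walks:
            np.add.at(counts, w, 1.0)
        probs = counts**0.75
        total = probs.sum()
        self.cdf = np.cumsum(probs / total) if total > 0 else None
        self.n_positive = int((counts > 0).sum())


def _draw_negatives(cdf: np.ndarray, ns: int, excluded: set, rng: np.random.Generator) -> list[int]:
    out: list[int] = []
    for _ in range(1000):
        draws = np.searchsorted(cdf, rng.random(ns - len(out)), side="right")
        for k in draws:
            k = min(int(k), len(cdf) - 1)
            if k not in excluded:
                out.append(k)
                if len(out) == ns:
                    return out
    return out  # excluded set covers nearly all mass; train with what we have


def train(
    bn: BipartiteNetwork,
    corpus_u: WalkCorpus,
    corpus_v: WalkCorpus,
    hp: Hyperparams,
) -> EmbeddingModel:
    """Run the joint SGD optimization.

    Each epoch interleaves (a) one skip-gram pass over every (center,
    window) pair of both corpora — walks visited in a fresh shuffled order,
    ``ns`` fresh negatives per pair — and (b) one pass of explicit updates
    over the bipartite edges in shuffled order.  Training stops after
    ``hp.epochs`` epochs or when the relative change of the tracked
    objective falls below ``hp.tol``.  Fully deterministic given
    ``hp.seed``.
    """
    if hp.gamma == 0 and not corpus_u.walks and not corpus_v.walks:
        raise ValueError("nothing to optimize: empty corpora and gamma = 0")

    model = EmbeddingModel.initialize(bn.u_nodes, bn.v_nodes, hp.d, seed=[hp.seed, 0])
    if hp.epochs == 0:
        return model

    sides = [
        (_CorpusArrays(corpus_u, model.u_index, bn.n_u), model.u_emb, model.u_ctx, hp.alpha),
        (_CorpusArrays(corpus_v, model.v_index, bn.n_v), model.v_emb, model.v_ctx, hp.beta),
    ]
    edge_list = [
        (model.u_index[u], model.v_index[v], w) for (u, v), w in bn.edges.items()
    ]
    lam, ws, ns = hp.lam, hp.ws, hp.ns

    prev_loss = None
    for epoch in range(hp.epochs):
        rng = np.random.default_rng([hp.seed, 1 + epoch])
        sampled_ll = [0.0, 0.0]
        for side_no, (arrays, emb, ctx, coef) in enumerate(sides):
            ll = 0.0
            for wi in rng.permutation(len(arrays.walks)):
                walk = arrays.walks[wi]
                length = len(walk)
                for t in range(length):
                    lo = max(0, t - ws)
                    n_ctx = (t - lo) + min(length - t - 1, ws)
                    if n_ctx == 0:
                        continue
                    context = np.concatenate([walk[lo:t], walk[t + 1 : t + 1 + ws]])
                    center = int(walk[t])
                    if ns > 0 and arrays.n_positive > len(set(context)) + 1:
                        negs = _draw_negatives(
                            arrays.cdf, ns, set(context) | {center}, rng
                        )
                    else:
                        negs = []
                    z_idx = np.concatenate([context, np.array(negs, dtype=np.int64)])
                    indicator = np.concatenate([np.ones(n_ctx), np.zeros(len(negs))])
                    center_vec = emb[center].copy()
                    m = ctx[z_idx]
                    s = _sigmoid(m @ center_vec)
                    ll += float(np.log(s[:n_ctx]).sum() + np.log1p(-s[n_ctx:]).sum())
                    g = lam * coef * (indicator - s)
                    emb[center] = center_vec + g @ m
                    np.add.at(ctx, z_idx, g[:, None] * center_vec)
            sampled_ll[side_no] = ll

        if hp.gamma > 0:
            for ei in rng.permutation(len(edge_list)):
                i, j, w = edge_list[ei]
                ui = model.u_emb[i].copy()
                vj = model.v_emb[j].copy()
                g = lam * hp.gamma * w * (1.0 - _sigmoid(ui @ vj))
                model.u_emb[i] = ui + g * vj
                model.v_emb[j] = vj + g * ui

        o1 = explicit_loss(bn, model)
        o2, o3 = sampled_ll
        objective = hp.alpha * o2 + hp.beta * o3 - hp.gamma * o1  # maximized
        model.loss_history.append((o1, o2, o3, objective))
        if prev_loss is not None:
            if abs(objective - prev_loss) <= hp.tol * max(abs(prev_loss), 1e-12):
                break
        prev_loss = objective

    if not (np.isfinite(model.u_emb).all() and np.isfinite(model.v_emb).all()):
        raise FloatingPointError("training diverged: non-finite embeddings")
    return model


def embed_network(
    bn: BipartiteNetwork,
    sim_u: SimilarityNetwork | None,
    sim_v: SimilarityNetwork | None,
    hp: Hyperparams,
) -> EmbeddingModel:
    """Full embedding pipeline: project both partitions (similarity
    coefficients ``e`` for the miRNA side, ``c`` for the disease side),
    allocate importance-weighted walk budgets, generate the two corpora and
    train the joint model."""
    corpora = {}
    for side, sim, coeff, tag in (("U", sim_u, hp.e, 1), ("V", sim_v, hp.c, 2)):
        proj = project_homogeneous(bn, side, sim, coeff)
        n = proj.n_nodes
        imp = node_importance(proj, hp.importance)
        if sum(imp.scores.values()) > 0:
            counts = allocate_walks(imp, hp.walks_per_node * n)
        else:  # edgeless projection: one trivial walk per node
            counts = {node: 1 for node in proj.nodes}
        corpora[side] = generate_walks(
            proj,
            counts,
            max_t=hp.max_t,
            min_t=hp.min_t,
            stop_prob=hp.stop_prob,
            rng_seed=[hp.seed, 100 + tag],
            weighted=hp.weighted_transitions,
        )
    return train(bn, corpora["U"], corpora["V"], hp)


def sweep(hp_grid: dict, evaluate, base_hp: Hyperparams | None = None) -> pd.DataFrame:
    """Grid analysis over {ws, ns, d, alpha, beta, gamma}.

    ``evaluate`` is called with one Hyperparams per setting and must return
    (roc_auc, pr_auc).  Returns a table with one row per (parameter, value)
    in grid order.
    """
    allowed = {"ws", "ns", "d", "alpha", "beta", "gamma"}
    base = base_hp if base_hp is not None else Hyperparams()
    rows = []
    for param, values in hp_grid.items():
        if param not in allowed:
            raise ValueError(f"unknown sweep parameter {param!r}")
        for value in values:
            roc, pr = evaluate(replace(base, **{param: value}))
            rows.append(
                {"parameter": param, "value": value, "roc_auc": roc, "pr_auc": pr}
            )
    return pd.DataFrame(rows, columns=["parameter", "value", "roc_auc", "pr_auc"])
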