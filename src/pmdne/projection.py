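"""Homogeneous (same-partition) projections of the bipartite graph.

Two diseases that share associated miRNAs — or two miRNAs that share
diseases — are linked in the projected network with weight

    W(i, j) = sum_k w_ik * w_jk + coeff * sim(i, j),

the co-neighbor weight product over the opposite partition plus the
precomputed intra-partition similarity scaled by a nonnegative coefficient
(``c`` on the disease side, ``e`` on the miRNA side; both default 0.5).
Setting the coefficient to 0 gives the pure co-neighbor projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .net_io import BipartiteNetwork, SimilarityNetwork

__all__ = ["HomogeneousNetwork", "project_homogeneous", "degree_map"]


@dataclass
class HomogeneousNetwork:
    """Weighted undirected same-partition network; no self-loops, zero
    weights not stored."""

    nodes: list[str]
    weights: dict[tuple[str, str], float]  # canonical (min, max) keys
    sim_coefficient: float = 0.0
    _adj: dict[str, list[tuple[str, float]]] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for (i, j), w in self.weights.items():
            if i == j:
                raise ValueError("self-loops are not allowed")
            if i > j:
                raise ValueError(f"non-canonical edge key ({i!r}, {j!r})")
            if i not in node_set or j not in node_set:
                raise ValueError("edge endpoint outside the node set")
            if not w > 0:
                raise ValueError(f"non-positive stored weight {w!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def adjacency(self) -> dict[str, list[tuple[str, float]]]:
        """Neighbor lists ``node -> [(neighbor, weight), ...]`` in node order."""
        if self._adj is None:
            adj: dict[str, list[tuple[str, float]]] = {n: [] for n in self.nodes}
            for (i, j), w in self.weights.items():
                adj[i].append((j, w))
                adj[j].append((i, w))
            self._adj = adj
        return self._adj

    def dense_matrix(self) -> np.ndarray:
        index = {n: k for k, n in enumerate(self.nodes)}
        a = np.zeros((self.n_nodes, self.n_nodes))
        for (i, j), w in self.weights.items():
            a[index[i], index[j]] = w
            a[index[j], index[i]] = w
        return a

    def to_tsv(self, path: str) -> None:
        """Export as sparse triples for inspection."""
        with open(path, "w") as fh:
            for (i, j), w in sorted(self.weights.items()):
                fh.write(f"{i}\t{j}\t{w:.10g}\n")


def project_homogeneous(
    bn: BipartiteNetwork,
    side: str,
    sim: SimilarityNetwork | None = None,
    coefficient: float = 0.5,
) -> HomogeneousNetwork:
    """Project one partition of ``bn`` onto a homogeneous weighted network.

    ``side`` is ``"U"`` (miRNA-like) or ``"V"`` (disease-like).  The
    co-neighbor term is computed as the sparse product B·Bᵀ of the bipartite
    weight matrix; the similarity term adds ``coefficient * sim(i, j)`` for
    covered pairs.  Diagonal entries are discarded and pairs with total
    weight 0 are not stored.
    """
    if coefficient < 0:
        raise ValueError(f"similarity coefficient must be nonnegative, got {coefficient}")
    if side not in ("U", "V"):
        raise ValueError(f"side must be 'U' or 'V', got {side!r}")
    nodes = bn.u_nodes if side == "U" else bn.v_nodes
    node_set = set(nodes)
    if sim is not None and not set(sim.nodes) <= node_set:
        raise ValueError("similarity network covers nodes outside the chosen partition")

    index = {n: k for k, n in enumerate(nodes)}
    opp = bn.v_nodes if side == "U" else bn.u_nodes
    opp_index = {n: k for k, n in enumerate(opp)}

    rows, cols, vals = [], [], []
    for (u, v), w in bn.edges.items():
        i, j = (u, v) if side == "U" else (v, u)
        rows.append(index[i])
        cols.append(opp_index[j])
        vals.append(w)
    b = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(nodes), len(opp))
    )
    b.sum_duplicates()
    b.sort_indices()
    p = (b @ b.T).tocoo()

    weights: dict[tuple[str, str], float] = {}
    for r, c, w in zip(p.row, p.col, p.data):
        if r < c and w != 0.0:
            weights[(min(nodes[r], nodes[c]), max(nodes[r], nodes[c]))] = float(w)

    if sim is not None and coefficient > 0:
        for (i, j), s in sim.sim.items():
            if s == 0.0:
                continue
            key = (min(i, j), max(i, j))
            total = weights.get(key, 0.0) + coefficient * s
            if total != 0.0:
                weights[key] = total
    return HomogeneousNetwork(nodes=list(nodes), weights=weights, sim_coefficient=coefficient)


def degree_map(hn: HomogeneousNetwork) -> dict[str, float]:
    """Weighted degree of every node (sum of incident weights; isolated -> 0)."""
    deg = {n: 0.0 for n in hn.nodes}
    for (i, j), w in hn.weights.items():
        deg[i] += w
        deg[j] += w
    return deg
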