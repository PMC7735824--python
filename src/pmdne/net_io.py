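"""Plain-text I/O for bipartite association networks, similarity matrices
and node embeddings.

Formats
-------
* Association edge list: tab/whitespace separated, one edge per line,
  ``<u_id> <v_id> [weight]``; a missing weight column means weight 1.
* Similarity: either a 3-column sparse triple list ``<i> <j> <value>`` or a
  square labelled matrix (first row = column labels, first column = row
  labels).
* Embeddings: word2vec text convention — header ``<n_nodes> <d>`` then one
  line ``<id> <v1> ... <vd>`` per node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BipartiteNetwork",
    "SimilarityNetwork",
    "read_association_edges",
    "read_similarity_matrix",
    "write_embeddings",
    "read_embeddings",
]


@dataclass
class BipartiteNetwork:
    """Weighted bipartite association graph.

    Partition U holds the miRNA-like nodes, partition V the disease-like
    nodes.  Edges are keyed ``(u, v)``; an absent pair has implicit weight 0
    and every stored weight is positive (known associations default to 1).
    The two partitions are stored separately, so identical raw labels on the
    two sides cannot collide.
    """

    u_nodes: list[str]
    v_nodes: list[str]
    edges: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        u_set, v_set = set(self.u_nodes), set(self.v_nodes)
        if len(u_set) != len(self.u_nodes) or len(v_set) != len(self.v_nodes):
            raise ValueError("duplicate node identifiers within a partition")
        for (u, v), w in self.edges.items():
            if u not in u_set:
                raise ValueError(f"edge endpoint {u!r} missing from partition U")
            if v not in v_set:
                raise ValueError(f"edge endpoint {v!r} missing from partition V")
            if not w > 0:
                raise ValueError(f"non-positive edge weight {w!r} for ({u!r}, {v!r})")

    @property
    def n_u(self) -> int:
        return len(self.u_nodes)

    @property
    def n_v(self) -> int:
        return len(self.v_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight_matrix(self) -> np.ndarray:
        """Dense ``n_u x n_v`` weight matrix (0 for absent pairs)."""
        u_index = {u: i for i, u in enumerate(self.u_nodes)}
        v_index = {v: j for j, v in enumerate(self.v_nodes)}
        w = np.zeros((self.n_u, self.n_v))
        for (u, v), val in self.edges.items():
            w[u_index[u], v_index[v]] = val
        return w


@dataclass
class SimilarityNetwork:
    """Symmetric nonnegative intra-partition similarity.

    ``nodes`` is the coverage set, which may be a strict subset of the
    partition (real miRNA functional similarity covers only part of the
    network); any pair not stored — including pairs touching uncovered
    nodes — has similarity 0.  Entries are stored once under a canonical
    ``(min, max)`` key; the diagonal is never stored.
    """

    nodes: list[str]
    sim: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for (i, j), s in self.sim.items():
            if i == j:
                raise ValueError("self-similarity entries are not stored")
            if (i, j) != self._key(i, j):
                raise ValueError(f"non-canonical similarity key ({i!r}, {j!r})")
            if i not in node_set or j not in node_set:
                raise ValueError("similarity entry outside the coverage set")
            if s < 0:
                raise ValueError(f"negative similarity {s!r}")

    @staticmethod
    def _key(i: str, j: str) -> tuple[str, str]:
        return (i, j) if i <= j else (j, i)

    def get(self, i: str, j: str) -> float:
        if i == j:
            return 0.0
        return self.sim.get(self._key(i, j), 0.0)

    def set(self, i: str, j: str, value: float) -> None:
        if value < 0:
            raise ValueError(f"negative similarity {value!r}")
        self.sim[self._key(i, j)] = value

    @property
    def coverage(self) -> int:
        return len(self.nodes)

    @classmethod
    def empty(cls) -> "SimilarityNetwork":
        return cls(nodes=[], sim={})


def _tokenize(path: str) -> list[list[str]]:
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if toks and not toks[0].startswith("#"):
                rows.append(toks)
    return rows


def read_association_edges(path: str) -> BipartiteNetwork:
    """Read a bipartite edge list; node order is first-appearance order.

    A third column, when present, is the edge weight (must be positive);
    otherwise every edge gets weight 1.  Exact duplicate lines are tolerated,
    but a duplicate pair with a conflicting weight is an error.
    """
    rows = _tokenize(path)
    if not rows:
        raise ValueError(f"empty association file: {path}")
    u_nodes: list[str] = []
    v_nodes: list[str] = []
    u_seen: set[str] = set()
    v_seen: set[str] = set()
    edges: dict[tuple[str, str], float] = {}
    for toks in rows:
        if len(toks) not in (2, 3):
            raise ValueError(f"expected 2 or 3 columns, got {len(toks)}: {toks!r}")
        u, v = toks[0], toks[1]
        w = float(toks[2]) if len(toks) == 3 else 1.0
        if not w > 0:
            raise ValueError(f"non-positive weight {w} for edge ({u}, {v})")
        if (u, v) in edges and edges[(u, v)] != w:
            raise ValueError(f"duplicate edge ({u}, {v}) with conflicting weights")
        if u not in u_seen:
            u_seen.add(u)
            u_nodes.append(u)
        if v not in v_seen:
            v_seen.add(v)
            v_nodes.append(v)
        edges[(u, v)] = w
    return BipartiteNetwork(u_nodes=u_nodes, v_nodes=v_nodes, edges=edges)


def _looks_like_triples(rows: list[list[str]]) -> bool:
    first = rows[0]
    if len(first) != 3:
        return False
    try:
        float(first[2])
    except ValueError:
        return False
    return True


def read_similarity_matrix(path: str, partition: list[str] | set[str]) -> SimilarityNetwork:
    """Read similarity data, symmetrize it, and restrict it to ``partition``.

    Accepts either a 3-column sparse list or a square labelled matrix.  If a
    pair appears in both orientations with different values the two are
    averaged (with a warning).  Entries naming nodes outside ``partition``
    are dropped with a warning; negative values are an error.  Diagonal
    entries are discarded — self-similarity plays no role downstream.
    """
    rows = _tokenize(path)
    if not rows:
        raise ValueError(f"empty similarity file: {path}")
    partition_set = set(partition)

    raw: dict[tuple[str, str], float] = {}  # directed, as read
    if _looks_like_triples(rows):
        for toks in rows:
            if len(toks) != 3:
                raise ValueError(f"expected 3 columns in sparse list, got {toks!r}")
            raw[(toks[0], toks[1])] = float(toks[2])
    else:
        col_labels = rows[0]
        body = rows[1:]
        # tolerate an optional corner token in the header
        if body and len(rows[0]) == len(body[0]):
            col_labels = rows[0][1:]
        if len(body) != len(col_labels):
            raise ValueError(
                f"non-square labelled matrix: {len(body)} rows, {len(col_labels)} columns"
            )
        for toks in body:
            if len(toks) != len(col_labels) + 1:
                raise ValueError(f"matrix row has wrong length: {toks!r}")
            i = toks[0]
            for j, val in zip(col_labels, toks[1:]):
                raw[(i, j)] = float(val)

    dropped: set[str] = set()
    pair_values: dict[tuple[str, str], list[float]] = {}
    for (i, j), s in raw.items():
        if s < 0:
            raise ValueError(f"negative similarity {s} for ({i}, {j})")
        if i == j:
            continue
        if i not in partition_set or j not in partition_set:
            dropped.update({i, j} - partition_set)
            continue
        pair_values.setdefault(SimilarityNetwork._key(i, j), []).append(s)
    if dropped:
        warnings.warn(
            f"dropped similarity entries for {len(dropped)} node(s) outside the partition",
            stacklevel=2,
        )

    sim: dict[tuple[str, str], float] = {}
    asymmetric = 0
    covered: set[str] = set()
    for key, vals in pair_values.items():
        if len(vals) > 1 and max(vals) != min(vals):
            asymmetric += 1
        sim[key] = float(np.mean(vals))
        covered.update(key)
    if asymmetric:
        warnings.warn(
            f"averaged {asymmetric} asymmetric similarity pair(s)", stacklevel=2
        )
    nodes = [n for n in partition if n in covered] if not isinstance(partition, set) else sorted(covered)
    return SimilarityNetwork(nodes=nodes, sim=sim)


def write_embeddings(model, path: str) -> None:
    """Write all node vectors in word2vec text format.

    The two partitions share one file, so ids are namespaced ``u:<id>`` /
    ``v:<id>`` to rule out collisions.  Values are printed with 10
    significant digits, enough for a 1e-7 round trip.
    """
    lines = [f"{model.n_nodes} {model.d}"]
    for node, vec in model.iter_vectors():
        lines.append(node + " " + " ".join(f"{x:.10g}" for x in vec))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_embeddings(path: str) -> dict[str, np.ndarray]:
    """Read a word2vec-format text file back into an id -> vector map."""
    rows = _tokenize(path)
    if not rows:
        raise ValueError(f"empty embedding file: {path}")
    n, d = int(rows[0][0]), int(rows[0][1])
    if len(rows) - 1 != n:
        raise ValueError(f"header promises {n} vectors, file has {len(rows) - 1}")
    out: dict[str, np.ndarray] = {}
    for toks in rows[1:]:
        if len(toks) != d + 1:
            raise ValueError(f"vector line has wrong length: {toks[0]!r}")
        out[toks[0]] = np.array([float(x) for x in toks[1:]])
    return out
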