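"""Variable-length random-walk corpus generation.

Walks play the role of sentences for the skip-gram stage.  Rather than the
fixed-length truncated walks of DeepWalk, each walk terminates with a fixed
per-step stop probability (default 0.15) once it has reached the minimum
length (default 1), and is hard-capped at ``max_t`` nodes (default 32) — so
walk lengths follow a truncated geometric law, mimicking the variable
length of natural-language sentences.  More walks start from structurally
important nodes: the per-node walk budget is allocated proportionally to a
centrality score, either weighted degree or HITS authority.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .projection import HomogeneousNetwork, degree_map

__all__ = [
    "ImportanceScores",
    "WalkCorpus",
    "node_importance",
    "allocate_walks",
    "generate_walks",
]


@dataclass
class ImportanceScores:
    scores: dict[str, float]
    method: str

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.scores.values()):
            raise ValueError("importance scores must be nonnegative")


@dataclass
class WalkCorpus:
    """Sequences of same-partition node ids plus the stopping parameters
    (max_t, min_t, stop_prob) that produced them."""

    walks: list[list[str]]
    params: tuple[int, int, float]

    def __len__(self) -> int:
        return len(self.walks)

    @property
    def n_tokens(self) -> int:
        return sum(len(w) for w in self.walks)

    def to_text(self, path: str) -> None:
        with open(path, "w") as fh:
            for walk in self.walks:
                fh.write(" ".join(walk) + "\n")


def node_importance(hn: HomogeneousNetwork, method: str = "degree") -> ImportanceScores:
    """Score nodes by weighted degree or by HITS authority.

    On an undirected network hub and authority scores coincide, so the HITS
    fixed point is the dominant eigenvector of the (nonnegative symmetric)
    adjacency matrix, found here by L1-normalized power iteration to
    relative tolerance 1e-8.
    """
    if hn.n_nodes == 0:
        raise ValueError("cannot score an empty network")
    if method == "degree":
        return ImportanceScores(scores=degree_map(hn), method="degree")
    if method == "hits":
        a = hn.dense_matrix()
        x = np.full(hn.n_nodes, 1.0 / hn.n_nodes)
        for _ in range(10000):
            y = a @ x
            total = y.sum()
            if total == 0:  # no edges: fall back to the uniform vector
                x = np.full(hn.n_nodes, 1.0 / hn.n_nodes)
                break
            y /= total
            if np.abs(y - x).sum() <= 1e-8 * np.abs(y).sum():
                x = y
                break
            x = y
        return ImportanceScores(
            scores={n: float(s) for n, s in zip(hn.nodes, x)}, method="hits"
        )
    raise ValueError(f"unknown importance method {method!r}")


def allocate_walks(imp: ImportanceScores, total_walks: int) -> dict[str, int]:
    """Allocate a walk budget proportionally to importance.

    Every node with positive importance receives at least one walk
    (ceiling rule), so the realized total lies in
    [total_walks, total_walks + n_nodes].
    """
    total_imp = sum(imp.scores.values())
    if total_imp <= 0:
        raise ValueError("all importance scores are zero")
    n_positive = sum(1 for s in imp.scores.values() if s > 0)
    if total_walks < n_positive:
        raise ValueError(
            f"total_walks={total_walks} below the {n_positive} nodes needing >=1 walk"
        )
    return {
        n: (math.ceil(total_walks * s / total_imp) if s > 0 else 0)
        for n, s in imp.scores.items()
    }


def generate_walks(
    hn: HomogeneousNetwork,
    counts: dict[str, int],
    max_t: int = 32,
    min_t: int = 1,
    stop_prob: float = 0.15,
    rng_seed=0,
    weighted: bool = True,
) -> WalkCorpus:
    """Generate the allotted walks from each start node.

    Each step: stop if the walk holds ``max_t`` nodes; otherwise, once at
    least ``min_t`` nodes long, stop with probability ``stop_prob``;
    otherwise move to a neighbor sampled proportionally to edge weight.
    With ``min_t = 1`` the stop rule already applies before the first step,
    so one-node walks occur with probability ``stop_prob``.  A node without
    neighbors yields a one-node walk.  Fully reproducible from ``rng_seed``
    (anything ``numpy.random.default_rng`` accepts).  With
    ``weighted=False`` transitions are uniform over neighbors instead of
    proportional to edge weight.
    """
    if not 0.0 <= stop_prob <= 1.0:
        raise ValueError(f"stop_prob must be in [0, 1], got {stop_prob}")
    if min_t < 1:
        raise ValueError(f"min_t must be >= 1, got {min_t}")
    if max_t < min_t:
        raise ValueError(f"max_t ({max_t}) must be >= min_t ({min_t})")

    adj = hn.adjacency()
    nbrs: dict[str, tuple[list[str], np.ndarray]] = {}
    for node, pairs in adj.items():
        if pairs:
            names = [p[0] for p in pairs]
            cum = np.cumsum([p[1] if weighted else 1.0 for p in pairs])
            nbrs[node] = (names, cum)

    rng = np.random.default_rng(rng_seed)
    walks: list[list[str]] = []
    for start in hn.nodes:
        for _ in range(counts.get(start, 0)):
            walk = [start]
            while True:
                if len(walk) >= max_t:
                    break
                if len(walk) >= min_t and rng.random() < stop_prob:
                    break
                step = nbrs.get(walk[-1])
                if step is None:
                    break
                names, cum = step
                idx = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
                walk.append(names[min(idx, len(names) - 1)])
            walks.append(walk)
    return WalkCorpus(walks=walks, params=(max_t, min_t, stop_prob))
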