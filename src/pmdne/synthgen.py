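"""Synthetic bipartite association networks with planted structure.

The generator emulates the shape of real miRNA-disease data: a bipartite
association graph with binary weights, plus two intra-partition similarity
matrices that carry correlated signal.  Nodes of each partition are
assigned round-robin to blocks; a same-block (u, v) pair is an edge with
probability ``p_in``, a cross-block pair with ``p_out``.  Same-block
same-partition pairs get similarity ``sim_signal`` plus Gaussian noise,
cross-block pairs pure noise, all clipped to [0, 1].  ``partial_coverage``
restricts a similarity network to a random node subset, mimicking
real similarity data that covers only part of the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .net_io import BipartiteNetwork, SimilarityNetwork

__all__ = ["SyntheticDataset", "make_synthetic", "partial_coverage"]


@dataclass
class SyntheticDataset:
    network: BipartiteNetwork
    sim_u: SimilarityNetwork
    sim_v: SimilarityNetwork
    heldout_positives: list[tuple[str, str]]
    block_of: dict[str, int]
    params: dict


def _block_similarity(
    nodes: list[str],
    blocks: np.ndarray,
    sim_signal: float,
    sim_noise_sd: float,
    rng: np.random.Generator,
) -> SimilarityNetwork:
    n = len(nodes)
    base = np.where(blocks[:, None] == blocks[None, :], sim_signal, 0.0)
    values = np.clip(base + rng.normal(0.0, sim_noise_sd, (n, n)), 0.0, 1.0)
    sim = SimilarityNetwork(nodes=list(nodes), sim={})
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        v = float(values[i, j])
        if v > 0:
            sim.set(nodes[i], nodes[j], v)
    return sim


def make_synthetic(
    n_u: int = 100,
    n_v: int = 100,
    n_blocks: int = 2,
    p_in: float = 0.3,
    p_out: float = 0.02,
    sim_signal: float = 0.6,
    sim_noise_sd: float = 0.1,
    heldout_frac: float = 0.0,
    seed: int = 0,
    weighted: bool = False,
) -> SyntheticDataset:
    """Generate a block-structured bipartite dataset, fully seeded.

    With ``weighted=True`` edge weights are drawn uniformly from (0.5, 1.5]
    instead of the default binary weight 1 (for exercising weighted code
    paths).  ``heldout_frac`` of the positive edges is removed from the
    network and returned separately as held-out positives.
    """
    if not (0.0 <= p_out < p_in <= 1.0):
        raise ValueError(f"require 0 <= p_out < p_in <= 1, got p_in={p_in}, p_out={p_out}")
    if not 0.0 <= heldout_frac <= 1.0:
        raise ValueError(f"heldout_frac must be in [0, 1], got {heldout_frac}")
    if n_blocks > min(n_u, n_v) or n_blocks < 1:
        raise ValueError("n_blocks must be in [1, min(n_u, n_v)]")

    rng = np.random.default_rng(seed)
    u_nodes = [f"m{i:04d}" for i in range(n_u)]
    v_nodes = [f"d{j:04d}" for j in range(n_v)]
    u_blocks = np.arange(n_u) % n_blocks
    v_blocks = np.arange(n_v) % n_blocks

    prob = np.where(u_blocks[:, None] == v_blocks[None, :], p_in, p_out)
    adj = rng.random((n_u, n_v)) < prob
    edges: dict[tuple[str, str], float] = {}
    for i, j in zip(*np.nonzero(adj)):
        w = 1.0 if not weighted else float(0.5 + rng.random())
        edges[(u_nodes[i], v_nodes[j])] = w

    sim_u = _block_similarity(u_nodes, u_blocks, sim_signal, sim_noise_sd, rng)
    sim_v = _block_similarity(v_nodes, v_blocks, sim_signal, sim_noise_sd, rng)

    heldout: list[tuple[str, str]] = []
    if heldout_frac > 0 and edges:
        keys = sorted(edges)
        n_hold = int(round(heldout_frac * len(keys)))
        for idx in rng.choice(len(keys), size=n_hold, replace=False):
            heldout.append(keys[idx])
            del edges[keys[idx]]

    network = BipartiteNetwork(u_nodes=u_nodes, v_nodes=v_nodes, edges=edges)
    block_of = {n: int(b) for n, b in zip(u_nodes, u_blocks)}
    block_of.update({n: int(b) for n, b in zip(v_nodes, v_blocks)})
    return SyntheticDataset(
        network=network,
        sim_u=sim_u,
        sim_v=sim_v,
        heldout_positives=heldout,
        block_of=block_of,
        params={
            "n_u": n_u,
            "n_v": n_v,
            "n_blocks": n_blocks,
            "p_in": p_in,
            "p_out": p_out,
            "sim_signal": sim_signal,
            "sim_noise_sd": sim_noise_sd,
            "heldout_frac": heldout_frac,
            "seed": seed,
        },
    )


def partial_coverage(
    sim: SimilarityNetwork, keep_frac: float, seed: int = 0
) -> SimilarityNetwork:
    """Restrict a similarity network to a seeded random subset of its nodes.

    Keeps ``round(keep_frac * n)`` nodes; entries between kept nodes are
    retained exactly, all others dropped.
    """
    if not 0.0 < keep_frac <= 1.0:
        raise ValueError(f"keep_frac must be in (0, 1], got {keep_frac}")
    if keep_frac == 1.0:
        return SimilarityNetwork(nodes=list(sim.nodes), sim=dict(sim.sim))
    rng = np.random.default_rng(seed)
    n_keep = int(round(keep_frac * len(sim.nodes)))
    kept_idx = rng.choice(len(sim.nodes), size=n_keep, replace=False)
    kept = {sim.nodes[i] for i in kept_idx}
    return SimilarityNetwork(
        nodes=[n for n in sim.nodes if n in kept],
        sim={(i, j): s for (i, j), s in sim.sim.items() if i in kept and j in kept},
    )
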