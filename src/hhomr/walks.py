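"""Second-order biased random walks over the heterogeneous graph.

The walk policy is the node2vec one: standing at ``curr`` having arrived from
``prev``, each neighbor ``x`` of ``curr`` gets an unnormalised weight

* ``1/p``  if ``x == prev``            (return),
* ``1``    if ``x`` is adjacent to ``prev``  (stay close),
* ``1/q``  otherwise                   (move outward),

which is normalised into a proper transition distribution.  Low ``p`` keeps
walks local (structural roles), low ``q`` pushes them outward (community
structure).  The first step of a walk has no predecessor and is uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import HeteroGraph


@dataclass
class WalkConfig:
    """Hyperparameters for biased walks and the skip-gram embedding."""

    p: float = 1.0
    q: float = 1.0
    walks_per_node: int = 10
    walk_length: int = 80
    window: int = 5
    dim: int = 64
    epochs: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.walk_length < 2:
            raise ValueError("walk_length must be at least 2")
        if self.dim < 1:
            raise ValueError("dim must be at least 1")


def step_distribution(
    graph: HeteroGraph, prev: int, curr: int, p: float, q: float
) -> tuple[np.ndarray, np.ndarray]:
    """Transition distribution over ``neighbors(curr)`` given predecessor ``prev``.

    Returns ``(candidates, probabilities)``; probabilities sum to 1 and are
    supported exactly on the neighbors of ``curr``.
    """
    if prev not in graph.neighbor_set(curr):
        raise ValueError(f"({prev}, {curr}) is not an edge")
    candidates = graph.neighbors(curr)
    if candidates.size == 0:
        raise ValueError(f"node {curr} is isolated; no step possible")
    prev_nbrs = graph.neighbor_set(prev)
    weights = np.empty(candidates.size)
    for i, x in enumerate(candidates):
        if x == prev:
            weights[i] = 1.0 / p
        elif x in prev_nbrs:
            weights[i] = 1.0
        else:
            weights[i] = 1.0 / q
    return candidates, weights / weights.sum()


def generate_walks(graph: HeteroGraph, cfg: WalkConfig) -> list[list[int]]:
    """Sample ``walks_per_node`` biased walks from every node.

    Walks have at most ``walk_length`` nodes; isolated nodes yield length-1
    walks.  Deterministic for a fixed ``cfg.seed``.
    """
    if graph.n_nodes == 0:
        raise ValueError("graph has no nodes")
    rng = np.random.default_rng(cfg.seed)
    inv_p, inv_q = 1.0 / cfg.p, 1.0 / cfg.q
    adjacency = [graph.neighbors(v) for v in range(graph.n_nodes)]
    neighbor_sets = [graph.neighbor_set(v) for v in range(graph.n_nodes)]
    walks: list[list[int]] = []
    for _ in range(cfg.walks_per_node):
        for start in range(graph.n_nodes):
            walk = [start]
            if adjacency[start].size == 0:
                walks.append(walk)
                continue
            # first step: uniform (no predecessor, so the bias is undefined)
            curr = int(rng.choice(adjacency[start]))
            walk.append(curr)
            while len(walk) < cfg.walk_length:
                candidates = adjacency[curr]
                if candidates.size == 0:
                    break
                prev = walk[-2]
                prev_nbrs = neighbor_sets[prev]
                weights = np.empty(candidates.size)
                for i, x in enumerate(candidates):
                    if x == prev:
                        weights[i] = inv_p
                    elif x in prev_nbrs:
                        weights[i] = 1.0
                    else:
                        weights[i] = inv_q
                curr = int(rng.choice(candidates, p=weights / weights.sum()))
                walk.append(curr)
            walks.append(walk)
    return walks
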