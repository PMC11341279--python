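"""Skip-gram embeddings of walk corpora, trained with negative sampling.

The trainer optimises the expected skip-gram-with-negative-sampling (SGNS)
objective in full batch: (center, context) pairs within the window are
aggregated into a co-occurrence count matrix, and the noise term uses the
smoothed unigram distribution (``counts^0.75``) in closed form instead of
sampled draws.  On the small vocabularies produced by these graphs this is
deterministic under the seed and orders of magnitude faster than
pair-by-pair stochastic updates, while optimising the same objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .walks import WalkConfig

logger = logging.getLogger(__name__)

NEGATIVE_RATE = 5  # noise-to-data ratio k of SGNS
_ITERS_PER_EPOCH = 30


@dataclass
class TopoEmbedding:
    """Per-node topological embedding vectors, aligned with node indices."""

    ids: list[int]
    vectors: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[0] != len(self.ids):
            raise ValueError("one embedding row per node id required")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding contains non-finite entries")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


def cooccurrence_counts(walks: list[list[int]], window: int, n_nodes: int) -> np.ndarray:
    """Aggregate (center, context) pair counts within ``window`` over the corpus."""
    counts = np.zeros((n_nodes, n_nodes))
    for walk in walks:
        L = len(walk)
        for i, w in enumerate(walk):
            for j in range(max(0, i - window), min(L, i + window + 1)):
                if j != i:
                    counts[w, walk[j]] += 1.0
    return counts


def skipgram_embed(
    walks: list[list[int]], cfg: WalkConfig, n_nodes: int | None = None
) -> TopoEmbedding:
    """Train SGNS embeddings on a walk corpus.

    Nodes that never appear in the corpus are embedded as zero vectors (with
    a warning).  Deterministic under ``cfg.seed``.
    """
    if not walks:
        raise ValueError("walk corpus is empty")
    if n_nodes is None:
        n_nodes = max(max(w) for w in walks if w) + 1
    counts = cooccurrence_counts(walks, cfg.window, n_nodes)
    center_totals = counts.sum(axis=1)
    context_totals = counts.sum(axis=0)
    present = (center_totals > 0) | (context_totals > 0)
    if not present.all():
        logger.warning(
            "%d node(s) absent from the walk corpus; embedded as zero vectors",
            int((~present).sum()),
        )

    # smoothed unigram noise distribution over contexts
    noise = np.where(present, np.maximum(context_totals, 1.0) ** 0.75, 0.0)
    noise_total = noise.sum()
    if noise_total == 0:
        raise ValueError("corpus covers no nodes")
    noise /= noise_total
    negatives = NEGATIVE_RATE * np.outer(center_totals, noise)

    rng = np.random.default_rng(cfg.seed)
    scale = 0.5 / cfg.dim
    U = rng.uniform(-scale, scale, size=(n_nodes, cfg.dim))
    V = rng.uniform(-scale, scale, size=(n_nodes, cfg.dim))
    total = counts.sum() + negatives.sum()

    # full-batch Adam on the expected SGNS loss
    lr, b1, b2, eps = 0.05, 0.9, 0.999, 1e-8
    mU = np.zeros_like(U); vU = np.zeros_like(U)
    mV = np.zeros_like(V); vV = np.zeros_like(V)
    n_iter = _ITERS_PER_EPOCH * max(1, cfg.epochs)
    for t in range(1, n_iter + 1):
        sig = 1.0 / (1.0 + np.exp(-(U @ V.T)))
        G = (sig * (counts + negatives) - counts) / total
        gU = G @ V
        gV = G.T @ U
        for P, g, m, v in ((U, gU, mU, vU), (V, gV, mV, vV)):
            m *= b1; m += (1 - b1) * g
            v *= b2; v += (1 - b2) * g * g
            P -= lr * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + eps)
    U[~present] = 0.0
    return TopoEmbedding(ids=list(range(n_nodes)), vectors=U)


def embed_graph(graph, cfg: WalkConfig) -> TopoEmbedding:
    """Walk + embed convenience wrapper for a :class:`~hhomr.graph.HeteroGraph`."""
    from .walks import generate_walks

    walks = generate_walks(graph, cfg)
    return skipgram_embed(walks, cfg, n_nodes=graph.n_nodes)
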