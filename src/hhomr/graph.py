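"""Heterogeneous miRNA-disease graph construction and negative sampling.

The message-passing graph is bipartite: miRNA nodes on one side, disease
nodes on the other, with one undirected edge per validated association.
Nodes carry their fused-similarity row as raw attribute features.  Unobserved
pairs are sampled uniformly (without replacement) as negatives; negatives are
scored by the model but never become message-passing edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import AssociationMatrix, SimilarityMatrix
from .exceptions import AlignmentError, CapacityError, ConsistencyError

DEFAULT_SEED = 0


@dataclass
class HeteroGraph:
    """Bipartite miRNA-disease graph with per-node feature rows.

    Node indexing is canonical: miRNAs first (``0 .. n_mirnas-1``), then
    diseases (``n_mirnas .. n_mirnas+n_diseases-1``).
    """

    mirna_ids: list[str]
    disease_ids: list[str]
    #: (n_edges, 2) int array of (mirna_index, global disease index) pairs
    edge_index: np.ndarray = field(repr=False)
    mirna_features: np.ndarray = field(repr=False)
    disease_features: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.edge_index = np.asarray(self.edge_index, dtype=np.int64).reshape(-1, 2)
        self._adjacency = [[] for _ in range(self.n_nodes)]
        for m, d in self.edge_index:
            self._adjacency[m].append(int(d))
            self._adjacency[d].append(int(m))
        self._adjacency = [np.array(sorted(set(a)), dtype=np.int64) for a in self._adjacency]
        self._neighbor_sets = [frozenset(a.tolist()) for a in self._adjacency]

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_mirnas + self.n_diseases

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[0]

    def node_id(self, index: int) -> str:
        if index < self.n_mirnas:
            return self.mirna_ids[index]
        return self.disease_ids[index - self.n_mirnas]

    def mirna_node(self, mirna_id: str) -> int:
        return self.mirna_ids.index(mirna_id)

    def disease_node(self, disease_id: str) -> int:
        return self.n_mirnas + self.disease_ids.index(disease_id)

    def neighbors(self, node: int) -> np.ndarray:
        return self._adjacency[node]

    def neighbor_set(self, node: int) -> frozenset[int]:
        return self._neighbor_sets[node]

    def degree(self, node: int) -> int:
        return len(self._adjacency[node])

    def undirected_edge_set(self) -> frozenset[tuple[int, int]]:
        return frozenset((int(m), int(d)) for m, d in self.edge_index)

    def flat_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Directed (center, neighbor) index arrays covering both directions."""
        src = np.concatenate([self.edge_index[:, 0], self.edge_index[:, 1]])
        dst = np.concatenate([self.edge_index[:, 1], self.edge_index[:, 0]])
        return src, dst


@dataclass
class LabeledPairSet:
    """Scored (mirna_id, disease_id, label) pairs with sampling provenance."""

    pairs: list[tuple[str, str, int]]
    provenance: str = "positive"
    seed: int | None = None

    def __post_init__(self):
        keyed = [(m, d) for m, d, _ in self.pairs]
        if len(set(keyed)) != len(keyed):
            raise ConsistencyError("duplicate (mirna, disease) pair in labeled set")
        labels = {lab for _, _, lab in self.pairs}
        if not labels <= {0, 1}:
            raise ValueError(f"labels must be 0/1, got {labels}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, _, lab in self.pairs], dtype=np.int64)

    def index_pairs(self, graph: HeteroGraph) -> np.ndarray:
        """(n, 2) array of (mirna node index, disease node index)."""
        m_of = {mid: i for i, mid in enumerate(graph.mirna_ids)}
        d_of = {did: graph.n_mirnas + i for i, did in enumerate(graph.disease_ids)}
        return np.array([[m_of[m], d_of[d]] for m, d, _ in self.pairs], dtype=np.int64)


def build_graph(
    assoc: AssociationMatrix, fm: SimilarityMatrix, fd: SimilarityMatrix
) -> HeteroGraph:
    """Build the bipartite graph: one undirected edge per positive association.

    Each miRNA node carries its row of the fused miRNA similarity matrix as
    features, each disease node its row of the fused disease matrix.
    """
    if fm.ids != list(assoc.mirna_ids):
        raise AlignmentError("fused miRNA matrix ids do not match association rows")
    if fd.ids != list(assoc.disease_ids):
        raise AlignmentError("fused disease matrix ids do not match association columns")
    rows, cols = np.nonzero(assoc.values)
    if rows.size == 0:
        raise ValueError("association matrix has no positive entries; graph would be empty")
    edge_index = np.stack([rows, cols + assoc.n_mirnas], axis=1)
    return HeteroGraph(
        mirna_ids=list(assoc.mirna_ids),
        disease_ids=list(assoc.disease_ids),
        edge_index=edge_index,
        mirna_features=fm.values.copy(),
        disease_features=fd.values.copy(),
    )


def sample_negatives(
    assoc: AssociationMatrix, n_neg: int, seed: int = DEFAULT_SEED
) -> LabeledPairSet:
    """Uniform sample without replacement from the unobserved (zero) entries."""
    zeros_flat = np.flatnonzero(assoc.values == 0)
    if n_neg > zeros_flat.size:
        raise CapacityError(
            f"requested {n_neg} negatives but only {zeros_flat.size} zero entries exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(zeros_flat, size=n_neg, replace=False)
    chosen.sort()
    n_d = assoc.n_diseases
    pairs = [
        (assoc.mirna_ids[idx // n_d], assoc.disease_ids[idx % n_d], 0) for idx in chosen
    ]
    return LabeledPairSet(pairs=pairs, provenance="sampled_negative", seed=seed)


def assemble_pairs(assoc: AssociationMatrix, negatives: LabeledPairSet) -> LabeledPairSet:
    """Union of all positive pairs (label 1) and sampled negatives (label 0).

    Ordering is stable (positives in row-major matrix order, then negatives
    in their sampled order) so downstream fold assignment is reproducible.
    """
    positives = [(m, d, 1) for m, d in assoc.positives()]
    pos_keys = {(m, d) for m, d, _ in positives}
    overlap = [(m, d) for m, d, _ in negatives if (m, d) in pos_keys]
    if overlap:
        raise ConsistencyError(f"negative pairs overlap positives: {overlap[:5]}")
    return LabeledPairSet(
        pairs=positives + list(negatives.pairs),
        provenance="positive+sampled_negative",
        seed=negatives.seed,
    )
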