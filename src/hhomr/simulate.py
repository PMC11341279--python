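"""Synthetic association data with planted block structure.

The generator emulates the shape of curated miRNA-disease catalogues: a
binary incidence matrix, a rooted disease hierarchy, and the similarity
inputs derived from them.  Associations follow a planted stochastic block
model — miRNAs and diseases are partitioned into matching blocks and a pair
is associated with probability ``p_in`` inside a block and ``p_out`` across
blocks — so recovering the blocks is a controllable signal for the whole
pipeline.  Setting ``p_in == p_out`` yields the signal-free null.  Disease
blocks are aligned with subtrees of the simulated hierarchy so the semantic
similarity also carries block signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as hio
from .containers import AssociationMatrix, SimilarityMatrix
from .dag import DiseaseDAG, build_dag, disease_semantic_similarity
from .evaluate import FoldPlan, make_folds
from .graph import HeteroGraph, LabeledPairSet, assemble_pairs, build_graph, sample_negatives
from .similarity import feature_matrices

ROOT_ID = "root"


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset."""

    n_mirnas: int = 40
    n_diseases: int = 30
    n_blocks: int = 3
    p_in: float = 0.6
    p_out: float = 0.02
    dag_branching: int = 3
    seed: int = 0

    def __post_init__(self):
        if min(self.n_mirnas, self.n_diseases) < self.n_blocks:
            raise ValueError("need at least one miRNA and one disease per block")
        for p in (self.p_in, self.p_out):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.dag_branching < 1:
            raise ValueError("dag_branching must be >= 1")

    @property
    def is_null(self) -> bool:
        return self.p_in == self.p_out


def _block_labels(n: int, n_blocks: int) -> np.ndarray:
    """Contiguous block assignment: block b owns indices chunk b."""
    return np.concatenate([np.full(len(c), b) for b, c in enumerate(np.array_split(np.arange(n), n_blocks))])


def simulate_associations(spec: FixtureSpec) -> tuple[AssociationMatrix, np.ndarray, np.ndarray]:
    """Draw a planted-block binary association matrix.

    Returns the matrix plus the miRNA and disease block labels.
    """
    rng = np.random.default_rng(spec.seed)
    m_blocks = _block_labels(spec.n_mirnas, spec.n_blocks)
    d_blocks = _block_labels(spec.n_diseases, spec.n_blocks)
    probs = np.where(m_blocks[:, None] == d_blocks[None, :], spec.p_in, spec.p_out)
    values = (rng.random((spec.n_mirnas, spec.n_diseases)) < probs).astype(np.int8)
    assoc = AssociationMatrix(
        mirna_ids=[f"mir{i:03d}" for i in range(spec.n_mirnas)],
        disease_ids=[f"d{j:03d}" for j in range(spec.n_diseases)],
        values=values,
    )
    return assoc, m_blocks, d_blocks


def simulate_dag(
    n_diseases: int, dag_branching: int = 3, seed: int = 0, block_labels=None
) -> DiseaseDAG:
    """Random rooted disease hierarchy covering every disease.

    With ``block_labels`` given, each block becomes its own subtree under the
    root, so hierarchy-derived similarity is higher within blocks.  With
    ``dag_branching=1`` every subtree is a chain.
    """
    if n_diseases < 1:
        raise ValueError("need at least one disease")
    rng = np.random.default_rng(seed)
    ids = [f"d{j:03d}" for j in range(n_diseases)]
    if block_labels is None:
        block_labels = np.zeros(n_diseases, dtype=int)
    block_labels = np.asarray(block_labels)
    edges: list[tuple[str, str]] = []
    for block in np.unique(block_labels):
        members = [ids[i] for i in np.flatnonzero(block_labels == block)]
        attachable = []  # nodes with spare child slots, repeated per slot
        head = members[0]
        edges.append((ROOT_ID, head))
        attachable.extend([head] * dag_branching)
        for node in members[1:]:
            pick = int(rng.integers(len(attachable)))
            parent = attachable.pop(pick)
            edges.append((parent, node))
            attachable.extend([node] * dag_branching)
    return build_dag(edges)


@dataclass
class FixtureBundle:
    """Everything one synthetic study needs, derived end-to-end from a spec."""

    spec: FixtureSpec
    assoc: AssociationMatrix
    dag: DiseaseDAG
    dsim: SimilarityMatrix
    fm: SimilarityMatrix
    fd: SimilarityMatrix
    graph: HeteroGraph
    pairs: LabeledPairSet
    mirna_blocks: np.ndarray = field(repr=False)
    disease_blocks: np.ndarray = field(repr=False)

    def fold_plan(self, n_folds: int = 5, seed: int | None = None) -> FoldPlan:
        return make_folds(self.pairs, n_folds=n_folds, seed=self.spec.seed if seed is None else seed)


def make_fixture(spec: FixtureSpec | None = None) -> FixtureBundle:
    """Run the similarity and graph pipeline end-to-end on synthetic inputs."""
    spec = spec or FixtureSpec()
    assoc, m_blocks, d_blocks = simulate_associations(spec)
    if assoc.positive_pairs == 0:
        raise ValueError("simulated matrix has no positives; raise p_in/p_out")
    dag = simulate_dag(spec.n_diseases, spec.dag_branching, seed=spec.seed, block_labels=d_blocks)
    dsim = disease_semantic_similarity(dag, assoc.disease_ids)
    fm, fd = feature_matrices(assoc, dsim)
    graph = build_graph(assoc, fm, fd)
    negatives = sample_negatives(assoc, n_neg=assoc.positive_pairs, seed=spec.seed)
    pairs = assemble_pairs(assoc, negatives)
    return FixtureBundle(
        spec=spec,
        assoc=assoc,
        dag=dag,
        dsim=dsim,
        fm=fm,
        fd=fd,
        graph=graph,
        pairs=pairs,
        mirna_blocks=m_blocks,
        disease_blocks=d_blocks,
    )


def write_bundle(bundle: FixtureBundle, out_dir) -> None:
    """Serialise a bundle to a directory of TSVs in the package dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hio.write_association_tsv(bundle.assoc, out / "associations.tsv")
    hio.write_dag_tsv(sorted(bundle.dag.graph.edges), out / "dag.tsv")
    hio.write_similarity_tsv(bundle.dsim, out / "semantic_similarity.tsv")
    hio.write_similarity_tsv(bundle.fm, out / "fused_mirna.tsv")
    hio.write_similarity_tsv(bundle.fd, out / "fused_disease.tsv")
    hio.write_pairs_tsv(bundle.pairs, out / "pairs.tsv")


def load_bundle(in_dir) -> dict:
    """Read a serialised bundle back into package objects."""
    src = Path(in_dir)
    return {
        "assoc": hio.read_association_tsv(src / "associations.tsv"),
        "dag": build_dag(hio.read_dag_tsv(src / "dag.tsv")),
        "dsim": hio.read_similarity_tsv(src / "semantic_similarity.tsv", kind="semantic"),
        "fm": hio.read_similarity_tsv(src / "fused_mirna.tsv", kind="fused_mirna"),
        "fd": hio.read_similarity_tsv(src / "fused_disease.tsv", kind="fused_disease"),
        "pairs": hio.read_pairs_tsv(src / "pairs.tsv"),
    }
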