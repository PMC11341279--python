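"""Disease-hierarchy handling and DAG-based semantic similarity.

Diseases live in a MeSH-style directed acyclic graph whose edges point from a
broader term (parent) to a narrower one (child).  Each disease ``d`` induces a
sub-DAG consisting of ``d`` and all of its ancestors; every ancestor
contributes semantic information to ``d``, attenuated by a decay factor
``delta`` per generation.  Two diseases are semantically similar to the extent
that their ancestor sets overlap, weighted by those contributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .containers import SimilarityMatrix
from .exceptions import CycleError, UnknownIdError

logger = logging.getLogger(__name__)

DEFAULT_DECAY = 0.5


@dataclass
class ContributionTable:
    """Semantic contribution of each ancestor to an anchor disease.

    ``values[n]`` is the contribution of ancestor ``n`` (the anchor itself
    contributes exactly 1); contributions decay by ``decay`` per generation
    along the steepest descending path back to the anchor.
    """

    anchor: str
    values: dict[str, float]
    decay: float = DEFAULT_DECAY

    @property
    def semantic_value(self) -> float:
        """Total semantic value of the anchor's sub-DAG (denominator terms)."""
        return float(sum(self.values.values()))


@dataclass
class DiseaseDAG:
    """A validated disease hierarchy with per-node ancestor closures."""

    graph: nx.DiGraph
    ancestors: dict[str, frozenset[str]] = field(repr=False)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def closure(self, disease: str) -> frozenset[str]:
        """Return ``T(d)``: the disease itself plus all its ancestors."""
        try:
            return self.ancestors[disease]
        except KeyError:
            raise UnknownIdError([disease]) from None

    def children_of(self, disease: str):
        return set(self.graph.successors(disease))


def build_dag(parent_edges) -> DiseaseDAG:
    """Build a :class:`DiseaseDAG` from ``(parent, child)`` edge pairs.

    Duplicate edges are ignored with a warning; a directed cycle raises
    :class:`~hhomr.exceptions.CycleError` naming one offending edge.
    """
    edges = list(parent_edges)
    if not edges:
        raise ValueError("edge list must be non-empty")
    g = nx.DiGraph()
    seen = set()
    for parent, child in edges:
        if not str(parent).strip() or not str(child).strip():
            raise ValueError(f"blank identifier in edge ({parent!r}, {child!r})")
        if (parent, child) in seen:
            logger.warning("duplicate hierarchy edge ignored: %r -> %r", parent, child)
            continue
        seen.add((parent, child))
        g.add_edge(parent, child)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise CycleError((cycle[0][0], cycle[0][1]))
    closures = {n: frozenset(nx.ancestors(g, n)) | {n} for n in g.nodes}
    return DiseaseDAG(graph=g, ancestors=closures)


def semantic_contribution(dag: DiseaseDAG, anchor: str, delta: float = DEFAULT_DECAY) -> ContributionTable:
    """Compute the decayed contribution of every ancestor of ``anchor``.

    The anchor contributes 1.  Every other node ``n`` in the anchor's closure
    contributes ``delta * max(contribution of c)`` over its children ``c``
    that also lie inside the closure, so contributions flow only along paths
    within the anchor's own sub-DAG.
    """
    if anchor not in dag.nodes:
        raise UnknownIdError([anchor])
    if not (0.0 < delta < 1.0):
        raise ValueError(f"decay must lie in (0, 1), got {delta}")
    closure = dag.closure(anchor)
    sub = dag.graph.subgraph(closure)
    values: dict[str, float] = {anchor: 1.0}
    # children must be resolved before parents: reversed topological order
    for node in reversed(list(nx.topological_sort(sub))):
        if node == anchor:
            continue
        child_vals = [values[c] for c in sub.successors(node) if c in values]
        values[node] = delta * max(child_vals)
    return ContributionTable(anchor=anchor, values=values, decay=delta)


def disease_semantic_similarity(
    dag: DiseaseDAG, diseases, delta: float = DEFAULT_DECAY
) -> SimilarityMatrix:
    """Semantic similarity between all pairs of ``diseases``.

    The similarity of ``d_i`` and ``d_j`` is the sum, over diseases shared by
    both closures, of each one's contribution to either anchor, divided by the
    two total semantic values.  The diagonal is exactly 1.
    """
    diseases = list(diseases)
    missing = [d for d in diseases if d not in dag.nodes]
    if missing:
        raise UnknownIdError(missing)
    tables = {d: semantic_contribution(dag, d, delta) for d in diseases}
    totals = {d: tables[d].semantic_value for d in diseases}
    n = len(diseases)
    out = np.eye(n)
    for i in range(n):
        ti = tables[diseases[i]]
        for j in range(i + 1, n):
            tj = tables[diseases[j]]
            shared = ti.values.keys() & tj.values.keys()
            num = sum(ti.values[k] + tj.values[k] for k in shared)
            out[i, j] = out[j, i] = num / (totals[diseases[i]] + totals[diseases[j]])
    return SimilarityMatrix(ids=diseases, values=out, kind="semantic")
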