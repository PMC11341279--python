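"""End-to-end training, cross-validation, sweeps and case-study ranking.

Every fold rebuilds the whole pipeline from its own training positives: the
GIP/functional similarities, the message-passing graph, and the topological
embedding are all recomputed on the fold's training associations so no
held-out edge can leak into the representation (``global_features=True`` instead
computes similarities once from the full association matrix, mimicking a
single global preprocessing pass; message-passing edges still come from
training positives only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .containers import AssociationMatrix, SimilarityMatrix
from .embedding import embed_graph
from .evaluate import FoldPlan, MetricReport, evaluate
from .exceptions import ConsistencyError, UnknownIdError
from .graph import LabeledPairSet, build_graph, sample_negatives
from .model import MomentGNN
from .similarity import feature_matrices
from .walks import WalkConfig


@dataclass
class TrainConfig:
    """Optimisation settings; the loss is always binary cross-entropy."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 500
    patience: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")


@dataclass
class FoldDiagnostics:
    """Structural record of one fold, for leakage auditing."""

    fold: int
    message_passing_edges: frozenset
    test_positive_edges: frozenset
    n_train: int
    n_test: int


@dataclass
class CVResult:
    """Mean metrics, per-fold reports and structural diagnostics."""

    mean: MetricReport
    diagnostics: list[FoldDiagnostics] = field(default_factory=list)

    @property
    def fold_reports(self) -> list[MetricReport]:
        return self.mean.fold_metrics


def train(graph, topo, pairs_train: np.ndarray, labels_train: np.ndarray,
          model: MomentGNN | None = None, train_cfg: TrainConfig | None = None) -> MomentGNN:
    """Fit a (possibly template) estimator on training pairs; returns it fitted."""
    train_cfg = train_cfg or TrainConfig()
    est = clone(model) if model is not None else MomentGNN()
    est.set_params(
        learning_rate=train_cfg.learning_rate,
        max_epochs=train_cfg.epochs,
        patience=train_cfg.patience,
    )
    return est.fit(pairs_train, labels_train, graph=graph, topo=topo)


def _masked_association(assoc: AssociationMatrix, keep_pairs) -> AssociationMatrix:
    """Association matrix whose positives are exactly ``keep_pairs``."""
    values = np.zeros_like(assoc.values)
    m_of = {m: i for i, m in enumerate(assoc.mirna_ids)}
    d_of = {d: j for j, d in enumerate(assoc.disease_ids)}
    for m, d in keep_pairs:
        values[m_of[m], d_of[d]] = 1
    return AssociationMatrix(
        mirna_ids=list(assoc.mirna_ids), disease_ids=list(assoc.disease_ids), values=values
    )


def cross_validate(
    assoc: AssociationMatrix,
    dsim: SimilarityMatrix,
    pairs: LabeledPairSet,
    plan: FoldPlan,
    model: MomentGNN | None = None,
    walk_cfg: WalkConfig | None = None,
    fsim: SimilarityMatrix | None = None,
    global_features: bool = False,
    threshold: float = 0.5,
) -> CVResult:
    """Leakage-guarded k-fold cross-validation of the full pipeline."""
    model = model if model is not None else MomentGNN()
    walk_cfg = walk_cfg or WalkConfig()
    pair_list = list(pairs.pairs)
    labels = pairs.labels
    reports: list[MetricReport] = []
    diagnostics: list[FoldDiagnostics] = []
    for fold in range(plan.n_folds):
        train_idx, test_idx = plan.fold_indices(fold)
        train_positives = [
            (pair_list[i][0], pair_list[i][1]) for i in train_idx if pair_list[i][2] == 1
        ]
        fold_assoc = _masked_association(assoc, train_positives)
        feature_source = assoc if global_features else fold_assoc
        fm, fd = feature_matrices(feature_source, dsim, fsim=fsim)
        graph = build_graph(fold_assoc, fm, fd)

        # structural leakage guard: no test positive may be a message edge
        edges = graph.undirected_edge_set()
        test_pos = frozenset(
            (graph.mirna_node(pair_list[i][0]), graph.disease_node(pair_list[i][1]))
            for i in test_idx
            if pair_list[i][2] == 1
        )
        leaked = edges & test_pos
        if leaked:
            raise ConsistencyError(f"fold {fold}: test positives leaked into message edges: {sorted(leaked)[:5]}")

        topo = embed_graph(graph, walk_cfg)
        index_pairs = pairs.index_pairs(graph)
        est = clone(model)
        est.fit(index_pairs[train_idx], labels[train_idx], graph=graph, topo=topo)
        scores = est.predict_proba(index_pairs[test_idx])[:, 1]
        reports.append(evaluate(scores, labels[test_idx], threshold=threshold))
        diagnostics.append(
            FoldDiagnostics(
                fold=fold,
                message_passing_edges=edges,
                test_positive_edges=test_pos,
                n_train=train_idx.size,
                n_test=test_idx.size,
            )
        )
    return CVResult(mean=MetricReport.mean_of(reports), diagnostics=diagnostics)


def hyperparameter_sweep(
    assoc: AssociationMatrix,
    dsim: SimilarityMatrix,
    pairs: LabeledPairSet,
    plan: FoldPlan,
    layers_grid=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10),
    orders_grid=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10),
    families=("origin",),
    model: MomentGNN | None = None,
    walk_cfg: WalkConfig | None = None,
    **cv_kwargs,
) -> pd.DataFrame:
    """Grid sweep over layer count, moment order and moment family.

    Every setting reuses the same fold plan so rows are directly comparable.
    The grid follows the two one-dimensional sweeps used to pick the
    defaults: layers are varied at the best moment order and vice versa.
    """
    model = model if model is not None else MomentGNN()
    rows = []
    settings = [
        (layers, order, family)
        for family in families
        for layers in layers_grid
        for order in orders_grid
    ]
    if not settings:
        raise ValueError("sweep grid is empty")
    for layers, order, family in settings:
        candidate = clone(model).set_params(
            n_layers=layers, moment_order=order, moment_family=family
        )
        result = cross_validate(
            assoc, dsim, pairs, plan, model=candidate, walk_cfg=walk_cfg, **cv_kwargs
        )
        rows.append(
            {
                "layers": layers,
                "moment_order": order,
                "moment_family": family,
                **result.mean.as_dict(),
            }
        )
    return pd.DataFrame(rows)


def case_study_rank(
    assoc: AssociationMatrix,
    dsim: SimilarityMatrix,
    target_disease: str,
    model: MomentGNN | None = None,
    walk_cfg: WalkConfig | None = None,
    fsim: SimilarityMatrix | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-disease-out ranking of every miRNA against ``target_disease``.

    All edges incident to the target are removed before training; the trained
    model then scores every miRNA against the target.  Returns a descending
    ranking with a ``known`` column flagging the held-out true partners.
    """
    if target_disease not in assoc.disease_ids:
        raise UnknownIdError([target_disease])
    col = assoc.disease_index(target_disease)
    if assoc.values[:, col].sum() == 0:
        raise ValueError(f"{target_disease!r} has no known associations to hold out")

    kept_positives = [(m, d) for m, d in assoc.positives() if d != target_disease]
    masked = _masked_association(assoc, kept_positives)

    # negatives come from unobserved pairs outside the held-out column
    pool = masked.values.copy()
    pool[:, col] = 1  # excluded from sampling
    pool_assoc = AssociationMatrix(
        mirna_ids=list(assoc.mirna_ids), disease_ids=list(assoc.disease_ids), values=pool
    )
    negatives = sample_negatives(pool_assoc, n_neg=len(kept_positives), seed=seed)
    train_pairs = [(m, d, 1) for m, d in kept_positives] + list(negatives.pairs)
    train_set = LabeledPairSet(pairs=train_pairs, provenance="case_study", seed=seed)

    fm, fd = feature_matrices(masked, dsim, fsim=fsim)
    graph = build_graph(masked, fm, fd)
    topo = embed_graph(graph, walk_cfg or WalkConfig())
    est = clone(model) if model is not None else MomentGNN()
    est.fit(train_set.index_pairs(graph), train_set.labels, graph=graph, topo=topo)

    target_node = graph.disease_node(target_disease)
    query = np.array([[graph.mirna_node(m), target_node] for m in assoc.mirna_ids])
    scores = est.predict_proba(query)[:, 1]
    frame = pd.DataFrame(
        {
            "mirna": assoc.mirna_ids,
            "score": scores,
            "known": assoc.values[:, col].astype(bool),
        }
    )
    return frame.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
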