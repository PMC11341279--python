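"""Moment-aggregation graph model with element-level attention and residuals.

Instead of aggregating a node's neighborhood with a single statistic (mean or
max), each layer computes the k-th order statistical moments of the
first-order neighbor features for k = 1..K — origin moments
``((1/n) sum_j h_j^k)^(1/k)`` and/or central moments of the mean-centered
neighbors — normalises them with a signed k-th root, and fuses them with a
per-feature-dimension sigmoid attention gate.  A residual mix
``beta * processed + gamma * previous`` stabilises depth.  Pair scores come
from an MLP over the concatenated miRNA and disease embeddings.

The estimator follows scikit-learn conventions: hyperparameters in
``__init__``, data in ``fit`` (the graph context is passed as fit
parameters), fitted attributes with a trailing underscore.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import autodiff as ad
from .autodiff import Tensor
from .embedding import TopoEmbedding
from .exceptions import NumericError, UnknownIdError
from .graph import HeteroGraph

MOMENT_FAMILIES = ("origin", "central", "hybrid")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``hidden_dim`` must equal ``proj_dim`` plus the topological embedding
    width, because layer 0 concatenates the projected attribute features with
    the topology vectors and every W_k is square.
    """

    layers: int = 4
    moment_order: int = 10
    moment_family: str = "origin"
    proj_dim: int = 64
    hidden_dim: int = 128
    beta: float = 0.5
    gamma: float = 0.5
    eps: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.layers < 1:
            raise ValueError("layers must be >= 1")
        if self.moment_order < 1:
            raise ValueError("moment_order must be >= 1")
        if self.moment_family not in MOMENT_FAMILIES:
            raise ValueError(f"moment_family must be one of {MOMENT_FAMILIES}")
        if self.beta < 0 or self.gamma < 0 or (self.beta == 0 and self.gamma == 0):
            raise ValueError("beta and gamma must be non-negative and not both zero")

    def moment_slots(self) -> list[tuple[str, int]]:
        """The (family, order) slices of the moment stack, in fusion order."""
        k_range = range(1, self.moment_order + 1)
        if self.moment_family == "origin":
            return [("origin", k) for k in k_range]
        if self.moment_family == "central":
            return [("central", k) for k in k_range]
        return [("origin", k) for k in k_range] + [("central", k) for k in k_range]


def _uniform_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def init_parameters(
    cfg: ModelConfig, n_feat_mirna: int, n_feat_disease: int, mlp_hidden: int = 64
) -> dict[str, Tensor]:
    """Seeded uniform fan-in initialisation of every learnable matrix."""
    rng = np.random.default_rng(cfg.seed)
    D = cfg.hidden_dim
    params: dict[str, Tensor] = {
        "W_m": Tensor(_uniform_init(rng, n_feat_mirna, (n_feat_mirna, cfg.proj_dim)), requires_grad=True),
        "W_d": Tensor(_uniform_init(rng, n_feat_disease, (n_feat_disease, cfg.proj_dim)), requires_grad=True),
    }
    n_slots = len(cfg.moment_slots())
    for layer in range(cfg.layers):
        for slot in range(n_slots):
            params[f"W_mom_{layer}_{slot}"] = Tensor(_uniform_init(rng, D, (D, D)), requires_grad=True)
            params[f"W_key_{layer}_{slot}"] = Tensor(_uniform_init(rng, D, (D, D)), requires_grad=True)
        params[f"W_q_{layer}"] = Tensor(_uniform_init(rng, D, (D, D)), requires_grad=True)
        params[f"W_alpha_{layer}"] = Tensor(_uniform_init(rng, 2 * D, (2 * D, D)), requires_grad=True)
    params["W_mlp1"] = Tensor(_uniform_init(rng, 3 * D, (3 * D, mlp_hidden)), requires_grad=True)
    params["b_mlp1"] = Tensor(np.zeros(mlp_hidden), requires_grad=True)
    params["W_mlp2"] = Tensor(_uniform_init(rng, mlp_hidden, (mlp_hidden, 1)), requires_grad=True)
    params["b_mlp2"] = Tensor(np.zeros(1), requires_grad=True)
    return params


# --------------------------------------------------------------------------
# tape-building blocks shared by the functional API and the estimator
# --------------------------------------------------------------------------

def _moment_slice(
    neigh: Tensor,
    src: np.ndarray,
    n_nodes: int,
    family: str,
    k: int,
    eps: float,
    mu: Tensor | None = None,
) -> Tensor:
    """Un-projected k-th moment of neighbor rows grouped by center node."""
    if family == "origin":
        powered = ad.power_int(neigh, k)
    else:
        if mu is None:
            mu = ad.segment_mean(neigh, src, n_nodes)
        centered = neigh + ad.scale(ad.gather(mu, src), -1.0)
        powered = ad.power_int(centered, k)
    averaged = ad.segment_mean(powered, src, n_nodes)
    return ad.signed_root(averaged, k, eps)


def _layer0(graph: HeteroGraph, topo: TopoEmbedding, params: dict[str, Tensor]) -> Tensor:
    fm = Tensor(graph.mirna_features)
    fd = Tensor(graph.disease_features)
    projected = ad.concat([fm @ params["W_m"], fd @ params["W_d"]], axis=0)
    return ad.concat([projected, Tensor(topo.vectors)], axis=1)


def _forward_tape(
    graph: HeteroGraph,
    topo: TopoEmbedding,
    cfg: ModelConfig,
    params: dict[str, Tensor],
    attention_override: float | None = None,
) -> Tensor:
    src, dst = graph.flat_edges()
    n = graph.n_nodes
    slots = cfg.moment_slots()
    h = _layer0(graph, topo, params)
    if h.data.shape[1] != cfg.hidden_dim:
        raise ValueError(
            f"hidden_dim {cfg.hidden_dim} != proj_dim + topo width {h.data.shape[1]}"
        )
    for layer in range(cfg.layers):
        neigh = ad.gather(h, dst)
        mu = ad.segment_mean(neigh, src, n) if any(f == "central" for f, _ in slots) else None
        h_query = h @ params[f"W_q_{layer}"]
        aggregated = None
        for slot, (family, k) in enumerate(slots):
            moment = _moment_slice(neigh, src, n, family, k, cfg.eps, mu)
            if not np.isfinite(moment.data).all():
                raise NumericError(f"non-finite moment at layer {layer}, {family} order {k}")
            moment = moment @ params[f"W_mom_{layer}_{slot}"]
            if attention_override is None:
                key = moment @ params[f"W_key_{layer}_{slot}"]
                gate = ad.sigmoid(ad.concat([h_query, key], axis=1) @ params[f"W_alpha_{layer}"])
                term = ad.mul(gate, moment)
            else:
                term = ad.scale(moment, attention_override)
            aggregated = term if aggregated is None else aggregated + term
        h = ad.scale(aggregated, cfg.beta) + ad.scale(h, cfg.gamma)
        if not np.isfinite(h.data).all():
            raise NumericError(f"non-finite embedding after layer {layer}")
    return h


def _pair_logits(h: Tensor, pair_index: np.ndarray, params: dict[str, Tensor]) -> Tensor:
    hm = ad.gather(h, pair_index[:, 0])
    hd = ad.gather(h, pair_index[:, 1])
    # the Hadamard term makes pair compatibility directly learnable instead
    # of leaving the MLP to synthesise interactions from the two halves
    z = ad.concat([hm, hd, ad.mul(hm, hd)], axis=1)
    hidden = ad.relu(z @ params["W_mlp1"] + params["b_mlp1"])
    return hidden @ params["W_mlp2"] + params["b_mlp2"]


# --------------------------------------------------------------------------
# functional API (numpy in, numpy out)
# --------------------------------------------------------------------------

def signed_root(s, k: int, eps: float = 1e-8) -> np.ndarray:
    """``sign(s) * (|s| + eps)**(1/k)`` elementwise; identity (up to eps) at k=1."""
    return ad.signed_root(Tensor(np.asarray(s, dtype=float)), k, eps).data


def project_and_concat(
    fm_rows: np.ndarray,
    fd_rows: np.ndarray,
    topo: TopoEmbedding,
    W_m: np.ndarray,
    W_d: np.ndarray,
) -> np.ndarray:
    """Layer-0 embedding: projected attribute rows concatenated with topology."""
    if fm_rows.shape[1] != W_m.shape[0] or fd_rows.shape[1] != W_d.shape[0]:
        raise ValueError("feature widths do not match projection matrices")
    if W_m.shape[1] != W_d.shape[1]:
        raise ValueError("W_m and W_d must project to the same width")
    projected = np.vstack([fm_rows @ W_m, fd_rows @ W_d])
    if topo.vectors.shape[0] != projected.shape[0]:
        raise ValueError("topology embedding rows do not match node count")
    return np.hstack([projected, topo.vectors])


def origin_moment(h, graph: HeteroGraph, k: int, W=None, eps: float = 0.0) -> np.ndarray:
    """Signed-rooted k-th origin moment of neighbor features, per node."""
    src, dst = graph.flat_edges()
    h = np.asarray(h, dtype=float)
    if h.ndim == 1:
        h = h[:, None]
    neigh = ad.gather(Tensor(h), dst)
    out = _moment_slice(neigh, src, graph.n_nodes, "origin", k, eps).data
    return out if W is None else out @ np.asarray(W, dtype=float)


def central_moment(h, graph: HeteroGraph, k: int, W=None, eps: float = 0.0) -> np.ndarray:
    """Signed-rooted k-th central moment of neighbor features, per node."""
    src, dst = graph.flat_edges()
    h = np.asarray(h, dtype=float)
    if h.ndim == 1:
        h = h[:, None]
    neigh = ad.gather(Tensor(h), dst)
    out = _moment_slice(neigh, src, graph.n_nodes, "central", k, eps).data
    return out if W is None else out @ np.asarray(W, dtype=float)


def element_attention(h, moment, W_q, W_k, W_alpha) -> np.ndarray:
    """Per-feature sigmoid gate in (0,1): sigmoid([h W_q || M W_k] W_alpha)."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    moment = np.atleast_2d(np.asarray(moment, dtype=float))
    W_q, W_k, W_alpha = (np.asarray(w, dtype=float) for w in (W_q, W_k, W_alpha))
    if W_q.ndim < 2:
        W_q = W_q.reshape(h.shape[1], -1)
    if W_k.ndim < 2:
        W_k = W_k.reshape(moment.shape[1], -1)
    query = h @ W_q
    key = moment @ W_k
    stacked = np.hstack([query, key])
    if W_alpha.ndim < 2:
        W_alpha = W_alpha.reshape(stacked.shape[1], -1)
    if W_alpha.shape[0] != stacked.shape[1]:
        raise ValueError(f"W_alpha must map {stacked.shape[1]} -> D, got {W_alpha.shape}")
    return ad.sigmoid(Tensor(stacked @ W_alpha)).data


def aggregate_moments(alphas, moments) -> np.ndarray:
    """Elementwise-weighted sum over moment orders: sum_k alpha_k ⊙ M_k."""
    alphas = [np.asarray(a, dtype=float) for a in alphas]
    moments = [np.asarray(m, dtype=float) for m in moments]
    if len(alphas) != len(moments):
        raise ValueError("one gate per moment slice required")
    out = None
    for a, m in zip(alphas, moments):
        if a.shape != m.shape:
            raise ValueError(f"gate shape {a.shape} != moment shape {m.shape}")
        out = a * m if out is None else out + a * m
    return out


def residual_fuse(F_o, F_s, beta: float = 0.5, gamma: float = 0.5) -> np.ndarray:
    """Residual mix beta * processed + gamma * previous (elementwise addition)."""
    F_o = np.asarray(F_o, dtype=float)
    F_s = np.asarray(F_s, dtype=float)
    if F_o.shape != F_s.shape:
        raise ValueError(f"shape mismatch: {F_o.shape} vs {F_s.shape}")
    return beta * F_o + gamma * F_s


def forward(
    graph: HeteroGraph,
    topo: TopoEmbedding,
    cfg: ModelConfig,
    params: dict[str, Tensor],
    attention_override: float | None = None,
) -> np.ndarray:
    """Full L-layer forward pass; returns the layer-L node embeddings.

    ``attention_override`` replaces every attention gate with a constant —
    used to check the reduction of the K=1 origin model to plain mean
    aggregation.
    """
    return _forward_tape(graph, topo, cfg, params, attention_override).data


def score_pairs(embeddings: np.ndarray, pair_index: np.ndarray, params: dict[str, Tensor]) -> np.ndarray:
    """MLP association scores in (0,1) for (mirna_node, disease_node) index pairs."""
    pair_index = np.asarray(pair_index, dtype=np.int64).reshape(-1, 2)
    if pair_index.size and pair_index.max() >= embeddings.shape[0]:
        raise UnknownIdError([int(pair_index.max())])
    logits = _pair_logits(Tensor(embeddings), pair_index, params)
    return ad.sigmoid(logits).data.ravel()


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

class MomentGNN(BaseEstimator, ClassifierMixin):
    """scikit-learn style classifier scoring miRNA-disease pairs.

    ``X`` is an ``(n, 2)`` integer array of (miRNA node index, disease node
    index) pairs in the graph's canonical node order; ``y`` the binary
    labels.  The graph and topological embedding are data, not
    hyperparameters, and are passed to :meth:`fit`.

    Parameters mirror :class:`ModelConfig` plus the training loop controls.
    """

    def __init__(
        self,
        n_layers: int = 4,
        moment_order: int = 10,
        moment_family: str = "origin",
        proj_dim: int = 64,
        beta: float = 0.5,
        gamma: float = 0.5,
        eps: float = 1e-8,
        learning_rate: float = 1e-3,
        max_epochs: int = 500,
        patience: int = 30,
        val_fraction: float = 0.1,
        clip_norm: float = 5.0,
        mlp_hidden: int = 64,
        random_state: int = 0,
    ):
        self.n_layers = n_layers
        self.moment_order = moment_order
        self.moment_family = moment_family
        self.proj_dim = proj_dim
        self.beta = beta
        self.gamma = gamma
        self.eps = eps
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.clip_norm = clip_norm
        self.mlp_hidden = mlp_hidden
        self.random_state = random_state

    def _config(self, topo_dim: int) -> ModelConfig:
        return ModelConfig(
            layers=self.n_layers,
            moment_order=self.moment_order,
            moment_family=self.moment_family,
            proj_dim=self.proj_dim,
            hidden_dim=self.proj_dim + topo_dim,
            beta=self.beta,
            gamma=self.gamma,
            eps=self.eps,
            seed=self.random_state,
        )

    def fit(self, X, y, *, graph: HeteroGraph, topo: TopoEmbedding):
        from .evaluate import auc_score  # local import to avoid a cycle

        X = np.asarray(X, dtype=np.int64).reshape(-1, 2)
        y = np.asarray(y, dtype=np.int64).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("training set must contain both labels 0 and 1")
        if X.size and X.max() >= graph.n_nodes:
            raise UnknownIdError([int(X.max())])

        cfg = self._config(topo.dim)
        params = init_parameters(cfg, graph.mirna_features.shape[1],
                                 graph.disease_features.shape[1], self.mlp_hidden)
        trainable = list(params.values())
        optimizer = ad.Adam(trainable, lr=self.learning_rate, clip_norm=self.clip_norm)

        # stratified validation split for early stopping
        rng = np.random.default_rng(self.random_state)
        val_mask = np.zeros(len(y), dtype=bool)
        if self.val_fraction > 0:
            for label in (0, 1):
                idx = np.flatnonzero(y == label)
                n_val = int(round(self.val_fraction * idx.size))
                if 0 < n_val < idx.size:
                    val_mask[rng.choice(idx, size=n_val, replace=False)] = True
        if val_mask.sum() == 0 or len(np.unique(y[val_mask])) < 2:
            val_mask[:] = False
        train_idx = np.flatnonzero(~val_mask)
        val_idx = np.flatnonzero(val_mask)

        loss_trace: list[float] = []
        val_trace: list[float] = []
        best_val, best_epoch, best_state, stall = -np.inf, -1, None, 0
        for epoch in range(self.max_epochs):
            h = _forward_tape(graph, topo, cfg, params)
            logits = _pair_logits(h, X[train_idx], params)
            loss = ad.bce_with_logits(logits, y[train_idx])
            if not np.isfinite(loss.data):
                raise NumericError(f"training diverged (non-finite loss) at epoch {epoch}")
            loss_trace.append(float(loss.data))
            if val_idx.size:
                val_scores = score_pairs(h.data, X[val_idx], params)
                val_auc = auc_score(y[val_idx], val_scores)
                val_trace.append(val_auc)
                if val_auc > best_val + 1e-6:
                    best_val, best_epoch, stall = val_auc, epoch, 0
                    best_state = {k: v.data.copy() for k, v in params.items()}
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        if best_state is not None:
            for k, v in params.items():
                v.data = best_state[k]

        self.classes_ = np.array([0, 1])
        self.config_ = cfg
        self.params_ = params
        self.graph_ = graph
        self.topo_ = topo
        self.embeddings_ = _forward_tape(graph, topo, cfg, params).data
        self.loss_trace_ = np.array(loss_trace)
        self.val_auc_trace_ = np.array(val_trace)
        self.best_epoch_ = best_epoch if best_state is not None else len(loss_trace) - 1
        self.n_epochs_ = len(loss_trace)
        return self

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "embeddings_"):
            raise RuntimeError("estimator is not fitted")
        scores = score_pairs(self.embeddings_, np.asarray(X, dtype=np.int64), self.params_)
        return np.column_stack([1.0 - scores, scores])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(np.int64)

    def save(self, path) -> None:
        """Write parameters as an .npz archive with a JSON config sidecar."""
        path = Path(path)
        np.savez(path, **{k: v.data for k, v in self.params_.items()})
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(asdict(self.config_), indent=2))

    @classmethod
    def load(cls, path, graph: HeteroGraph, topo: TopoEmbedding) -> "MomentGNN":
        """Restore a checkpoint and recompute embeddings on the given graph."""
        path = Path(path)
        cfg = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        archive = np.load(path if path.suffix else path.with_suffix(".npz"))
        est = cls(
            n_layers=cfg.layers,
            moment_order=cfg.moment_order,
            moment_family=cfg.moment_family,
            proj_dim=cfg.proj_dim,
            beta=cfg.beta,
            gamma=cfg.gamma,
            eps=cfg.eps,
            random_state=cfg.seed,
        )
        est.config_ = cfg
        est.params_ = {k: Tensor(archive[k], requires_grad=True) for k in archive.files}
        est.classes_ = np.array([0, 1])
        est.graph_ = graph
        est.topo_ = topo
        est.embeddings_ = _forward_tape(graph, topo, cfg, est.params_).data
        return est
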