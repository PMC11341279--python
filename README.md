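# hhomr

Predicting miRNA–disease associations with a residual graph model that
aggregates neighborhoods through attention-weighted high-order statistical
moments.

Aberrant microRNA expression is implicated in many diseases, but validating
individual miRNA–disease associations experimentally is slow and expensive.
Given a catalogue of validated associations (e.g. HMDD-style curated pairs),
a disease hierarchy (MeSH-style parent→child terms), and optionally a
precomputed miRNA functional-similarity matrix, `hhomr` scores unobserved
miRNA–disease pairs so that likely associations can be prioritised for
experimental follow-up. It is aimed at computational biologists doing link
prediction on bipartite biomedical networks.

## The model

**Node features.** Disease semantic similarity comes from the hierarchy:
each disease `d` inherits a contribution `D_d(t) = max(δ · D_d(t'))` over
children `t'` of ancestor `t` (with `D_d(d) = 1`, decay `δ = 0.5`), and

```
MDSS(d_i, d_j) = Σ_{t ∈ T_i ∩ T_j} (D_i(t) + D_j(t)) / (Σ D_i + Σ D_j).
```

miRNA functional similarity is the best-match average of `MDSS` between the
two miRNAs' disease sets. Gaps in both matrices are filled by the Gaussian
interaction-profile kernel `exp(−φ‖BV_i − BV_j‖²)` on binary association
profiles, with bandwidth `φ` normalised by the mean squared profile norm.
The fused similarity rows are each node's raw features; biased second-order
random walks (node2vec policy, return parameter `p`, in-out parameter `q`)
plus skip-gram give each node a topological embedding that is concatenated
on.

**Moment aggregation.** Instead of a single mean/max aggregator, each layer
computes, per node `v` with neighbors `N(v)`, the signed-rooted k-th origin
moments

```
M_k(v) = ((1/n) Σ_{j∈N(v)} h_j^k)^(1/k) · W_k ,   k = 1..K
```

and/or central moments of the mean-centered neighbors (k = 1 is mean
aggregation; central k = 2 is the neighborhood standard deviation, which
separates nodes that share a neighborhood mean). A per-feature-dimension
sigmoid gate `α_k(v) = σ([h_v W_q ‖ M_k(v) W_k'] W_α)` weights each moment,
the gated moments are summed, and a residual mix `β·processed + γ·previous`
stabilises depth. An MLP on `[h_m ‖ h_d ‖ h_m ⊙ h_d]` produces the pair
score in (0, 1); training minimises binary cross-entropy against validated
positives and uniformly sampled unobserved pairs.

## Worked example

Everything runs on synthetic planted-block data, no downloads. Blocks of
miRNAs and diseases are preferentially associated (`p_in = 0.6` within,
`p_out = 0.02` across), so cross-validated recovery of held-out positives is
measurable:

```python
import hhomr as hh

bundle = hh.make_fixture()            # 40 miRNAs x 30 diseases, 3 blocks, seed 0
result = hh.cross_validate(
    bundle.assoc, bundle.dsim, bundle.pairs, bundle.fold_plan(n_folds=5),
    model=hh.MomentGNN(n_layers=2, moment_order=3),
)
print(f"mean AUC {result.mean.auc:.4f}")
print("fold AUCs", [round(f.auc, 3) for f in result.fold_reports])
```

```
mean AUC 0.8751
fold AUCs [0.855, 0.864, 0.865, 0.921, 0.871]
```

Each fold rebuilds similarities, the message-passing graph and the walk
embeddings from its own training positives, so the held-out edges never
leak into the representation. A mean AUC near 0.88 on this fixture means
the model recovers most of the planted block structure from incomplete
observations; the same pipeline on a signal-free fixture (`p_in = p_out`)
stays at chance (AUC ≈ 0.5).

The same pipeline is scriptable from the shell:

```
hhomr simulate --out-dir data/
hhomr cv --assoc data/associations.tsv --dag data/dag.tsv --out-dir results/
hhomr rank --assoc data/associations.tsv --dag data/dag.tsv \
      --disease d008 --out-dir results/
```

## Layout

- `src/hhomr/dag.py`, `similarity.py` — semantic/functional/GIP similarity and fusion
- `src/hhomr/graph.py` — bipartite graph, negative sampling, labeled pairs
- `src/hhomr/walks.py`, `embedding.py` — biased walks and skip-gram embeddings
- `src/hhomr/model.py`, `autodiff.py` — the moment-aggregation model and its gradient engine
- `src/hhomr/evaluate.py`, `cv.py` — metrics, folds, cross-validation, sweeps, case studies
- `src/hhomr/simulate.py` — planted-block synthetic data
- `docs/methods.md` — modelling assumptions, defaults, and limitations
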