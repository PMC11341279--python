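# Methods

## Problem setting

The package predicts missing links in a bipartite miRNA–disease graph. The
observed data are (i) a binary incidence matrix `R` (miRNA rows, disease
columns; a 0 means *unobserved*, not *absent*), (ii) a rooted disease
hierarchy, and (iii) optionally a precomputed miRNA functional-similarity
matrix. Internally the incidence matrix is always miRNA-rows ×
disease-columns; readers and writers translate to/from the two-column edge
lists used on disk.

## Similarity layers

**Semantic (hierarchy) similarity.** Each disease anchors a sub-DAG of its
ancestors. Contributions decay geometrically with decay `δ ∈ (0,1)`
(default 0.5): the anchor contributes 1, and each ancestor contributes `δ`
times the maximum over its children *inside the anchor's sub-DAG* —
contributions flow only along paths that lead back to the anchor. Pair
similarity is the shared contribution mass divided by the two total
semantic values; the diagonal is exactly 1. Ties in the max are harmless
(max is well defined).

**Functional similarity.** For miRNAs with disease sets of sizes `m` and
`n`, the score is the best-match sum in both directions divided by `m + n`.
A miRNA with no observed disease would divide by zero; its row and column
(including the diagonal) are set to 0 and flagged for fallback.

**GIP kernel.** `exp(−φ · ‖BV_i − BV_j‖²)` on binary profiles, with
`φ = φ′ / mean(‖BV‖²)` and raw bandwidth `φ′ = 1`. The diagonal is set to
exactly 1 and the matrix symmetrised to remove floating-point asymmetry. An
all-zero matrix has no defined bandwidth and is rejected.

**Fusion.** An off-diagonal entry of the primary (functional or semantic)
matrix counts as *defined* iff it is strictly positive — zeros are
indistinguishable from missing scores in distributed similarity files —
and undefined entries take the GIP value. Diagonal entries always come from
the primary matrix.

## Topology embedding

Second-order biased walks follow the node2vec policy: from `curr` with
predecessor `prev`, neighbor `x` has unnormalised weight `1/p` (return),
`1` (adjacent to `prev`), or `1/q` (otherwise), normalised into a proper
transition distribution — the normalisation is required for sampling even
though the policy is usually stated as bare weights. The first step of each
walk has no predecessor and is uniform. In a strictly bipartite graph no
candidate can be adjacent to the predecessor, so the middle case only
arises in non-bipartite test graphs; the implementation handles all three.

The skip-gram embedding is trained on the *expected*
skip-gram-with-negative-sampling objective: (center, context) pairs within
the window are aggregated into a co-occurrence count matrix and the noise
term uses the smoothed unigram distribution (`counts^0.75`, rate 5) in
closed form. Full-batch Adam (lr 0.05, 30 iterations per nominal epoch)
optimises the same objective as pair-by-pair SGNS but deterministically and
fast enough to re-embed every cross-validation fold. Nodes absent from the
corpus get zero vectors with a warning.

Walk defaults: `p = q = 1`, 10 walks per node, length 80, window 5,
64 dimensions, 5 epochs. These are conventional values; all are exposed in
`WalkConfig`.

## The moment-aggregation model

Layer 0 projects miRNA and disease feature rows to `proj_dim` (64) with
separate learned matrices and concatenates the 64-dim topology vectors,
giving `hidden_dim = 128` throughout; all per-layer matrices are square so
residual shapes stay compatible.

Each layer computes, for `k = 1..K`, the k-th origin moments of the
first-order neighbor features (plain elementwise integer power, neighbor
mean, signed k-th root) and/or central moments of the mean-centered
neighbors; the family is `origin`, `central`, or `hybrid` (both stacks
jointly gated, 2K slices). The signed root `sign(s)·(|s|+ε)^(1/k)` with
`ε = 1e-8` keeps odd-order negative moments negative and the map
differentiable at 0. Plain powers (not sign-preserving powers) are used
inside the moment: that is what makes the central k = 2 slice equal the
per-dimension population standard deviation, the property that lets
higher moments separate nodes with equal neighborhood means. Isolated
nodes get zero moment vectors — the additive identity of the gated sum.

Element-level attention gates each moment slice per feature dimension:
`α = σ([h W_q ‖ M_k W_key] W_α)`, with separate key matrices per (layer,
order) — the gate's key projection is not the moment's own output
projection. The gated slices are summed and mixed residually:
`h ← β·Σ_k α_k ⊙ M_k + γ·h`, defaults `β = γ = 0.5`. No extra activation
is inserted between layers; the sigmoid gates are the nonlinearity.

**Pair scoring.** The MLP input is `[h_m ‖ h_d ‖ h_m ⊙ h_d]` (384 → 64 →
1, ReLU hidden, sigmoid output). The Hadamard term matters: with
concatenation alone, training on small balanced samples converged to
miRNA/disease main effects — the ranking for a fixed disease barely
depended on the disease — because degree is individually predictive and
nothing forced the hidden layer to build interactions. The elementwise
product makes pair compatibility directly learnable; it is the standard
link-feature construction for node-embedding link prediction.

**Training.** Full-batch Adam (lr 1e-3, up to 500 epochs) on binary
cross-entropy, gradient clipped to global norm 5 (the signed-root
derivative is steep near zero), early stopping on the AUC of a 10%
stratified validation split with patience 30, best-epoch weights restored.
All parameters are initialised from a seeded uniform fan-in scheme; runs
are bit-reproducible for a fixed seed. Gradients come from a small
reverse-mode tape over numpy implemented in `autodiff.py`.

Defaults `L = 4` layers and `K = 10` moment orders follow the
hyperparameter sweeps for catalogue-scale data; on the small synthetic
fixtures the cross-validation studies here use `L = 2, K = 3` (and the
case study `L = 1, K = 2`), because with ~70 nodes and a few hundred pairs
deeper stacks only add variance — documented problem sizes, not hidden
switches.

## Evaluation protocol

Negatives are sampled uniformly without replacement from unobserved pairs,
one per positive (balanced), once globally by default. Folds are
stratified, seeded, and sized within one pair of each other. Per fold, the
similarities, the message-passing graph and the walk embeddings are rebuilt
from the fold's training positives only; a structural guard asserts that no
held-out positive is a message-passing edge. `global_features=True` instead
computes similarities once from the full matrix (mimicking a single global
preprocessing pass) while still keeping held-out edges out of the
adjacency; the two regimes differ materially and the leakage-safe one is
the default. AUC uses the rank (Mann–Whitney) formula with average ranks,
so tied cross-class pairs count 0.5 exactly; accuracy/precision/F1 use
threshold 0.5, canonical for balanced classes.

The case study removes every edge of one target disease, retrains, and
ranks all miRNAs against it. The isolated target keeps only its
(γ-scaled) raw feature row — its moments and topology vector are zero — so
recovery relies on semantic-similarity transfer and is the hardest
configuration for the model; on small matrices the induced degree drop of
the target's block further masks the signal, which is why the case-study
analyses use the default 40×30 fixture and the shallow configuration.

## Synthetic data

`FixtureSpec` plants a stochastic block model: miRNAs and diseases are
partitioned into `n_blocks` matching blocks; a pair is associated with
probability `p_in` within a block (default 0.6) and `p_out` across
(default 0.02); defaults 40 miRNAs × 30 diseases, 3 blocks, seed 0 —
small enough that full cross-validation runs in minutes on one CPU.
`p_in = p_out` is the signal-free null. The simulated hierarchy makes each
disease block a subtree under a common root, so semantic similarity carries
the same block signal as the associations.

What the generator does *not* emulate: the heavy-tailed degree
distributions of curated catalogues, correlated annotation biases (well-
studied diseases accumulate associations), disease-term polysemy, or any
sequence-level biology. Passing tests therefore show that the pipeline
recovers planted low-rank block structure from partial observations and is
calibrated under the null — not that it attains any particular performance
on real catalogues.

## Known limitations

- Dense similarity matrices and full-batch training cap practical problem
  size at a few thousand nodes; there is no mini-batching or sparse kernel.
- The count-based skip-gram trainer is exact for the expected SGNS loss but
  materialises a vocabulary × vocabulary count matrix.
- Early stopping needs both classes in the validation split; with very few
  pairs the split is skipped and training runs to the epoch limit.
- Scores for nodes isolated at training time (the case-study target) are
  out-of-distribution for the scorer; rankings for such nodes carry
  substantially more variance than cross-validation metrics.
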