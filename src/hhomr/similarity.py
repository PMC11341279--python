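"""miRNA functional similarity, GIP kernel similarity, and feature fusion.

Functional similarity between two miRNAs is the best-match average of the
semantic similarities between their associated disease sets.  The Gaussian
interaction-profile (GIP) kernel measures similarity of binary association
profiles, ``exp(-phi * ||BV_i - BV_j||^2)``, with the bandwidth ``phi``
normalised by the mean squared profile norm.  Because functional/semantic
similarity matrices are sparse, the GIP kernel fills the gaps: the fused
feature matrix takes the primary similarity where it is defined and falls
back to GIP elsewhere.
"""

from __future__ import annotations

import numpy as np

from .containers import AssociationMatrix, SimilarityMatrix
from .exceptions import AlignmentError, DegenerateBandwidthError

DEFAULT_RAW_BANDWIDTH = 1.0


def mirna_functional_similarity(
    assoc: AssociationMatrix, dsim: SimilarityMatrix
) -> SimilarityMatrix:
    """Best-match functional similarity between miRNAs via their disease sets.

    For miRNAs with disease sets ``DT1`` (size m) and ``DT2`` (size n), the
    score is the sum of each disease's best semantic match in the opposite
    set, divided by ``m + n``.  A miRNA with no known disease gets a zero
    row/column (including its diagonal); the GIP fallback covers it later.
    """
    if dsim.kind != "semantic":
        raise ValueError("dsim must be a semantic similarity matrix")
    missing = set(assoc.disease_ids) - set(dsim.ids)
    if missing:
        raise AlignmentError(f"diseases absent from semantic matrix: {sorted(missing)}")
    col_of = {d: i for i, d in enumerate(dsim.ids)}
    sel = [col_of[d] for d in assoc.disease_ids]
    S = dsim.values[np.ix_(sel, sel)]

    n_m = assoc.n_mirnas
    sets = [np.nonzero(assoc.values[i])[0] for i in range(n_m)]
    out = np.zeros((n_m, n_m))
    for i in range(n_m):
        di = sets[i]
        if di.size == 0:
            continue
        out[i, i] = 1.0
        for j in range(i + 1, n_m):
            dj = sets[j]
            if dj.size == 0:
                continue
            block = S[np.ix_(di, dj)]
            score = (block.max(axis=1).sum() + block.max(axis=0).sum()) / (di.size + dj.size)
            out[i, j] = out[j, i] = score
    return SimilarityMatrix(ids=list(assoc.mirna_ids), values=out, kind="functional")


def gip_similarity(
    assoc: AssociationMatrix, axis: str, raw_bandwidth: float = DEFAULT_RAW_BANDWIDTH
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over binary association profiles.

    ``axis='mirna'`` uses matrix rows as profiles, ``axis='disease'`` columns.
    The bandwidth is ``raw_bandwidth`` divided by the mean squared profile
    norm (the average interaction count).
    """
    if axis == "mirna":
        profiles = assoc.values.astype(float)
        ids = list(assoc.mirna_ids)
        kind = "gip_mirna"
    elif axis == "disease":
        profiles = assoc.values.T.astype(float)
        ids = list(assoc.disease_ids)
        kind = "gip_disease"
    else:
        raise ValueError(f"axis must be 'mirna' or 'disease', got {axis!r}")
    sq_norms = (profiles**2).sum(axis=1)
    mean_sq = sq_norms.mean()
    if mean_sq == 0:
        raise DegenerateBandwidthError(
            f"all {axis} interaction profiles are zero; GIP bandwidth undefined"
        )
    bandwidth = raw_bandwidth / mean_sq
    # squared Euclidean distance between binary profiles
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (profiles @ profiles.T)
    np.maximum(sq_dist, 0.0, out=sq_dist)
    values = np.exp(-bandwidth * sq_dist)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(ids=ids, values=values, kind=kind)


def fuse_features(primary: SimilarityMatrix, fallback: SimilarityMatrix) -> SimilarityMatrix:
    """Fill undefined primary-similarity entries with the GIP fallback.

    An off-diagonal primary entry counts as defined iff it is strictly
    positive; zeros are indistinguishable from missing scores in distributed
    similarity matrices.  Diagonal entries always come from the primary
    matrix.
    """
    if not primary.aligned_with(fallback):
        raise AlignmentError("primary and fallback similarity matrices use different id orderings")
    if not fallback.kind.startswith("gip"):
        raise ValueError("fallback must be a GIP similarity matrix")
    defined = primary.values > 0
    np.fill_diagonal(defined, True)
    fused = np.where(defined, primary.values, fallback.values)
    kind = "fused_mirna" if fallback.kind == "gip_mirna" else "fused_disease"
    return SimilarityMatrix(ids=list(primary.ids), values=fused, kind=kind)


def feature_matrices(
    assoc: AssociationMatrix,
    dsim: SimilarityMatrix,
    fsim: SimilarityMatrix | None = None,
    raw_bandwidth: float = DEFAULT_RAW_BANDWIDTH,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Build the fused miRNA and disease feature matrices from one association matrix.

    ``fsim`` optionally supplies a precomputed miRNA functional-similarity
    matrix (e.g. distributed MISIM scores) in place of the best-match
    computation.
    """
    if fsim is None:
        fsim = mirna_functional_similarity(assoc, dsim)
    elif fsim.ids != list(assoc.mirna_ids):
        raise AlignmentError("precomputed functional similarity does not match miRNA ids")
    if dsim.ids != list(assoc.disease_ids):
        col_of = {d: i for i, d in enumerate(dsim.ids)}
        try:
            sel = [col_of[d] for d in assoc.disease_ids]
        except KeyError as e:
            raise AlignmentError(f"disease {e.args[0]!r} absent from semantic matrix") from None
        dsim = SimilarityMatrix(
            ids=list(assoc.disease_ids), values=dsim.values[np.ix_(sel, sel)], kind="semantic"
        )
    mgip = gip_similarity(assoc, "mirna", raw_bandwidth)
    dgip = gip_similarity(assoc, "disease", raw_bandwidth)
    fm = fuse_features(fsim, mgip)
    fd = fuse_features(dsim, dgip)
    return fm, fd
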