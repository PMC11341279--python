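"""Core array containers: the binary association matrix and similarity matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import AlignmentError

SIMILARITY_KINDS = frozenset(
    {"semantic", "functional", "gip_mirna", "gip_disease", "fused_mirna", "fused_disease"}
)

#: kinds whose diagonal is exactly 1 by construction
_UNIT_DIAGONAL_KINDS = frozenset({"semantic", "gip_mirna", "gip_disease"})


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease incidence matrix.

    Rows are miRNAs, columns are diseases; entry ``(i, j)`` is 1 iff miRNA
    ``i`` has a validated association with disease ``j``.  A 0 means the pair
    is unobserved, not that the association is known to be absent.
    """

    mirna_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise AlignmentError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.mirna_ids)} miRNAs x {len(self.disease_ids)} diseases"
            )
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA identifiers")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")
        uniq = np.unique(self.values)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("association entries must be binary")
        self.values = self.values.astype(np.int8)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def positive_pairs(self) -> int:
        return int(self.values.sum())

    def mirna_index(self, mirna_id: str) -> int:
        return self.mirna_ids.index(mirna_id)

    def disease_index(self, disease_id: str) -> int:
        return self.disease_ids.index(disease_id)

    def positives(self) -> list[tuple[str, str]]:
        """All associated ``(mirna_id, disease_id)`` pairs in row-major order."""
        rows, cols = np.nonzero(self.values)
        return [(self.mirna_ids[r], self.disease_ids[c]) for r, c in zip(rows, cols)]

    def disease_set(self, mirna_id: str) -> list[str]:
        """Diseases associated with one miRNA, in column order."""
        row = self.values[self.mirna_index(mirna_id)]
        return [self.disease_ids[j] for j in np.nonzero(row)[0]]


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1]."""

    ids: list[str]
    values: np.ndarray = field(repr=False)
    kind: str = "semantic"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in SIMILARITY_KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise AlignmentError(f"expected {n}x{n} matrix, got {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")
        if self.kind in _UNIT_DIAGONAL_KINDS and not np.allclose(np.diag(self.values), 1.0):
            raise ValueError(f"{self.kind} similarity must have unit diagonal")

    @property
    def n(self) -> int:
        return len(self.ids)

    def aligned_with(self, other: "SimilarityMatrix") -> bool:
        return self.ids == other.ids
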