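"""TSV readers and writers for every on-disk artefact.

All files are UTF-8 tab-separated text.  Similarity matrices are written
with an id header row, ids in the first column, and 6-decimal fixed-point
entries; association and hierarchy inputs are two-column edge lists; labeled
pairs are three columns (mirna, disease, label).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AssociationMatrix, SimilarityMatrix
from .graph import LabeledPairSet


def read_association_tsv(path) -> AssociationMatrix:
    """Read ``mirna_id<TAB>disease_id`` pairs into a binary matrix.

    Row/column orders follow first appearance.  A header line is detected by
    the literal column names ``mirna``/``disease``.
    """
    pairs = _read_pair_lines(path, n_cols=2)
    mirnas: list[str] = []
    diseases: list[str] = []
    m_of: dict[str, int] = {}
    d_of: dict[str, int] = {}
    entries = []
    for m, d in pairs:
        if m not in m_of:
            m_of[m] = len(mirnas)
            mirnas.append(m)
        if d not in d_of:
            d_of[d] = len(diseases)
            diseases.append(d)
        entries.append((m_of[m], d_of[d]))
    values = np.zeros((len(mirnas), len(diseases)), dtype=np.int8)
    for i, j in entries:
        values[i, j] = 1
    return AssociationMatrix(mirna_ids=mirnas, disease_ids=diseases, values=values)


def write_association_tsv(assoc: AssociationMatrix, path) -> None:
    lines = ["mirna\tdisease"]
    # canonical lexicographic order so equal matrices serialise identically
    lines += [f"{m}\t{d}" for m, d in sorted(assoc.positives())]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_dag_tsv(path) -> list[tuple[str, str]]:
    """Read ``parent<TAB>child`` hierarchy edges (header optional)."""
    return _read_pair_lines(path, n_cols=2, header_tokens={"parent", "child"})


def write_dag_tsv(edges, path) -> None:
    lines = ["parent\tchild"] + [f"{p}\t{c}" for p, c in edges]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_pair_lines(path, n_cols, header_tokens={"mirna", "disease"}) -> list[tuple]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != n_cols:
                raise ValueError(f"{path}:{line_no}: expected {n_cols} columns, got {len(fields)}")
            if line_no == 1 and fields[0].lower() in header_tokens:
                continue
            if any(not f.strip() for f in fields):
                raise ValueError(f"{path}:{line_no}: blank field")
            rows.append(tuple(fields))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return rows


def write_similarity_tsv(sim: SimilarityMatrix, path) -> None:
    """Write a square similarity matrix with ids and 6-decimal entries."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(sim.ids) + "\n")
        for i, row_id in enumerate(sim.ids):
            fh.write(row_id + "\t" + "\t".join(f"{v:.6f}" for v in sim.values[i]) + "\n")


def read_similarity_tsv(path, kind: str) -> SimilarityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in frame.columns]
    if [str(i) for i in frame.index] != ids:
        raise ValueError(f"{path}: row ids do not match column ids")
    values = frame.to_numpy(dtype=float)
    values = 0.5 * (values + values.T)  # undo asymmetric rounding
    return SimilarityMatrix(ids=ids, values=values, kind=kind)


def write_pairs_tsv(pairs: LabeledPairSet, path) -> None:
    lines = ["mirna\tdisease\tlabel"]
    lines += [f"{m}\t{d}\t{lab}" for m, d, lab in pairs]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_pairs_tsv(path, provenance: str = "loaded", seed: int | None = None) -> LabeledPairSet:
    rows = _read_pair_lines(path, n_cols=3)
    pairs = [(m, d, int(lab)) for m, d, lab in rows]
    return LabeledPairSet(pairs=pairs, provenance=provenance, seed=seed)


def write_embedding_tsv(ids, vectors: np.ndarray, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for node_id, row in zip(ids, vectors):
            fh.write(str(node_id) + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
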