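"""Readers/writers for the BEELINE-style file dialects.

Three inputs: an expression matrix CSV (rows = genes, columns = cells),
a two-column regulatory edge-list CSV (header ``Gene1,Gene2`` or
``TF,Target``), and a TF list (one id per line, optional ``TF`` header).
One output: a ranked-edge TSV of predicted regulatory scores.

Gene identifiers are matched case-insensitively across files; the casing in
the expression file is authoritative for output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PriorNetwork",
    "TFList",
    "read_expression",
    "read_network",
    "read_tf_list",
    "write_ranked_edges",
]


@dataclass
class ExpressionMatrix:
    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray  # genes x cells

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        lowered = [g.lower() for g in self.gene_ids]
        if len(set(lowered)) != len(lowered):
            dupes = sorted({g for g in lowered if lowered.count(g) > 1})
            raise ValueError(f"duplicate gene ids (case-insensitive): {dupes}")


@dataclass
class PriorNetwork:
    edges: list[tuple[str, str]]
    source_label: str = "synthetic"

    def __post_init__(self):
        seen = set()
        for tf, tg in self.edges:
            key = (tf.lower(), tg.lower())
            if key[0] == key[1]:
                raise ValueError(f"self-edge in network: {tf}")
            if key in seen:
                raise ValueError(f"duplicate edge: {tf}->{tg}")
            seen.add(key)


@dataclass
class TFList:
    tf_ids: set[str]

    def __post_init__(self):
        if not self.tf_ids:
            raise ValueError("TF list is empty")


def read_expression(path) -> ExpressionMatrix:
    """Parse a genes-by-cells expression CSV (BEELINE layout)."""
    df = pd.read_csv(path, header=0, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no cell columns found")
    if df.isna().any().any():
        rows, cols = np.where(df.isna().to_numpy())
        gene = df.index[rows[0]]
        cell = df.columns[cols[0]]
        raise ValueError(f"{path}: missing/ragged value at gene {gene!r}, cell {cell!r}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"{path}: non-numeric value at gene {gene!r}, cell {col!r}"
                ) from None
        raise
    gene_ids = [str(g) for g in df.index]
    lowered = [g.lower() for g in gene_ids]
    if len(set(lowered)) != len(lowered):
        dupes = sorted({gene_ids[i] for i, g in enumerate(lowered) if lowered.count(g) > 1})
        raise ValueError(f"{path}: duplicate gene ids: {dupes}")
    return ExpressionMatrix(gene_ids, [str(c) for c in df.columns], values)


_NETWORK_HEADERS = ({"gene1", "gene2"}, {"tf", "target"})


def read_network(path, source_label: str = "unspecified") -> PriorNetwork:
    """Parse a two-column edge list; dedup and drop self-edges with logging."""
    df = pd.read_csv(path, header=0, dtype=str)
    cols = {c.lower().strip() for c in df.columns[:2]}
    if len(df.columns) < 2 or cols not in _NETWORK_HEADERS:
        raise ValueError(
            f"{path}: expected header Gene1,Gene2 or TF,Target, got {list(df.columns)}"
        )
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = n_self = 0
    for tf, tg in df.iloc[:, :2].itertuples(index=False):
        tf, tg = str(tf).strip(), str(tg).strip()
        key = (tf.lower(), tg.lower())
        if key[0] == key[1]:
            n_self += 1
            continue
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        edges.append((tf, tg))
    if n_dup or n_self:
        log.info("%s: dropped %d duplicate and %d self edges", path, n_dup, n_self)
    if not edges:
        raise ValueError(f"{path}: empty edge list after filtering")
    return PriorNetwork(edges, source_label=source_label)


def read_tf_list(path) -> TFList:
    """Parse a TF list: one id per line or single-column CSV with 'TF' header."""
    with open(path) as fh:
        lines = [ln.strip().strip(",") for ln in fh if ln.strip()]
    if lines and lines[0].lower() == "tf":
        lines = lines[1:]
    if not lines:
        raise ValueError(f"{path}: empty TF list")
    ids: list[str] = []
    seen: set[str] = set()
    n_dup = 0
    for ln in lines:
        if ln.lower() in seen:
            n_dup += 1
            continue
        seen.add(ln.lower())
        ids.append(ln)
    if n_dup:
        log.info("%s: dropped %d duplicate TF ids", path, n_dup)
    return TFList(set(ids))


def write_ranked_edges(predictions, path) -> None:
    """Write scored TF-target pairs as TSV, descending score, lexicographic ties."""
    rows = [(str(tf), str(tg), float(s)) for tf, tg, s in predictions]
    for tf, tg, s in rows:
        if not np.isfinite(s):
            raise ValueError(f"non-finite score for ({tf},{tg})")
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("TF\tTarget\tScore\n")
        for tf, tg, s in rows:
            fh.write(f"{tf}\t{tg}\t{s:.10g}\n")
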