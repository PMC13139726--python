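"""Ranking metrics and network-level diagnostics.

AUROC is the Mann-Whitney probability that a random positive outscores a
random negative, counting ties as one half — computed from average ranks,
so it is deterministic and invariant under strictly monotone score
transforms.  AUPRC is stepwise average precision (mean over positives of
precision at their rank), the stricter convention commonly used for
regulatory-network benchmarking; ties are broken by stable input index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["MetricReport", "auroc", "auprc", "evaluate_pairs", "predict_all", "degree_distribution"]


@dataclass(frozen=True)
class MetricReport:
    auroc: float
    auprc: float
    n_pos: int
    n_neg: int
    split_name: str

    def to_dict(self) -> dict:
        return {
            "split": self.split_name,
            "auroc": self.auroc,
            "auprc": self.auprc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def _check_two_class(labels: np.ndarray, split: str):
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"{split}: both classes required (n_pos={n_pos}, n_neg={n_neg})")
    return n_pos, n_neg


def auroc(labels, scores, split: str = "eval") -> float:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos, n_neg = _check_two_class(labels, split)
    ranks = rankdata(scores)  # average ranks handle ties as 0.5
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auprc(labels, scores, split: str = "eval") -> float:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos, _ = _check_two_class(labels, split)
    order = np.lexsort((np.arange(len(scores)), -scores))  # desc score, stable
    sorted_labels = labels[order]
    hits = np.cumsum(sorted_labels)
    ranks = np.arange(1, len(scores) + 1)
    precision_at_pos = hits[sorted_labels == 1] / ranks[sorted_labels == 1]
    return float(precision_at_pos.mean())


def evaluate_pairs(labels, scores, split: str = "eval") -> MetricReport:
    labels = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_two_class(labels, split)
    return MetricReport(
        auroc=auroc(labels, scores, split),
        auprc=auprc(labels, scores, split),
        n_pos=n_pos,
        n_neg=n_neg,
        split_name=split,
    )


def predict_all(score_fn, tf_indices, gene_index, *, exclude=None):
    """Score every (tf, gene) pair with tf != gene.

    ``score_fn`` maps an (k, 2) index array to k scores.  ``exclude`` is an
    optional iterable of index pairs (typically training positives) removed
    from the candidate list.  Returns (id_triples, index_pairs, scores) with
    identifiers resolved through ``gene_index``.
    """
    excl = {(int(a), int(b)) for a, b in exclude} if exclude is not None else set()
    pairs = [
        (int(tf), g)
        for tf in tf_indices
        for g in range(len(gene_index))
        if g != tf and (int(tf), g) not in excl
    ]
    pairs = np.array(pairs, dtype=int).reshape(-1, 2)
    scores = np.asarray(score_fn(pairs), dtype=float)
    ids = [
        (gene_index.index_to_id[a], gene_index.index_to_id[b], float(s))
        for (a, b), s in zip(pairs, scores)
    ]
    return ids, pairs, scores


def degree_distribution(edges, n_bins: int | None = None):
    """Degree histogram of a (directed) edge list plus a log-log slope.

    Degrees are total (in + out).  The slope is the least-squares fit of
    log10(frequency) on log10(degree) over nonzero-count degrees; with fewer
    than 3 such degrees the slope is undefined and returned as None.
    """
    edges = list(edges)
    if not edges:
        raise ValueError("empty edge list")
    deg: dict = {}
    for u, v in edges:
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
    values, counts = np.unique(np.array(list(deg.values())), return_counts=True)
    hist = dict(zip((int(v) for v in values), (int(c) for c in counts)))
    positive = values > 0
    values, counts = values[positive], counts[positive]
    if len(values) < 3:
        return hist, None
    slope = np.polyfit(np.log10(values), np.log10(counts), 1)[0]
    return hist, float(slope)
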