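"""Assembly of the supervised link-prediction problem.

Positives (gold-standard edges) are split 8/10 train, 1/10 validation,
remainder test.  Negatives are TF-target pairs absent from the *entire* gold
standard, drawn either uniformly at a fixed ratio (balanced scheme) or, in
the hard scheme, enumerated exhaustively per TF before seeded subsampling;
either way they are split with the same fractions as the positives.

Message passing happens on a symmetrized training-positive adjacency with
self-loops; held-out edges never enter the graph.  Node features are the
genes' expression profiles across cells (optionally log1p + per-gene
z-score), optionally extended with a max-normalized degree column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import ExpressionMatrix, PriorNetwork, TFList

log = logging.getLogger(__name__)

__all__ = [
    "GeneIndex",
    "SplitConfig",
    "LabeledPairSet",
    "GraphInput",
    "align_inputs",
    "split_positives",
    "sample_negatives_balanced",
    "sample_negatives_hard",
    "split_by_fractions",
    "build_graph_input",
    "make_problem",
]


@dataclass(frozen=True)
class GeneIndex:
    index_to_id: tuple[str, ...]
    id_to_index: dict[str, int] = field(default=None, repr=False)

    def __post_init__(self):
        object.__setattr__(
            self, "id_to_index", {g.lower(): i for i, g in enumerate(self.index_to_id)}
        )

    def __len__(self) -> int:
        return len(self.index_to_id)

    def __getitem__(self, gene_id: str) -> int:
        return self.id_to_index[gene_id.lower()]


@dataclass(frozen=True)
class SplitConfig:
    train_frac: float = 0.8
    val_frac: float = 0.1
    test_frac: float = 0.1
    neg_pos_ratio: float = 1.0
    hard_negatives: bool = False
    seed: int = 0

    def __post_init__(self):
        fr = (self.train_frac, self.val_frac, self.test_frac)
        if not np.isclose(sum(fr), 1.0):
            raise ValueError("split fractions must sum to 1")
        if any(f <= 0 or f >= 1 for f in fr):
            raise ValueError("split fractions must lie in (0,1)")
        if self.neg_pos_ratio <= 0:
            raise ValueError("neg_pos_ratio must be > 0")


@dataclass(frozen=True)
class LabeledPairSet:
    """(tf_index, target_index, label) triples for one split."""

    pairs: np.ndarray  # (k, 3) int: tf, target, label in {0,1}
    split_name: str

    @property
    def tf(self):
        return self.pairs[:, 0]

    @property
    def target(self):
        return self.pairs[:, 1]

    @property
    def labels(self):
        return self.pairs[:, 2]

    def __len__(self):
        return len(self.pairs)


@dataclass(frozen=True)
class GraphInput:
    features: np.ndarray      # M x d
    adjacency: sp.csr_matrix  # symmetrized train positives + self-loops
    degree: np.ndarray | None

    @property
    def n_nodes(self) -> int:
        return self.features.shape[0]

    def dense_mask(self) -> np.ndarray:
        return self.adjacency.toarray().astype(bool)


def align_inputs(expr: ExpressionMatrix, network: PriorNetwork, tfs: TFList):
    """Case-insensitively reconcile the three inputs on the expression genes.

    Network edges or TFs naming genes absent from the expression matrix are
    dropped (node features are mandatory); counts are logged.  Returns
    (GeneIndex, positive edge index array, TF index array).
    """
    index = GeneIndex(tuple(expr.gene_ids))
    edges = []
    n_dropped = 0
    for tf, tg in network.edges:
        try:
            edges.append((index[tf], index[tg]))
        except KeyError:
            n_dropped += 1
    if n_dropped:
        log.info("dropped %d network edges with genes missing from expression", n_dropped)
    tf_idx = []
    n_missing_tf = 0
    for t in sorted(tfs.tf_ids):
        try:
            tf_idx.append(index[t])
        except KeyError:
            n_missing_tf += 1
    if n_missing_tf:
        log.info("dropped %d TFs missing from expression", n_missing_tf)
    if not edges:
        raise ValueError("no gold-standard edges remain after alignment")
    if not tf_idx:
        raise ValueError("no TFs remain after alignment")
    return index, np.array(edges, dtype=int), np.array(sorted(set(tf_idx)), dtype=int)


def _allocation(n: int, cfg: SplitConfig) -> tuple[int, int, int]:
    n_train = int(np.floor(cfg.train_frac * n))
    n_val = int(np.floor(cfg.val_frac * n))
    return n_train, n_val, n - n_train - n_val


def split_positives(edges: np.ndarray, cfg: SplitConfig):
    """Seeded shuffle then floor/floor/remainder allocation to train/val/test."""
    edges = np.asarray(edges, dtype=int)
    n = len(edges)
    if n < 3:
        raise ValueError(f"need at least 3 positive edges, got {n}")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_train, n_val, n_test = _allocation(n, cfg)
    if n >= 10 and min(n_train, n_val, n_test) == 0:
        warnings.warn("a split received zero positive edges", stacklevel=2)
    shuffled = edges[perm]
    return (
        shuffled[:n_train],
        shuffled[n_train:n_train + n_val],
        shuffled[n_train + n_val:],
    )


def _negative_pool(tf_idx: np.ndarray, n_genes: int, gold: set[tuple[int, int]],
                   restrict_tfs=None) -> list[tuple[int, int]]:
    pool = []
    tfs = tf_idx if restrict_tfs is None else restrict_tfs
    for tf in sorted(int(t) for t in tfs):
        for g in range(n_genes):
            if g == tf or (tf, g) in gold:
                continue
            pool.append((tf, g))
    return pool


def sample_negatives_balanced(positives: np.ndarray, tf_idx: np.ndarray,
                              n_genes: int, gold_edges: np.ndarray,
                              cfg: SplitConfig) -> np.ndarray:
    """Uniform seeded draw of ratio * |positives| pairs outside the gold standard."""
    gold = {(int(a), int(b)) for a, b in np.asarray(gold_edges, dtype=int)}
    pool = _negative_pool(tf_idx, n_genes, gold)
    if not pool:
        raise ValueError("negative-sampling pool is empty")
    want = int(round(cfg.neg_pos_ratio * len(positives)))
    if want > len(pool):
        warnings.warn(
            f"requested {want} negatives but pool holds {len(pool)}; taking all",
            stacklevel=2,
        )
        want = len(pool)
    rng = np.random.default_rng(cfg.seed + 1)
    chosen = rng.choice(len(pool), size=want, replace=False)
    return np.array([pool[i] for i in sorted(chosen)], dtype=int)


def sample_negatives_hard(positives: np.ndarray, tf_idx: np.ndarray,
                          n_genes: int, gold_edges: np.ndarray,
                          cfg: SplitConfig) -> np.ndarray:
    """Per-TF exhaustive candidates (all non-interacting genes), then subsample.

    Only TFs that appear among the positives contribute candidates; a TF whose
    every pairing is a known positive is skipped with a log line.
    """
    positives = np.asarray(positives, dtype=int)
    gold = {(int(a), int(b)) for a, b in np.asarray(gold_edges, dtype=int)}
    pos_tfs = sorted(set(int(t) for t in positives[:, 0]))
    pool: list[tuple[int, int]] = []
    for tf in pos_tfs:
        cands = [(tf, g) for g in range(n_genes) if g != tf and (tf, g) not in gold]
        if not cands:
            log.info("TF index %d has no negative candidates; skipped", tf)
            continue
        pool.extend(cands)
    if not pool:
        raise ValueError("hard-negative pool is empty")
    want = int(round(cfg.neg_pos_ratio * len(positives)))
    if want >= len(pool):
        return np.array(pool, dtype=int)
    rng = np.random.default_rng(cfg.seed + 2)
    chosen = rng.choice(len(pool), size=want, replace=False)
    return np.array([pool[i] for i in sorted(chosen)], dtype=int)


def split_by_fractions(pairs: np.ndarray, cfg: SplitConfig, seed_offset: int = 3):
    """Split an edge array with the same protocol as the positives."""
    pairs = np.asarray(pairs, dtype=int)
    rng = np.random.default_rng(cfg.seed + seed_offset)
    perm = rng.permutation(len(pairs))
    n_train, n_val, _ = _allocation(len(pairs), cfg)
    shuffled = pairs[perm]
    return (
        shuffled[:n_train],
        shuffled[n_train:n_train + n_val],
        shuffled[n_train + n_val:],
    )


def build_graph_input(expr: ExpressionMatrix, train_edges: np.ndarray, *,
                      log1p: bool = True, zscore: bool = True,
                      degree_feature: bool = True) -> GraphInput:
    """Adjacency (symmetrized train positives + self-loops) and node features.

    Degrees are counted on the symmetrized edge set excluding self-loops and
    max-normalized to [0, 1]; an edgeless graph yields an all-zero column.
    """
    m = len(expr.gene_ids)
    train_edges = np.asarray(train_edges, dtype=int).reshape(-1, 2)
    und = {(int(u), int(v)) for u, v in train_edges if u != v}
    und |= {(v, u) for u, v in und}
    rows = [u for u, _ in und] + list(range(m))
    cols = [v for _, v in und] + list(range(m))
    adj = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(m, m), dtype=np.float64
    )
    adj.data[:] = 1.0  # collapse any accidental duplicates

    x = expr.values.astype(float)
    if log1p:
        x = np.log1p(x)
    if zscore:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        x = (x - mu) / np.where(sd > 0, sd, 1.0)

    degree = None
    if degree_feature:
        deg = np.zeros(m)
        for u, _v in und:  # und holds both orientations: one hit per neighbor
            deg[u] += 1.0
        maxdeg = deg.max() if deg.size else 0.0
        degree = deg / maxdeg if maxdeg > 0 else deg
        x = np.hstack([x, degree[:, None]])

    return GraphInput(features=x, adjacency=adj, degree=degree)


def make_problem(expr: ExpressionMatrix, network: PriorNetwork, tfs: TFList,
                 cfg: SplitConfig, *, log1p: bool = True, zscore: bool = True,
                 degree_feature: bool = True):
    """Full pipeline: align, split, sample negatives, build the graph input.

    Returns (GeneIndex, tf_index_array, splits dict name -> LabeledPairSet,
    GraphInput).  The hard scheme is selected by ``cfg.hard_negatives``.
    """
    index, gold, tf_idx = align_inputs(expr, network, tfs)
    tr_pos, va_pos, te_pos = split_positives(gold, cfg)
    sampler = sample_negatives_hard if cfg.hard_negatives else sample_negatives_balanced
    negatives = sampler(gold, tf_idx, len(index), gold, cfg)
    tr_neg, va_neg, te_neg = split_by_fractions(negatives, cfg)

    def labelled(pos, neg, name):
        pairs = np.vstack([
            np.column_stack([pos, np.ones(len(pos), dtype=int)]) if len(pos)
            else np.empty((0, 3), dtype=int),
            np.column_stack([neg, np.zeros(len(neg), dtype=int)]) if len(neg)
            else np.empty((0, 3), dtype=int),
        ]).astype(int)
        return LabeledPairSet(pairs, name)

    splits = {
        "train": labelled(tr_pos, tr_neg, "train"),
        "val": labelled(va_pos, va_neg, "val"),
        "test": labelled(te_pos, te_neg, "test"),
    }
    graph = build_graph_input(
        expr, tr_pos, log1p=log1p, zscore=zscore, degree_feature=degree_feature
    )
    return index, tf_idx, splits, graph
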