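"""Persistent homology of the training subgraph.

The prior regulatory graph, restricted to training-split edges, is turned
into a filtered 1-skeleton: each undirected edge (i, j) receives the weight

    w_ij = scale * (1 - cos(x_i, x_j))

from the node feature vectors, and edges enter the complex in ascending
weight order.  A Union-Find sweep over this filtration yields the dimension-0
persistence pairs (component merges, born at 0, dying at the merging edge's
weight) and dimension-1 pairs (cycle-closing edges, born at their weight,
never dying).  Four graph-level statistics summarize the diagram:

* ``avg_pers0`` — mean lifetime of merged components, a multiscale measure of
  how tightly the regulatory graph is knit under expression similarity;
* ``num_cycles`` — count of independent 1-dimensional cycles (Betti-1 of the
  final graph), a proxy for feedback-loop prevalence;
* ``max_pers0`` — the longest component lifetime;
* ``norm_pers0`` — avg / (max + sigma), a scale-free connectivity index.

An edgeless (or otherwise degenerate) graph yields the fixed default vector
``(0.0, 0, 0.0, 0.0)``.

The computation is strictly inductive: only training positives may appear in
the filtration, so the descriptors carry no information about held-out edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TDAConfig",
    "Filtration",
    "PersistencePairs",
    "TDAFeatures",
    "edge_filtration",
    "persistent_homology",
    "summarize",
    "compute_tda_features",
]


@dataclass(frozen=True)
class TDAConfig:
    """Filtration settings.

    scale
        Multiplier applied to the cosine-dissimilarity weights.  1.0 leaves
        the filtration on its natural [0, 2] range; 0 collapses every weight
        to zero (kept legal for ablation parity).
    sigma
        Small stabilizer in the normalized-persistence denominator.
    """

    scale: float = 1.0
    sigma: float = 1e-8

    def __post_init__(self):
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class Filtration:
    """Canonical sorted edge filtration: u < v, weights ascending."""

    edges: np.ndarray          # (k, 2) int, upper-triangle canonical
    weights: np.ndarray        # (k,) float, non-decreasing
    n_nodes: int


@dataclass(frozen=True)
class PersistencePairs:
    dim0_deaths: np.ndarray    # births are all 0
    dim1_births: np.ndarray    # deaths are all +inf


@dataclass(frozen=True)
class TDAFeatures:
    avg_pers0: float
    num_cycles: int
    max_pers0: float
    norm_pers0: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.avg_pers0, float(self.num_cycles), self.max_pers0, self.norm_pers0]
        )


def edge_filtration(features: np.ndarray, edges, cfg: TDAConfig = TDAConfig()) -> Filtration:
    """Build the cosine-dissimilarity filtration over undirected edges.

    ``edges`` may be directed and contain duplicates/symmetric copies; they
    are canonicalized to u < v and deduplicated.  Self-edges are ignored.
    A zero-norm feature vector is assigned cosine 0 (weight ``scale``): an
    all-zero expression profile carries no similarity evidence.
    """
    features = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(features)):
        raise ValueError("node features must be finite")
    n_nodes = features.shape[0]

    canon: set[tuple[int, int]] = set()
    for u, v in edges:
        u, v = int(u), int(v)
        if u == v:
            continue
        if u > v:
            u, v = v, u
        if not (0 <= u and v < n_nodes):
            raise ValueError(f"edge ({u},{v}) outside node range [0,{n_nodes})")
        canon.add((u, v))

    if not canon:
        return Filtration(np.empty((0, 2), dtype=int), np.empty(0), n_nodes)

    e = np.array(sorted(canon), dtype=int)
    norms = np.linalg.norm(features, axis=1)
    xu, xv = features[e[:, 0]], features[e[:, 1]]
    denom = norms[e[:, 0]] * norms[e[:, 1]]
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(denom > 0, np.einsum("ij,ij->i", xu, xv) / np.where(denom > 0, denom, 1.0), 0.0)
    cos = np.clip(cos, -1.0, 1.0)
    w = cfg.scale * (1.0 - cos)

    # stable order: (w, u, v) — ties resolved lexicographically
    order = np.lexsort((e[:, 1], e[:, 0], w))
    return Filtration(e[order], w[order], n_nodes)


class _UnionFind:
    """Union by size with path compression."""

    def __init__(self, n: int):
        self.parent = np.arange(n)
        self.size = np.ones(n, dtype=int)
        self.n_components = n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        self.n_components -= 1
        return True


def persistent_homology(f: Filtration) -> PersistencePairs:
    """Single Union-Find sweep over the sorted filtration.

    A merging edge emits a dimension-0 pair (0, w); a non-merging edge closes
    a cycle and emits a dimension-1 pair (w, inf).
    """
    uf = _UnionFind(f.n_nodes)
    deaths: list[float] = []
    births: list[float] = []
    for (u, v), w in zip(f.edges, f.weights):
        if uf.union(int(u), int(v)):
            deaths.append(float(w))
        else:
            births.append(float(w))
    return PersistencePairs(np.array(deaths), np.array(births))


def summarize(p: PersistencePairs, cfg: TDAConfig = TDAConfig()) -> TDAFeatures:
    """Collapse persistence pairs into the 4-feature descriptor."""
    num_cycles = int(p.dim1_births.size)
    if p.dim0_deaths.size == 0:
        # degenerate default: nothing ever merged
        return TDAFeatures(0.0, num_cycles, 0.0, 0.0)
    pers0 = p.dim0_deaths  # births are all zero, so lifetime == death
    avg = float(pers0.mean())
    mx = float(pers0.max())
    norm = avg / (mx + cfg.sigma)
    return TDAFeatures(avg, num_cycles, mx, norm)


def compute_tda_features(features: np.ndarray, train_edges,
                         cfg: TDAConfig = TDAConfig()) -> TDAFeatures:
    """Filtration -> persistence -> summary, on training edges only."""
    f = edge_filtration(features, train_edges, cfg)
    return summarize(persistent_homology(f), cfg)
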