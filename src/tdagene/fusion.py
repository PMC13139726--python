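"""Gated topology fusion, role-specific branch MLPs, and the pair decoder.

The graph-level 4-vector of persistence features is broadcast to every gene,
standardized so its one unbounded channel (cycle count, log1p-compressed)
cannot dominate, and concatenated with the encoder embedding:
c = h || t'.  A sigmoid gate g = sigma(W_g c + b_g) modulates the
concatenation elementwise, f = g (*) c, and a width-preserving linear +
LeakyReLU projection refines the fused representation.

Two structurally identical but independently parameterized MLP branches
then specialize the fused embedding for the regulator and target roles
(3 blocks of linear -> layer-norm -> LeakyReLU -> dropout, then a LeakyReLU
projection to the output width O).  A pair (i, j) is scored by the decoder:
concatenate e_tf(i) || e_target(j), pass through a 3-layer MLP with
layer-norm and LeakyReLU between layers, and squash the scalar with a
sigmoid to obtain the regulatory probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .tda import TDAFeatures

__all__ = [
    "FusionConfig",
    "broadcast_tda",
    "GatedFusion",
    "BranchMLP",
    "PairDecoder",
    "FusionHead",
]

VARIANTS = ("full", "no_tda", "no_fusion", "no_residual", "no_branch")


@dataclass(frozen=True)
class FusionConfig:
    branch_out_dim: int = 16          # O, per-role embedding width
    slope: float = 0.4                # LeakyReLU slope throughout the head
    dropout: float = 0.1
    standardize_tda: bool = True
    # fixed per-channel divisors applied after log1p on the cycle count:
    # (avg_pers0, log1p(num_cycles), max_pers0, norm_pers0)
    tda_channel_scale: tuple = (1.0, 5.0, 2.0, 1.0)

    def __post_init__(self):
        if self.branch_out_dim < 1:
            raise ValueError("branch_out_dim must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0,1)")


def broadcast_tda(t: TDAFeatures, n_nodes: int, cfg: FusionConfig = FusionConfig(),
                  *, standardize: bool | None = None) -> np.ndarray:
    """Expand the graph-level feature vector to an (M, 4) matrix.

    With standardization on, num_cycles is log1p-compressed and every channel
    divided by its fixed scale constant; the other three channels already
    live on O(1) ranges for cosine filtrations.
    """
    vec = t.as_array().copy()
    if standardize is None:
        standardize = cfg.standardize_tda
    if standardize:
        vec[1] = np.log1p(vec[1])
        vec = vec / np.asarray(cfg.tda_channel_scale, dtype=float)
    return np.tile(vec, (n_nodes, 1))


class _Linear:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = ad.glorot_uniform(rng, in_dim, out_dim)
        self.b = ad.parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def params(self):
        return [self.W, self.b]


class _LayerNorm:
    def __init__(self, dim: int):
        self.gamma = ad.parameter(np.ones(dim))
        self.beta = ad.parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gamma, self.beta)

    def params(self):
        return [self.gamma, self.beta]


class GatedFusion:
    """c = h || t'; g = sigma(W_g c + b_g); f = g (*) c; then projection."""

    def __init__(self, embed_dim: int, cfg: FusionConfig, rng: np.random.Generator,
                 *, gate: bool = True):
        self.cfg = cfg
        self.gate_enabled = gate
        width = embed_dim + 4
        self.gate = _Linear(width, width, rng) if gate else None
        self.proj = _Linear(width, embed_dim, rng)  # width-preserving wrt h

    def params(self):
        ps = list(self.proj.params())
        if self.gate is not None:
            ps = self.gate.params() + ps
        return ps

    def fuse(self, h: Tensor, t_broadcast: np.ndarray) -> Tensor:
        c = ad.concat([h, Tensor(t_broadcast)], axis=1)
        if self.gate_enabled:
            g = ad.sigmoid(self.gate(c))
            f = g * c
        else:
            f = c  # ablation: plain concatenation, no gating
        return ad.leaky_relu(self.proj(f), self.cfg.slope)


class BranchMLP:
    """3 blocks of (linear, layer-norm, LeakyReLU, dropout) + projection to O."""

    def __init__(self, in_dim: int, cfg: FusionConfig, rng: np.random.Generator):
        self.cfg = cfg
        dims = [in_dim, max(in_dim // 2, cfg.branch_out_dim),
                max(in_dim // 4, cfg.branch_out_dim)]
        self.blocks = []
        d = in_dim
        for out_d in dims[1:] + [dims[-1]]:
            self.blocks.append((_Linear(d, out_d, rng), _LayerNorm(out_d)))
            d = out_d
        self.proj = _Linear(d, cfg.branch_out_dim, rng)

    def params(self):
        ps = []
        for lin, ln in self.blocks:
            ps += lin.params() + ln.params()
        return ps + self.proj.params()

    def __call__(self, f: Tensor, *, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        h = f
        for lin, ln in self.blocks:
            h = ad.leaky_relu(ln(lin(h)), self.cfg.slope)
            h = ad.dropout(h, self.cfg.dropout,
                           rng if rng is not None else np.random.default_rng(0), training)
        return ad.leaky_relu(self.proj(h), self.cfg.slope)


class PairDecoder:
    """3-layer MLP on e_tf(i) || e_target(j); sigmoid output probability."""

    def __init__(self, branch_out_dim: int, cfg: FusionConfig, rng: np.random.Generator):
        self.cfg = cfg
        d = 2 * branch_out_dim
        self.l1 = _Linear(d, branch_out_dim, rng)
        self.n1 = _LayerNorm(branch_out_dim)
        self.l2 = _Linear(branch_out_dim, max(branch_out_dim // 2, 2), rng)
        self.n2 = _LayerNorm(max(branch_out_dim // 2, 2))
        self.l3 = _Linear(max(branch_out_dim // 2, 2), 1, rng)

    def params(self):
        return (self.l1.params() + self.n1.params() + self.l2.params()
                + self.n2.params() + self.l3.params())

    def __call__(self, e_tf_rows: Tensor, e_target_rows: Tensor) -> Tensor:
        c = ad.concat([e_tf_rows, e_target_rows], axis=1)
        h = self.n1(ad.leaky_relu(self.l1(c), self.cfg.slope))
        h = self.n2(ad.leaky_relu(self.l2(h), self.cfg.slope))
        return ad.sigmoid(self.l3(h))


class FusionHead:
    """Everything downstream of the encoder, wired per ablation variant."""

    def __init__(self, embed_dim: int, cfg: FusionConfig, rng: np.random.Generator,
                 variant: str = "full"):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        self.cfg = cfg
        self.variant = variant
        self.fusion = None
        if variant != "no_tda":
            self.fusion = GatedFusion(embed_dim, cfg, rng, gate=(variant != "no_fusion"))
        branch_in = embed_dim
        self.tf_branch = BranchMLP(branch_in, cfg, rng)
        self.target_branch = (self.tf_branch if variant == "no_branch"
                              else BranchMLP(branch_in, cfg, rng))
        self.decoder = PairDecoder(cfg.branch_out_dim, cfg, rng)

    def params(self):
        ps = []
        if self.fusion is not None:
            ps += self.fusion.params()
        ps += self.tf_branch.params()
        if self.target_branch is not self.tf_branch:
            ps += self.target_branch.params()
        return ps + self.decoder.params()

    def embed(self, h: Tensor, t_broadcast: np.ndarray, *, training: bool = False,
              rng: np.random.Generator | None = None):
        """Per-gene (e_tf, e_target) role embeddings."""
        f = h if self.fusion is None else self.fusion.fuse(h, t_broadcast)
        e_tf = self.tf_branch(f, training=training, rng=rng)
        e_target = self.target_branch(f, training=training, rng=rng)
        return e_tf, e_target

    def decode_pairs(self, e_tf: Tensor, e_target: Tensor, pairs: np.ndarray) -> Tensor:
        pairs = np.asarray(pairs, dtype=int)
        rows_tf = ad.gather_rows(e_tf, pairs[:, 0])
        rows_tg = ad.gather_rows(e_target, pairs[:, 1])
        return self.decoder(rows_tf, rows_tg).reshape(-1)
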