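"""Multi-head graph-attention encoder with projected residual connections.

Four attention layers by default.  Each head computes the standard GAT
score e_ij = LeakyReLU(a^T [W x_i || W x_j]) for neighbors j of i (the
adjacency always contains self-loops), normalizes with a row softmax over
the neighborhood, and aggregates h_i' = sum_j alpha_ij W x_j.  Head outputs
are concatenated at every layer, so the encoder output width is
heads_rest * hidden_dim.  Each layer ends with a projected residual merge,
out = ELU(concat_heads + P(in)), where P is a learned linear map when the
widths differ and the identity otherwise; the residual can be disabled for
ablation.

The attention score is decomposed as a^T[Wx_i || Wx_j] = a_src^T Wx_i +
a_dst^T Wx_j, so the dense logit matrix is an outer sum — exact, and cheap
at the graph sizes this package targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

__all__ = ["EncoderConfig", "GATLayer", "GATEncoder", "attention_logits", "attention_weights"]


@dataclass(frozen=True)
class EncoderConfig:
    n_layers: int = 4
    heads_first: int = 4
    heads_rest: int = 4
    hidden_dim: int = 32
    attn_slope: float = 0.4
    dropout: float = 0.1
    residual: bool = True

    def __post_init__(self):
        if self.n_layers < 1 or self.heads_first < 1 or self.heads_rest < 1:
            raise ValueError("n_layers and head counts must be >= 1")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0,1)")
        if self.n_layers > 5:
            warnings.warn(
                "more than 5 attention layers tends to over-smooth sparse "
                "regulatory graphs", stacklevel=2,
            )

    @property
    def out_dim(self) -> int:
        return self.heads_rest * self.hidden_dim if self.n_layers > 1 \
            else self.heads_first * self.hidden_dim


def attention_logits(x_i: np.ndarray, x_j: np.ndarray, W: np.ndarray,
                     a: np.ndarray, slope: float) -> float:
    """Single-pair attention score e_ij = LeakyReLU(a^T [W x_i || W x_j])."""
    z = np.concatenate([W.T @ x_i, W.T @ x_j]) @ a
    return float(z if z >= 0 else slope * z)


def attention_weights(logits: np.ndarray) -> np.ndarray:
    """Softmax over a neighborhood, max-subtracted for overflow safety."""
    logits = np.asarray(logits, dtype=float)
    e = np.exp(logits - logits.max())
    return e / e.sum()


class GATLayer:
    """One multi-head attention layer over a dense adjacency mask."""

    def __init__(self, in_dim: int, n_heads: int, hidden_dim: int,
                 cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.in_dim = in_dim
        self.out_dim = n_heads * hidden_dim
        self.W = [ad.glorot_uniform(rng, in_dim, hidden_dim) for _ in range(n_heads)]
        # attention vector split into source/destination halves
        self.a_src = [ad.glorot_uniform(rng, hidden_dim, 1) for _ in range(n_heads)]
        self.a_dst = [ad.glorot_uniform(rng, hidden_dim, 1) for _ in range(n_heads)]
        if cfg.residual and in_dim != self.out_dim:
            self.P = ad.glorot_uniform(rng, in_dim, self.out_dim)
        else:
            self.P = None

    def params(self) -> list[Tensor]:
        ps = self.W + self.a_src + self.a_dst
        if self.P is not None:
            ps = ps + [self.P]
        return ps

    def forward(self, h: Tensor, mask: np.ndarray, *, training: bool,
                rng: np.random.Generator) -> Tensor:
        h_in = ad.dropout(h, self.cfg.dropout, rng, training)
        heads = []
        for W, a_s, a_d in zip(self.W, self.a_src, self.a_dst):
            z = h_in @ W                                   # (M, H)
            s_src = z @ a_s                                # (M, 1)
            s_dst = z @ a_d
            logits = ad.leaky_relu(s_src + s_dst.T, self.cfg.attn_slope)
            alpha = ad.masked_softmax(logits, mask)
            alpha = ad.dropout(alpha, self.cfg.dropout, rng, training)
            heads.append(alpha @ z)
        out = ad.concat(heads, axis=1) if len(heads) > 1 else heads[0]
        if self.cfg.residual:
            res = h if self.P is None else h @ self.P
            out = out + res
        return ad.elu(out)

    def attention_matrices(self, h: Tensor, mask: np.ndarray) -> list[np.ndarray]:
        """Eval-mode per-head attention matrices (diagnostics/tests)."""
        mats = []
        for W, a_s, a_d in zip(self.W, self.a_src, self.a_dst):
            z = h @ W
            s_src = z @ a_s
            s_dst = z @ a_d
            logits = ad.leaky_relu(s_src + s_dst.T, self.cfg.attn_slope)
            mats.append(ad.masked_softmax(logits, mask).data)
        return mats


class GATEncoder:
    """Stack of GAT layers producing per-gene embeddings."""

    def __init__(self, in_dim: int, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.layers: list[GATLayer] = []
        d = in_dim
        for li in range(cfg.n_layers):
            heads = cfg.heads_first if li == 0 else cfg.heads_rest
            layer = GATLayer(d, heads, cfg.hidden_dim, cfg, rng)
            self.layers.append(layer)
            d = layer.out_dim
        self.out_dim = d

    def params(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.params()]

    def encode(self, features: Tensor, mask: np.ndarray, *, training: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        if training and rng is None:
            raise ValueError("training mode needs an rng for dropout")
        h = features
        for li, layer in enumerate(self.layers):
            h = layer.forward(h, mask, training=training,
                              rng=rng if rng is not None else np.random.default_rng(0))
            if not np.all(np.isfinite(h.data)):
                raise FloatingPointError(f"non-finite embeddings after layer {li}")
        return h
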