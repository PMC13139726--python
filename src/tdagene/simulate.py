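"""Synthetic BEELINE-style fixtures with planted regulatory structure.

The generator emulates the three inputs the pipeline consumes: a directed
TF->target network with hub structure, an expression matrix from a linear
structural model with additive noise and zero-inflation, and the TF list.

Network: TFs form the hub layer; each target attaches to ``edges_per_node``
distinct TFs with probability proportional to (current TF out-degree + 1),
i.e. preferential attachment, which yields the right-skewed, scale-free-like
out-degree distributions typical of real regulatory networks.

Expression: cells are i.i.d.  Each TF loads on one of ``n_programs`` shared
latent programs, TF_i = |a * z_p(i) + sqrt(1-a^2) * eta_i| with a = 0.5, so
TFs are mildly correlated (same-program TF-TF correlation 0.25) but each
target's planted parents remain its dominant correlates.  A target is the
signed sum of its parents (weights +/- effect_sd, random sign) plus
Gaussian noise; the matrix is shifted to non-negative and entries are then
zeroed independently with probability ``dropout_rate`` to mimic scRNA-seq
dropout.  Everything is deterministic per seed.

This is a statistical emulation for testing link predictors, not a kinetic
model of transcription.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import ExpressionMatrix, PriorNetwork, TFList

__all__ = ["SimConfig", "simulate_grn", "simulate_expression", "write_fixture", "simulate_dataset"]


@dataclass(frozen=True)
class SimConfig:
    n_tfs: int = 10
    n_targets: int = 100
    n_cells: int = 300
    edges_per_node: int = 2
    effect_sd: float = 1.0
    noise_sd: float = 0.3
    dropout_rate: float = 0.3
    n_programs: int = 3
    program_mix: float = 0.5  # latent-program loading; TF-TF same-program corr = mix^2
    seed: int = 0

    def __post_init__(self):
        if self.n_tfs < 2:
            raise ValueError("need at least 2 TFs")
        if self.n_cells < 10:
            raise ValueError("need at least 10 cells")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0,1)")
        if self.edges_per_node < 1 or self.edges_per_node > self.n_tfs:
            raise ValueError("edges_per_node must be in [1, n_tfs]")
        if self.effect_sd <= 0 or self.noise_sd < 0:
            raise ValueError("effect_sd > 0 and noise_sd >= 0 required")


def _gene_names(cfg: SimConfig):
    tfs = [f"TF{i + 1}" for i in range(cfg.n_tfs)]
    targets = [f"G{i + 1}" for i in range(cfg.n_targets)]
    return tfs, targets


def simulate_grn(cfg: SimConfig) -> tuple[PriorNetwork, TFList]:
    """Planted TF->target network by preferential attachment over TF hubs."""
    rng = np.random.default_rng(cfg.seed)
    tfs, targets = _gene_names(cfg)
    out_degree = np.zeros(cfg.n_tfs)
    edges: list[tuple[str, str]] = []
    for tg in targets:
        weights = out_degree + 1.0
        probs = weights / weights.sum()
        parents = rng.choice(cfg.n_tfs, size=cfg.edges_per_node, replace=False, p=probs)
        for p in sorted(int(i) for i in parents):
            edges.append((tfs[p], tg))
            out_degree[p] += 1
    return PriorNetwork(edges, source_label="synthetic"), TFList(set(tfs))


def simulate_expression(network: PriorNetwork, cfg: SimConfig) -> ExpressionMatrix:
    """Linear structural model over the planted network, per the module doc."""
    rng = np.random.default_rng(cfg.seed + 10_000)
    tfs, targets = _gene_names(cfg)
    tf_pos = {t: i for i, t in enumerate(tfs)}

    programs = rng.integers(0, cfg.n_programs, size=cfg.n_tfs)
    z = rng.standard_normal((cfg.n_programs, cfg.n_cells))
    eta = rng.standard_normal((cfg.n_tfs, cfg.n_cells))
    a = cfg.program_mix
    tf_expr = np.abs(a * z[programs] + np.sqrt(1.0 - a * a) * eta)

    parents: dict[str, list[str]] = {t: [] for t in targets}
    for tf, tg in network.edges:
        parents[tg].append(tf)

    target_expr = np.zeros((cfg.n_targets, cfg.n_cells))
    for i, tg in enumerate(targets):
        acc = np.zeros(cfg.n_cells)
        for tf in parents[tg]:
            w = cfg.effect_sd * rng.choice([-1.0, 1.0])
            acc += w * tf_expr[tf_pos[tf]]
        acc += cfg.noise_sd * rng.standard_normal(cfg.n_cells)
        target_expr[i] = acc

    values = np.vstack([tf_expr, target_expr])
    # shift each gene so its minimum is 0: count-like, and dropout zeros land
    # at the low end of the gene's own range instead of far outside it
    values = values - values.min(axis=1, keepdims=True)
    if cfg.dropout_rate > 0:
        mask = rng.random(values.shape) < cfg.dropout_rate
        values = np.where(mask, 0.0, values)

    gene_ids = tfs + targets
    cell_ids = [f"C{j + 1}" for j in range(cfg.n_cells)]
    return ExpressionMatrix(gene_ids, cell_ids, values)


def simulate_dataset(cfg: SimConfig):
    """Convenience: (expression, network, tf_list) for one seed."""
    network, tf_list = simulate_grn(cfg)
    expr = simulate_expression(network, cfg)
    return expr, network, tf_list


def write_fixture(network: PriorNetwork, tfs: TFList, expr: ExpressionMatrix,
                  out_dir) -> dict[str, Path]:
    """Write ExpressionData.csv, network.csv, TF.csv in the reader dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "ExpressionData.csv",
        "network": out / "network.csv",
        "tfs": out / "TF.csv",
    }
    with open(paths["expression"], "w") as fh:
        fh.write("," + ",".join(expr.cell_ids) + "\n")
        for g, row in zip(expr.gene_ids, expr.values):
            fh.write(g + "," + ",".join(f"{v:.8g}" for v in row) + "\n")
    with open(paths["network"], "w") as fh:
        fh.write("Gene1,Gene2\n")
        for tf, tg in network.edges:
            fh.write(f"{tf},{tg}\n")
    with open(paths["tfs"], "w") as fh:
        fh.write("TF\n")
        for t in sorted(tfs.tf_ids):
            fh.write(t + "\n")
    return paths
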