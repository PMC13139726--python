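# tdagene

Supervised gene-regulatory-network (GRN) link prediction for single-cell
RNA-seq data, fusing **global persistent-homology descriptors** of the prior
regulatory graph with **local multi-head graph-attention embeddings**.

## Who this is for

Given a genes × cells expression matrix, a prior/gold-standard network of
transcription-factor (TF) → target edges, and a TF list (all in the
BEELINE-style CSV dialects), `tdagene` scores unobserved TF–target pairs for
regulatory potential. It is aimed at computational biologists benchmarking
supervised GRN inference and at anyone who wants a transparent, pure-NumPy
reference implementation of a topology-aware graph link predictor.

## The model

The prior network G(V, E) with adjacency A and expression matrix X define a
supervised link-prediction problem: known edges are positives, sampled
non-edges negatives, split 8/10 : 1/10 : 1/10 into train/validation/test.

1. **Topology branch.** The training subgraph is filtered by cosine
   dissimilarity of node feature vectors, w_ij = s · (1 − cos(x_i, x_j)),
   and a Union-Find sweep over edges in ascending weight order extracts the
   dimension-0 (component-merge) and dimension-1 (cycle) persistence pairs.
   Four graph-level statistics summarize the diagram: `avg_pers0`,
   `num_cycles`, `max_pers0`, and `norm_pers0 = avg/(max + σ)`, σ = 1e-8.
   An edgeless graph yields the degenerate default `[0.0, 0, 0.0, 0.0]`.
   Only training edges enter the filtration — the descriptors are strictly
   inductive.
2. **Attention branch.** A 4-layer multi-head GAT encoder over the
   symmetrized training adjacency (self-loops added):
   e_ij = LeakyReLU(aᵀ[Wx_i ‖ Wx_j]), α_ij = softmax over N(i),
   h_i′ = Σ_j α_ij W x_j, heads concatenated, with projected residual
   merges h′ = ELU(h′ + P(h)).
3. **Gated fusion.** c = h ‖ t′ (the 4-vector broadcast to every gene),
   g = σ(W_g c + b_g), f = g ⊙ c, then a projection MLP.
4. **Role branches + decoder.** Independent TF and target MLP branches
   (3 × [linear, layer-norm, LeakyReLU, dropout] + projection) produce
   e_tf, e_target; a 3-layer MLP on [e_tf(i) ‖ e_target(j)] with a sigmoid
   gives the regulatory probability, trained with binary cross-entropy
   (Adam, lr 5e-4, weight decay 5e-4, 100 epochs, edge batches of 256,
   best-validation-AUPRC checkpointing).

Ablation variants (`no_tda`, `no_fusion`, `no_residual`, `no_branch`) are
first-class configuration, and a synthetic-data module generates planted
scale-free TF→target networks with linear-structural-model expression
(additive noise + dropout zero-inflation) so the whole pipeline is testable
offline. The neural components run on a small, gradient-checked NumPy
reverse-mode autodiff core (`tdagene._autodiff`) — no GPU or deep-learning
framework required.

## Worked example

```python
import tdagene as tg

cfg = tg.SimConfig(n_tfs=5, n_targets=20, n_cells=60, noise_sd=0.2,
                   dropout_rate=0.1, seed=7)
expr, network, tfs = tg.simulate_dataset(cfg)
model = tg.TDAGene(expr, network, tfs,
                   split=tg.SplitConfig(seed=7),
                   training=tg.TrainConfig(seed=7, epochs=20))
res = model.fit()
print(res.summary())
```

prints

```
TDAGene regulatory link prediction
==================================================
genes: 25   TFs: 5   cells: 60
gold-standard edges: 40   splits hash: 7667e6938749
variant: full   encoder out dim: 128
persistence features: avg_pers0=0.8745  num_cycles=8  max_pers0=1.4751  norm_pers0=0.5928
epochs: 20   best epoch (val AUPRC): 5
best val AUROC 0.8750   best val AUPRC 0.8875
test AUROC 0.9375   test AUPRC 0.9500   (4 pos / 4 neg)
```

The persistence line is the topology summary of the training subgraph:
8 independent cycles (candidate feedback structures) and a mean/max
component lifetime of 0.87/1.48 on the cosine-dissimilarity scale.  The
test line is ranking quality on held-out edges versus sampled non-edges
(here a very small split — 4 positives — so treat it qualitatively).
`res.predict_all()` then scores every candidate TF–target pair and
`res.write_ranked_edges(path)` exports the ranked TSV.

The same pipeline is scriptable from the shell:

```bash
tdagene simulate --n-tfs 10 --n-targets 100 --n-cells 300 --seed 1 --out fx/
tdagene train --expr fx/ExpressionData.csv --network fx/network.csv \
              --tfs fx/TF.csv --seed 1 --out run/
tdagene evaluate --expr fx/ExpressionData.csv --network fx/network.csv \
              --tfs fx/TF.csv --checkpoint run/checkpoint.npz --split test
```

See `docs/methods.md` for the full model description, parameter meanings,
what the synthetic generator does and does not emulate, and known
limitations (including an honest account of held-out performance at
desk-scale fixture sizes).

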