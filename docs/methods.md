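# Methods

This note documents the model implemented in `tdagene`, the choices made
where the design was genuinely open, the synthetic data used to exercise it,
and the limits of what the tests demonstrate.

## Problem formulation

GRN inference is cast as supervised link prediction on a prior regulatory
graph. Nodes are genes; node features are each gene's expression profile
across cells. Known TF→target edges are positives; negatives are TF–gene
pairs absent from the *entire* gold standard (never only the current
split's positives, so no true edge is mislabeled). Positives are shuffled by
seed and allocated floor(0.8·n) / floor(0.1·n) / remainder to
train/validation/test; negatives are sampled and then split with the same
fractions. Two negative-sampling schemes are provided: **balanced** (uniform
draw at a configurable positive:negative ratio, default 1:1) and **hard**
(per TF appearing among positives, all non-interacting genes are enumerated
before seeded truncation — the imbalanced regime used with cell-type-specific
gold standards). We read "genes not positively correlated with the TF" in the
conventional sense of "no known interaction with that TF"; the alternative
reading (expression-correlation filtering of candidates) is noted but not
implemented.

Message passing uses only training positives: the adjacency is symmetrized
(directionality is recovered later by the asymmetric role branches) and
self-loops are added so every node retains its own signal. Expression is
log1p-transformed and per-gene z-scored by default (toggleable); this
stabilizes both the cosine filtration and the attention logits on
count-like data. A max-normalized node degree column is appended by default.

## Topology descriptors

The training subgraph is turned into an edge filtration: each undirected
edge (i, j), i < j, receives w_ij = scale · (1 − cos(x_i, x_j)), with edges
processed in ascending weight order (ties broken by (u, v) for
determinism — the dimension-0 multiset is tie-order invariant, so tests
compare multisets). A zero-norm feature vector is assigned cosine 0, i.e.
maximal dissimilarity among non-negative-cosine pairs: an all-zero profile
carries no similarity evidence. The cosine input is the expression block of
the node-feature matrix; the appended degree column is a structural
covariate and is excluded from the similarity computation.

A Union-Find sweep (union by size, path compression; near-linear in |E|)
classifies each edge: a merge emits a dimension-0 pair (0, w), a non-merge
closes a cycle and emits (w, ∞). Summaries:

| feature      | definition                        | interpretation |
|--------------|-----------------------------------|----------------|
| `avg_pers0`  | mean death time of dim-0 pairs    | multiscale tightness of connectivity |
| `num_cycles` | count of dim-1 pairs (= Betti-1)  | independent cycles ≈ feedback-loop prevalence |
| `max_pers0`  | max death time                    | the slowest merge |
| `norm_pers0` | avg / (max + σ), σ = 1e-8         | scale-free connectivity index in [0, 1] |

An edgeless input returns exactly (0.0, 0, 0.0, 0.0). The `scale`
multiplier (default 1.0; 0–2 is the sensible range, 0 collapses all weights
and is kept legal for ablation parity) rescales avg/max linearly and leaves
`num_cycles` and `norm_pers0` invariant up to σ — a property the tests
assert. Descriptors are computed once before training from the raw feature
matrix; an experimental `tda_dynamic` flag recomputes them from encoder
output each epoch (default off). Homology above dimension 1 is out of
scope; the graph 1-skeleton is the only complex built.

The descriptors are graph-level by design: one 4-vector summarizes the
whole training subgraph and is broadcast to all genes, injecting global
topological context without per-node topological computation.

## Encoder

Four multi-head attention layers (the tested optimum for sparse regulatory
graphs; more than five over-smooths, and the configuration warns
accordingly). Per head: e_ij = LeakyReLU(aᵀ[Wx_i ‖ Wx_j]) — computed as an
outer sum of source/destination half-scores, which is exact and cheap at
these graph sizes — masked softmax over the neighborhood (self-loops
guarantee non-emptiness), optional attention dropout, aggregation
h_i′ = Σ α_ij W x_j. Head outputs are concatenated at every layer, so the
output width is heads · hidden = 4 · 32 = 128 by default; head counts are
configurable because no canonical value exists for them. Each layer ends
with a projected residual merge h′ = ELU(h′ + P(h)); P is learned when
dimensions differ and the identity otherwise, and ELU is applied only at
the merge. Hidden width 32 and LeakyReLU slope 0.4 are the tuned defaults
(the slope is also used, deliberately, in the fusion head); dropout 0.1 sits
on attention coefficients and layer inputs. Parameters are Glorot-uniform,
seeded.

## Fusion, branches, decoder

The broadcast topology matrix t′ is standardized before fusion: the one
unbounded channel (`num_cycles`) is log1p-compressed, then all four channels
are divided by fixed constants (1, 5, 2, 1) so no channel dominates the
gate; raw mode is a flag. Fusion: c = h ‖ t′, gate g = σ(W_g c + b_g),
f = g ⊙ c, followed by a width-preserving linear + LeakyReLU projection
(the refinement step is unconstrained in principle; width-preserving is the
minimal choice).

Two structurally identical, independently parameterized branches specialize
f for the regulator and target roles: three blocks of linear → layer-norm →
LeakyReLU → dropout with halving widths, then a LeakyReLU projection to
O = 16. The decoder concatenates e_tf(i) ‖ e_target(j) — always in that
role order — and applies linear → LeakyReLU → layer-norm twice, then a
final linear to a scalar. A sigmoid converts the score to a probability:
the loss is binary cross-entropy over probabilities, which requires the
squashing even though the raw architecture description stops at the scalar.

## Training

Adam with learning rate 5e-4 and weight decay 5e-4 (the tuned values; an
initial 5e-3 also appears in the source literature and remains reachable by
config), 100 epochs, edge batches of 256. "Full-batch" refers to encoding:
every optimizer step re-encodes the entire graph — node representations are
never neighborhood-sampled — while labeled pairs are consumed in shuffled
mini-batches for decoding. Probabilities are clamped to [1e-7, 1 − 1e-7]
inside the loss. Model selection keeps the epoch with the best validation
AUPRC (the headline metric under class imbalance); `restore_best=False`
returns the final-epoch parameters instead, which is what the
overfit-capability test inspects. The history records both the
batch-averaged optimization loss and an end-of-epoch eval-mode BCE on the
full training set; the latter is the monotonicity diagnostic because it is
free of dropout jitter. All randomness flows from one integer seed through
`numpy` SeedSequence spawning; two runs with the same seed produce
bit-identical trajectories and prediction files on the same machine.

A "reparameterization technique" is mentioned in the source description of
training, but no stochastic layer exists anywhere in the architecture; it is
treated as vestigial and not implemented.

Ablation variants are composition flags sharing one architecture: `no_tda`
(skip broadcast and fusion; branches consume h), `no_fusion` (concatenate
h ‖ t′ without the gate, projection retained), `no_residual` (encoder
residual off), `no_branch` (one shared branch for both roles). The ablation
driver trains each variant on identical splits per seed — splits depend only
on the split seed, verified by hash — and emits a mean ± sd metrics table.

## Evaluation

AUROC uses the rank (Mann–Whitney) formulation with average ranks, so ties
count one half and the value is invariant under strictly monotone transforms.
AUPRC is stepwise average precision — the mean over positives of precision at
their rank, descending scores, ties broken by stable index — the stricter
convention for GRN benchmarking; note that under exact score ties it differs
from threshold-grouping implementations, which the test suite documents.
Prediction export scores all TF–gene pairs (self-pairs excluded, training
positives excluded by default) and writes a ranked TSV with deterministic
lexicographic tie-breaking. A degree-distribution diagnostic fits a
least-squares slope to log-frequency vs log-degree over nonzero bins (≥3
bins required) for power-law sanity checks of thresholded predictions.

## Synthetic data

The generator emulates the three input files with planted structure.
Network: TFs are hubs; each target attaches to `edges_per_node = 2` distinct
TFs with probability ∝ (out-degree + 1), giving right-skewed out-degrees.
Expression: cells are i.i.d.; each TF loads on one of 3 latent programs with
mixing coefficient 0.5 (same-program TF–TF correlation 0.25 — strong enough
to be realistic, weak enough that planted parents stay the top correlates),
TF profiles are folded normals; a target is the ±1-weighted sum of its
parents plus Gaussian noise (noise_sd 0.3 default), per-gene shifted to a
zero minimum (count-like, and dropout zeros then land at the low end of each
gene's own range rather than far outside it), then zero-inflated at
dropout_rate 0.3. This is a linear structural model chosen for statistical
transparency, not a kinetic simulator: it has no trajectories, pseudotime,
cell types, or mean–variance relationships of real scRNA-seq counts.

A lower-bound oracle guarantees the planted problem is solvable: absolute
Pearson correlation ranking recovers planted edges with AUROC > 0.9 on the
noiseless fixture (and 0.74–0.94 under default noise/dropout).

## What the tests do and do not show

Persistence is verified against exhaustive and randomized independent
oracles (incremental component tracking; the Euler relation
`num_cycles = |E| − |V| + C`), the metrics against an independent library,
gradients against finite differences, and the training loop for loss
decrease, memorization capacity (train AUROC ≥ 0.95 on a small instance),
determinism and checkpoint integrity.

Held-out ranking quality at desk scale is reported honestly: on the default
fixture (200 planted edges → 160 training positives over 110 genes), the
trained model's mean held-out test AUROC is ≈ 0.53 over five seeds —
indistinguishable from an untrained model — even though the fixture's signal
is strong. The dominant generalizable signal there is a pairwise
multiplicative interaction (|correlation| between profiles), and a decoder
restricted to an MLP over concatenated, independently computed per-node
embeddings approximates such interactions poorly from 160 examples (a
diagnostic with 16× more pairs still plateaus near AUROC 0.6). Real
benchmark gold standards additionally offer strong hub-degree skew and
modular co-expression — per-node properties this model class does exploit —
which the deliberately simple generator (fixed in-degree 2, sign-random
regulatory weights) does not reproduce. Passing tests therefore demonstrate
pipeline correctness, capacity, and reproducibility, not desk-scale recovery
of planted edges; performance claims on real data must be established on
real data.

## Numerical and degenerate-input policy

Softmax uses max-subtraction; sigmoid is computed in its numerically stable
split form; layer-norm uses ε = 1e-5. Zero-norm cosine inputs and edgeless
graphs follow the fixed policies above. Duplicate gene identifiers
(case-insensitive), ragged or non-numeric expression rows, unknown network
headers, empty TF lists, single-class metric inputs and non-finite scores
all raise informative errors. Genes referenced by the network or TF list but
absent from the expression matrix are dropped with a logged count (node
features are mandatory); identifier case from the expression file wins in
all outputs.

## Problem sizes used by the shipped checks

The test suite and acceptance script run entirely on generated data: the
study-condition fixture (110 genes × 300 cells, 200 edges), a small fixture
(25 genes × 60 cells), exhaustive persistence enumeration over all edge
subsets of K5 plus randomized graphs up to 30 nodes, and a 20-gene
memorization instance. These sizes keep the whole suite in the low minutes
on one CPU while exercising every code path; the implementation itself
handles graphs of a few hundred nodes comfortably (dense attention memory
grows as M², which is the practical ceiling of this NumPy implementation).
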