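# Methods

## The supra-graph

Gene and miRNA nodes share one graph. Blocks: the gene–gene interaction
(GGI) network (intra-omic), the miRNA–gene target network (inter-omics, used
symmetrically — target directionality is discarded because the adjacency
uses the block and its transpose), and miRNA–miRNA meta-path edges derived
as the off-diagonal support of `A_gene-miᵀ A_gene-mi`: two miRNAs connect
exactly when they share a target gene. The meta-path definition uses the
*same* gene as the intermediary; we do not extend it to genes adjacent in
the GGI network (a defensible alternative reading, but the stricter
definition keeps meta-path edges sparse and interpretable). Every node gets
a self-loop, so no node is isolated and attention neighborhoods are never
empty.

Graph variants for ablation: `full` (all blocks), `intra_only`
(off-diagonal blocks zeroed), `inter_only` (diagonal blocks reduced to the
identity), `gene_only`, `mirna_only`. When an omic combination provides
only one node type, `full`/`intra_only` reduce to the corresponding
single-layer graph and `inter_only` is reported as incompatible — there are
no between-layer edges to keep.

Node ordering is frozen at construction (genes in input order, then miRNAs
in input order) and recorded in every export, because the max-pool readout
windows are taken over this ordering: the readout is deliberately
order-sensitive, and reproducibility requires the order to be part of the
artifact.

## Spectral preprocessing

The adjacency is normalized to the symmetric graph Laplacian
`L = I − D^{−1/2} A D^{−1/2}` (spectrum in [0, 2]) and rescaled to
`L̃ = 2L/λmax − I` (spectrum in [−1, 1]), the domain of Chebyshev
polynomials. An alternative normalization `I + D^{−1/2} A D^{1/2}` is
selectable via `laplacian_form="as_printed"`; it is not symmetric-normalized
and breaks the spectral bound, so the standard form is the default. λmax is
computed by a sparse Lanczos solve with a dense fallback; a degenerate
λmax ≤ 1e−12 (single self-looped node) falls back to λmax = 2, the
normalized-Laplacian upper bound.

## The network

* **Dimension increase** (module 1): gene attributes (mRNA, CNV) ∈ ℝ² and
  miRNA attributes ∈ ℝ¹ are lifted by two parallel affine layers to a
  common width **F = 8** (an artifact default — wide enough to separate the
  planted signal, small enough to train in seconds).
* **GNN** (module 2): two layers.
  * *Chebyshev (GCN)*: `y = Σ_{k<K} T_k(L̃) X B_k` with the recurrence
    `T_0 X = X`, `T_1 X = L̃X`, `T_k X = 2L̃(T_{k−1}X) − T_{k−2}X`; K = 5.
    The polynomial is applied through the recurrence on feature matrices,
    never materializing `T_k(L̃)`. The channel-mixing matrices `B_k`
    generalize scalar coefficients β_k (recoverable as the 1×1 case). ReLU
    between layers.
  * *Attention (GAT)*: 8 heads; per head,
    `α_ij = softmax_{j∈NB(i)} LeakyReLU(aᵀ[Wx_i ‖ Wx_j])` (slope 0.2, the
    GAT convention) masked to first-order neighborhoods, and
    `y_i = σ(Σ_j α_ij W x_j)` with ELU. Heads are concatenated on layer 1
    and averaged on layer 2 (the usual multi-head convention; only the head
    count is prescribed). The production path evaluates all heads in one
    batched fused pass with a hand-written softmax backward; a test asserts
    exact equality with the per-head reference implementation.
* **Readout**: non-overlapping max-pool windows of p = 8 nodes over the
  frozen ordering (final partial window pooled as-is; no graph coarsening),
  flattened, then one linear layer to a 64-d local representation θ_local.
* **Decoder** (module 3): 64 → 64 (ReLU) → 2N+M, reconstructing the
  flattened attribute vector (gene pairs row-major, then miRNA scalars).
  The decoder reads θ_local by default; `decoder_input="x_prime"`
  reconstructs from the lifted attributes instead, since both readings of
  the architecture are defensible.
* **Parallel branch** (module 4): flatten(X′) → 64 (ReLU) → 64 = θ_global,
  a shallow network that sees the data without the graph and captures
  global structure the localized GNN filters may miss.
* **Classifier**: softmax on `[θ_local ‖ θ_global]` (θ_local alone when the
  parallel branch is ablated).

Hidden widths of the decoder and parallel branch (64) are artifact
defaults; all are configurable. No dropout or batch-norm by default.

## Loss and training

`L = λ₁ L_ent + λ₂ L_recon + λ₃ L_reg` with defaults λ = (1.0, 0.1, 1e−4)
(artifact defaults, configurable). `L_ent` is the mean negative log
probability of the true class (probabilities clamped at 1e−12). `L_recon`
is the squared error summed over samples and elements; a `mean` reduction
is available for scale stability. `L_reg` is the sum of squares of every
learnable scalar. Linearity in each λ and agreement of analytic gradients
with central differences (1e−4 relative) are asserted in the test suite.

Optimization is minibatch Adam (batch 64 by default) with learning rate
1e−3 for GCN and 5e−4 for GAT — the attention model prefers the smaller
step. The parameters with the best validation accuracy over the run are
kept. Divergence (non-finite loss) aborts with the loss breakdown in the
diagnostic. Everything is deterministic given the config seed: parameter
initialization (Glorot uniform), minibatch shuffling, and splits all derive
from explicit seeds, and repeated runs produce byte-identical metrics.

The whole model runs on a small reverse-mode autodiff engine over dense
float64 NumPy arrays (`supragnn.autodiff`). At the package's graph sizes
(hundreds of nodes) dense tensors are faster and far simpler than sparse
ones; gradient correctness is property-tested against central differences
op by op.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, not
TCGA marginals. An Erdős–Rényi GGI network (edge probability 0.08) and a
random bipartite target network (0.10) connect the default 60 genes and 20
miRNAs — densities chosen so the default graph has a giant component and
miRNAs typically share targets, giving a non-trivial meta-path block. Each
of the 4 subtypes owns a disjoint module of 8 genes grown from a seed gene
through GGI neighbors (breadth-first, padded with random unused genes), so
the planted signal is aligned with the graph — the property the GNN is
supposed to exploit. For a sample of class c: module-gene expression is
shifted by `effect_size` (default 3) over N(0, 1) noise; CNV is
`0.5 × (clean expression signal)` plus matched independent noise,
discretized to integer dosage in {−2..2} — correlated with but
complementary to expression, as in real tumors; miRNAs targeting module
genes are shifted by −effect/2, the repressor direction, which routes class
signal through the inter-omics edges and makes the inter-only graph
ablation meaningful. Class labels are drawn from configurable proportions
(uniform by default). All randomness flows from one seed; equal specs
regenerate byte-identical files.

What passing tests on this cohort do **not** show: robustness to batch
effects, to heavy-tailed expression marginals, to class imbalance of the
27-subtype kind, or to misannotated knowledge graphs. The generator plants
a clean, graph-aligned signal; results on it validate the machinery, not
clinical performance.

## Preprocessing

Samples are split 80/10/10 (train/validation/test), stratified, with exact
global sizes by largest-remainder rounding and at least one test sample per
class whenever the test split is large enough. Normalization is per-feature
z-scoring within each omic, with statistics estimated on the training split
only (leakage-free; `normalize_scope="all"` mimics whole-cohort scaling).
Feature selection keeps the top-variance genes by mRNA variance — computed
on raw values, because z-scoring flattens every per-feature variance to 1
and would make the ranking degenerate (`select_on="normalized"` is exposed
for the other ordering) — and applies the same gene set to CNV so both gene
channels stay aligned; miRNAs are selected independently. Ties break by
input order. Variance is the population variance.

## Evaluation

Metrics come from the argmax confusion matrix: accuracy, precision, recall
and F1, macro and weighted. Summary rows use **weighted** F1 as the primary
F1. Results aggregate over 5 trials; each trial re-seeds initialization
*and* the split by default (`vary_split=False` restricts trials to
re-initialization only). The ablation grid runs every preset over shared
splits and emits one row per preset; incompatible presets are recorded as
skipped with the reason.

## Problem sizes used by the tests and acceptance script

Single CPU, a few minutes end to end: the standard cohort (60 genes, 20
miRNAs, 300 samples) with 100 training epochs for GCN and 50 for GAT
(both presets plateau well before these budgets on the planted signal);
the effect-size sweep {0, 1, 3} uses the GCN preset over 3 seeds; the
ablation grid runs 1 trial per preset at 30 epochs; the gradient-flow
(overfit) check uses a 16-sample, 2-class toy on a 16-node graph with
learning rate 1e−2 and up to 500 epochs.

## Known limitations

* Dense adjacency and Laplacian: fine to a few thousand nodes, not beyond.
* The GAT path materializes per-head attention over all node pairs;
  memory grows as batch × heads × nodes², which is why training batches.
* Meta-paths use shared-target co-membership only.
* No batch-effect correction, imputation, or identifier-namespace mapping;
  inputs are assumed clean and pre-mapped.
* Subtype discovery (unsupervised) is out of scope; the model is a
  classifier.
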