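"""The four-module supra-graph network.

Module 1 — two parallel linear dimension-increase layers lift gene (2-d) and
miRNA (1-d) node attributes to a common width F. Module 2 — two graph
neural network layers on the supra-graph: either Chebyshev spectral
convolutions (ChebNet, order K) on the rescaled Laplacian, or multi-head
graph attention (GAT) on the adjacency. A max-pool over the frozen node
ordering plus one fully connected layer reads the node features out into a
fixed-length local representation theta_local. Module 3 — a two-layer
decoder reconstructs the flattened input node attributes from theta_local.
Module 4 — a shallow two-layer parallel network maps the lifted attributes
directly to a global representation theta_global. The classifier is a
softmax layer on the concatenation of the two representations.

All forward operations are written against the autodiff :class:`Tensor`, so
the same code path serves training and inference.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .features import OMIC_COMBOS, NodeAttributeSet
from .graph import GRAPH_VARIANTS, SpectralGraph, SupraAdjacency

_NEG_BIG = -1e9  # masked-out attention score


class ModelError(ValueError):
    """Raised on invalid model configuration or shape mismatches."""


@dataclass
class ModelConfig:
    """Every architectural and training switch of the framework.

    Defaults follow the framework conventions: Chebyshev order K=5, 8
    attention heads, pooling window 8, 64-dimensional representations.
    Hidden widths (F, decoder/parallel hidden) are artifact defaults.
    """

    F: int = 8                       # dimension-increase width
    gnn_type: str = "GCN"            # {GCN, GAT}
    K: int = 5                       # Chebyshev order
    heads: int = 8                   # attention heads
    pool_p: int = 8                  # max-pool window over nodes
    repr_dim: int = 64               # readout / representation length
    include_decoder: bool = True
    include_parallel: bool = True
    graph_variant: str = "full"
    omic_combo: str = "mRNA+CNV+miRNA"
    n_classes: int = 2
    learning_rate: float | None = None  # default 1e-3 (GCN) / 5e-4 (GAT)
    epochs: int = 200
    seed: int = 0
    lambda1: float = 1.0             # cross-entropy weight
    lambda2: float = 0.1             # reconstruction weight
    lambda3: float = 1e-4            # parameter-norm weight
    laplacian_form: str = "standard"   # {standard, as_printed}
    leaky_slope: float = 0.2         # attention LeakyReLU slope
    decoder_hidden: int = 64
    parallel_hidden: int = 64
    recon_reduction: str = "sum"     # {sum, mean}
    decoder_input: str = "theta_local"  # {theta_local, x_prime}
    batch_size: int = 64             # 0 = full-batch training

    def __post_init__(self):
        if self.gnn_type not in ("GCN", "GAT"):
            raise ModelError(f"unknown gnn_type {self.gnn_type!r}")
        if self.K < 1:
            raise ModelError("K must be >= 1")
        if self.heads < 1:
            raise ModelError("heads must be >= 1")
        if self.pool_p < 1:
            raise ModelError("pool_p must be >= 1")
        if self.repr_dim < 1:
            raise ModelError("repr_dim must be >= 1")
        if self.n_classes < 2:
            raise ModelError("n_classes must be >= 2")
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ModelError("loss weights must be non-negative")
        if self.graph_variant not in GRAPH_VARIANTS:
            raise ModelError(f"unknown graph variant {self.graph_variant!r}")
        if self.omic_combo not in OMIC_COMBOS:
            raise ModelError(f"unknown omic combination {self.omic_combo!r}")

    @property
    def lambdas(self) -> tuple[float, float, float]:
        return (self.lambda1, self.lambda2, self.lambda3)

    @property
    def lr(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 1e-3 if self.gnn_type == "GCN" else 5e-4


@dataclass
class SampleRepresentation:
    """Local (GNN path) and global (parallel branch) per-sample vectors."""

    theta_local: np.ndarray
    theta_global: np.ndarray  # all-zero sentinel when the branch is disabled


@dataclass
class ForwardResult:
    probabilities: Tensor
    x_hat: Tensor | None
    theta_local: Tensor
    theta_global: Tensor | None

    def representation(self) -> SampleRepresentation:
        tg = (self.theta_global.data if self.theta_global is not None
              else np.zeros_like(self.theta_local.data))
        return SampleRepresentation(self.theta_local.data.copy(), tg.copy())


# -- functional building blocks ----------------------------------------------


def dim_increase(gene_attrs, mirna_attrs, params: dict) -> Tensor:
    """Lift 2-d gene and 1-d miRNA attributes to shared width F.

    Returns (S, N+M, F) in the frozen node order (genes first).
    """
    parts = []
    gene_attrs = Tensor.as_tensor(gene_attrs)
    mirna_attrs = Tensor.as_tensor(mirna_attrs)
    if gene_attrs.shape[-1] != 2:
        raise ModelError("gene attributes must be 2-dimensional per node")
    if mirna_attrs.shape[-1] != 1:
        raise ModelError("miRNA attributes must be scalar per node")
    if gene_attrs.shape[1] > 0:
        parts.append(gene_attrs @ params["gene_w"] + params["gene_b"])
    if mirna_attrs.shape[1] > 0:
        parts.append(mirna_attrs @ params["mirna_w"] + params["mirna_b"])
    if not parts:
        raise ModelError("no nodes to embed")
    return parts[0] if len(parts) == 1 else concat(parts, axis=1)


def cheb_conv(x: Tensor, l_tilde: np.ndarray, coeffs: list[Tensor],
              bias: Tensor | None = None) -> Tensor:
    """Chebyshev spectral convolution Y = Σ_k T_k(L̃) X B_k.

    The polynomial acts through the recurrence T_0 X = X, T_1 X = L̃ X,
    T_k X = 2 L̃ (T_{k-1} X) − T_{k-2} X, never materializing T_k(L̃); B_k
    mix channels (scalar β_k is the 1×1 special case).
    """
    if len(coeffs) < 1:
        raise ModelError("K must be >= 1")
    x = Tensor.as_tensor(x)
    lt = Tensor(np.asarray(l_tilde, dtype=np.float64))
    t_prev2 = x
    out = t_prev2 @ coeffs[0]
    if len(coeffs) > 1:
        t_prev1 = lt @ x
        out = out + t_prev1 @ coeffs[1]
        for k in range(2, len(coeffs)):
            t_k = 2.0 * (lt @ t_prev1) - t_prev2
            out = out + t_k @ coeffs[k]
            t_prev2, t_prev1 = t_prev1, t_k
    if bias is not None:
        out = out + bias
    return out


def gat_attention(x: Tensor, adjacency: np.ndarray, w: Tensor, a: Tensor,
                  slope: float = 0.2) -> Tensor:
    """Masked attention matrix alpha, supported on the graph neighborhoods.

    alpha[i, j] = softmax_{j ∈ NB(i)} LeakyReLU(aᵀ [W x_i ‖ W x_j]); rows
    sum to 1 over NB(i) (never empty: every node has a self-loop) and are
    exactly zero elsewhere.
    """
    x = Tensor.as_tensor(x)
    adj = np.asarray(adjacency, dtype=np.float64)
    mask = (adj > 0).astype(np.float64)
    h = x @ w.T  # (S, n, F')
    f_out = h.shape[-1]
    if a.shape[0] != 2 * f_out:
        raise ModelError("attention vector length must be 2·F'")
    a_col = a.reshape(2 * f_out, 1)
    s_self = h @ a_col[:f_out]      # (S, n, 1): aᵀ_left W x_i
    s_neigh = h @ a_col[f_out:]     # (S, n, 1): aᵀ_right W x_j
    scores = (s_self + s_neigh.swapaxes(-2, -1)).leaky_relu(slope)
    masked = scores * Tensor(mask) + Tensor(_NEG_BIG * (1.0 - mask))
    shift = Tensor(masked.data.max(axis=-1, keepdims=True))  # constant
    z = (masked - shift).exp() * Tensor(mask)
    return z / z.sum(axis=-1, keepdims=True)


def _masked_attention(h: Tensor, a: Tensor, mask: np.ndarray,
                      slope: float) -> Tensor:
    """Fused masked-softmax attention: (S,H,n,F') features → (S,H,n,n) alpha.

    Single tape node with a hand-written backward (softmax Jacobian +
    LeakyReLU factor); numerically identical to the composed
    :func:`gat_attention` but avoids materializing the intermediate score
    tensors on the tape.
    """
    f_out = h.shape[-1]
    a1 = a.data[:, :f_out, :]                         # (H, F', 1)
    a2 = a.data[:, f_out:, :]
    s_self = h.data @ a1                              # (S, H, n, 1)
    s_neigh = np.swapaxes(h.data @ a2, -1, -2)        # (S, H, 1, n)
    e = s_self + s_neigh
    factor = np.where(e > 0, 1.0, slope)
    e *= factor
    e = np.where(mask > 0, e, _NEG_BIG)
    e -= e.max(axis=-1, keepdims=True)
    z = np.exp(e)
    z *= mask
    alpha = z / z.sum(axis=-1, keepdims=True)

    def bwd(g, h=h, a=a, alpha=alpha, factor=factor, a1=a1, a2=a2):
        ge = alpha * (g - (g * alpha).sum(axis=-1, keepdims=True))
        ge *= factor
        gs_self = ge.sum(axis=-1, keepdims=True)                    # (S,H,n,1)
        gs_neigh = np.swapaxes(ge.sum(axis=-2, keepdims=True), -1, -2)
        if h.requires_grad:
            h._accum(gs_self @ np.swapaxes(a1, -1, -2)
                     + gs_neigh @ np.swapaxes(a2, -1, -2), own=True)
        if a.requires_grad:
            ht = np.swapaxes(h.data, -1, -2)
            ga1 = (ht @ gs_self).sum(axis=0)
            ga2 = (ht @ gs_neigh).sum(axis=0)
            a._accum(np.concatenate([ga1, ga2], axis=1), own=True)

    return Tensor._make(alpha, (h, a), bwd)


def gat_layer(x: Tensor, adjacency: np.ndarray, head_params: list[dict],
              slope: float = 0.2, agg: str = "concat",
              activation: str = "elu") -> Tensor:
    """One multi-head attention layer.

    Heads are concatenated on hidden layers and averaged on the final layer
    (the usual multi-head convention); the nonlinearity defaults to ELU.
    All heads are evaluated in one batched pass (head axis); the result is
    identical to looping :func:`gat_attention` head by head.
    """
    x = Tensor.as_tensor(x)
    n_heads = len(head_params)
    if n_heads < 1:
        raise ModelError("at least one attention head is required")
    f_out, f_in = head_params[0]["w"].shape
    w_all = concat([hp["w"].reshape(1, f_out, f_in) for hp in head_params],
                   axis=0)                                  # (H, F', F)
    a_all = concat([hp["a"].reshape(1, 2 * f_out, 1) for hp in head_params],
                   axis=0)                                  # (H, 2F', 1)
    adj = np.asarray(adjacency, dtype=np.float64)
    mask = (adj > 0).astype(np.float64)

    s, n, _ = x.shape
    h = x.reshape(s, 1, n, f_in) @ w_all.swapaxes(-1, -2)   # (S, H, n, F')
    alpha = _masked_attention(h, a_all, mask, slope)
    y = alpha @ h                                           # (S, H, n, F')

    if agg == "concat":
        y = y.swapaxes(1, 2).reshape(s, n, n_heads * f_out)
    elif agg == "average":
        y = y.mean(axis=1)
    else:
        raise ModelError(f"unknown head aggregation {agg!r}")
    if activation == "elu":
        y = y.elu()
    elif activation == "relu":
        y = y.relu()
    elif activation != "none":
        raise ModelError(f"unknown activation {activation!r}")
    return y


def graph_readout(y: Tensor, pool_p: int, w: Tensor, b: Tensor) -> Tensor:
    """Windowed max-pool over the frozen node ordering, then one FC layer.

    Non-overlapping windows of ``pool_p`` nodes (final partial window
    allowed) are max-pooled per channel; the pooled map is flattened and
    linearly transformed to the representation length.
    """
    if pool_p < 1:
        raise ModelError("pool_p must be >= 1")
    y = Tensor.as_tensor(y)
    s, n, c = y.shape
    n_windows = math.ceil(n / pool_p)
    pad = n_windows * pool_p - n
    if pad:
        y = concat([y, Tensor(np.full((s, pad, c), -np.inf))], axis=1)
    pooled = y.reshape(s, n_windows, pool_p, c).max(axis=2)  # (S, nw, C)
    return pooled.reshape(s, n_windows * c) @ w.T + b


def parallel_branch(x_prime: Tensor, params: dict) -> Tensor:
    """Shallow two-layer network on the flattened lifted attributes."""
    x = Tensor.as_tensor(x_prime)
    s = x.shape[0]
    flat = x.reshape(s, -1) if x.ndim == 3 else x
    h = (flat @ params["w1"].T + params["b1"]).relu()
    return h @ params["w2"].T + params["b2"]


def decode(theta: Tensor, params: dict) -> Tensor:
    """Two-layer decoder from a representation back to flattened attributes."""
    t = Tensor.as_tensor(theta)
    if t.ndim == 3:
        t = t.reshape(t.shape[0], -1)
    h = (t @ params["w1"].T + params["b1"]).relu()
    return h @ params["w2"].T + params["b2"]


def softmax(logits: Tensor) -> Tensor:
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))
    z = (logits - shift).exp()
    return z / z.sum(axis=-1, keepdims=True)


def classify(theta_local: Tensor | None, theta_global: Tensor | None,
             w: Tensor, b: Tensor) -> Tensor:
    """Softmax classifier on the concatenated representations."""
    if theta_local is None and theta_global is None:
        raise ModelError("at least one representation is required")
    reps = [t for t in (theta_local, theta_global) if t is not None]
    x = reps[0] if len(reps) == 1 else concat(reps, axis=-1)
    return softmax(x @ w.T + b)


# -- the assembled model ------------------------------------------------------


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = shape[-1] if len(shape) > 1 else shape[0]
    fan_out = shape[0]
    lim = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class SupraGNN:
    """The full network for a fixed graph size and omic combination.

    Parameters are initialized deterministically from ``config.seed``;
    identical configs and inputs give bit-identical forward outputs.
    """

    def __init__(self, config: ModelConfig, n_genes: int, n_mirnas: int):
        self.config = config
        self.n_genes = int(n_genes)
        self.n_mirnas = int(n_mirnas)
        self.n_nodes = self.n_genes + self.n_mirnas
        self.flat_len = 2 * self.n_genes + self.n_mirnas
        if self.n_nodes < 1:
            raise ModelError("graph must contain at least one node")
        self.params: dict = {}
        self._init_params(np.random.default_rng(config.seed))

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        f = cfg.F
        p: dict = {}
        p["dim"] = {
            "gene_w": Tensor(_glorot(rng, (2, f)), requires_grad=True),
            "gene_b": Tensor(np.zeros(f), requires_grad=True),
            "mirna_w": Tensor(_glorot(rng, (1, f)), requires_grad=True),
            "mirna_b": Tensor(np.zeros(f), requires_grad=True),
        }
        if cfg.gnn_type == "GCN":
            p["gnn1"] = {
                "coeffs": [Tensor(_glorot(rng, (f, f)), requires_grad=True)
                           for _ in range(cfg.K)],
                "bias": Tensor(np.zeros(f), requires_grad=True),
            }
            p["gnn2"] = {
                "coeffs": [Tensor(_glorot(rng, (f, f)), requires_grad=True)
                           for _ in range(cfg.K)],
                "bias": Tensor(np.zeros(f), requires_grad=True),
            }
            self.channels = f
        else:
            p["gnn1"] = {"heads": [
                {"w": Tensor(_glorot(rng, (f, f)), requires_grad=True),
                 "a": Tensor(_glorot(rng, (2 * f, 1)).ravel(), requires_grad=True)}
                for _ in range(cfg.heads)
            ]}
            p["gnn2"] = {"heads": [
                {"w": Tensor(_glorot(rng, (f, cfg.heads * f)), requires_grad=True),
                 "a": Tensor(_glorot(rng, (2 * f, 1)).ravel(), requires_grad=True)}
                for _ in range(cfg.heads)
            ]}
            self.channels = f
        n_windows = math.ceil(self.n_nodes / cfg.pool_p)
        p["readout"] = {
            "w": Tensor(_glorot(rng, (cfg.repr_dim, n_windows * self.channels)),
                        requires_grad=True),
            "b": Tensor(np.zeros(cfg.repr_dim), requires_grad=True),
        }
        if cfg.include_parallel:
            p["parallel"] = {
                "w1": Tensor(_glorot(rng, (cfg.parallel_hidden, self.n_nodes * f)),
                             requires_grad=True),
                "b1": Tensor(np.zeros(cfg.parallel_hidden), requires_grad=True),
                "w2": Tensor(_glorot(rng, (cfg.repr_dim, cfg.parallel_hidden)),
                             requires_grad=True),
                "b2": Tensor(np.zeros(cfg.repr_dim), requires_grad=True),
            }
        if cfg.include_decoder:
            dec_in = (cfg.repr_dim if cfg.decoder_input == "theta_local"
                      else self.n_nodes * f)
            p["decoder"] = {
                "w1": Tensor(_glorot(rng, (cfg.decoder_hidden, dec_in)),
                             requires_grad=True),
                "b1": Tensor(np.zeros(cfg.decoder_hidden), requires_grad=True),
                "w2": Tensor(_glorot(rng, (self.flat_len, cfg.decoder_hidden)),
                             requires_grad=True),
                "b2": Tensor(np.zeros(self.flat_len), requires_grad=True),
            }
        clf_in = cfg.repr_dim * (2 if cfg.include_parallel else 1)
        p["classifier"] = {
            "w": Tensor(_glorot(rng, (cfg.n_classes, clf_in)), requires_grad=True),
            "b": Tensor(np.zeros(cfg.n_classes), requires_grad=True),
        }
        self.params = p

    # -- parameter bookkeeping ------------------------------------------------

    def _named_parameters(self) -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []

        def walk(prefix, node):
            if isinstance(node, Tensor):
                out.append((prefix, node))
            elif isinstance(node, dict):
                for k in sorted(node):
                    walk(f"{prefix}.{k}" if prefix else k, node[k])
            elif isinstance(node, list):
                for i, v in enumerate(node):
                    walk(f"{prefix}[{i}]", v)

        walk("", self.params)
        return out

    def parameters(self) -> list[Tensor]:
        """All learnable tensors (W_all), in a deterministic order."""
        return [t for _, t in self._named_parameters()]

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.parameters())

    # -- forward --------------------------------------------------------------

    def _resolve_graph(self, graph):
        cfg = self.config
        if cfg.gnn_type == "GCN":
            if not isinstance(graph, SpectralGraph):
                raise ModelError("GCN forward requires a SpectralGraph (L̃)")
            if graph.laplacian.shape[0] != self.n_nodes:
                raise ModelError("graph size does not match model")
            return graph.laplacian_rescaled
        if isinstance(graph, SpectralGraph):
            graph = graph.adjacency
        if not isinstance(graph, SupraAdjacency):
            raise ModelError("GAT forward requires a SupraAdjacency")
        if graph.n_nodes != self.n_nodes:
            raise ModelError("graph size does not match model")
        return graph.matrix

    def forward(self, attrs: NodeAttributeSet | tuple, graph) -> ForwardResult:
        """Full forward pass over a batch of samples."""
        cfg = self.config
        if isinstance(attrs, NodeAttributeSet):
            gene_attrs, mirna_attrs = attrs.gene_attrs, attrs.mirna_attrs
        else:
            gene_attrs, mirna_attrs = attrs
        if gene_attrs.shape[1] != self.n_genes or mirna_attrs.shape[1] != self.n_mirnas:
            raise ModelError("attribute node counts do not match model")
        op = self._resolve_graph(graph)

        x_prime = dim_increase(gene_attrs, mirna_attrs, self.params["dim"])
        if cfg.gnn_type == "GCN":
            y = cheb_conv(x_prime, op, self.params["gnn1"]["coeffs"],
                          self.params["gnn1"]["bias"]).relu()
            y = cheb_conv(y, op, self.params["gnn2"]["coeffs"],
                          self.params["gnn2"]["bias"]).relu()
        else:
            y = gat_layer(x_prime, op, self.params["gnn1"]["heads"],
                          slope=cfg.leaky_slope, agg="concat", activation="elu")
            y = gat_layer(y, op, self.params["gnn2"]["heads"],
                          slope=cfg.leaky_slope, agg="average", activation="elu")
        theta_local = graph_readout(y, cfg.pool_p, self.params["readout"]["w"],
                                    self.params["readout"]["b"])

        theta_global = None
        if cfg.include_parallel:
            theta_global = parallel_branch(x_prime, self.params["parallel"])

        x_hat = None
        if cfg.include_decoder:
            dec_src = (theta_local if cfg.decoder_input == "theta_local"
                       else x_prime)
            x_hat = decode(dec_src, self.params["decoder"])

        probs = classify(theta_local, theta_global,
                         self.params["classifier"]["w"],
                         self.params["classifier"]["b"])
        return ForwardResult(probabilities=probs, x_hat=x_hat,
                             theta_local=theta_local, theta_global=theta_global)

    # -- checkpointing --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize parameters (.npz) plus a JSON config sidecar."""
        path = Path(path)
        arrays = {name: t.data for name, t in self._named_parameters()}
        np.savez(path, **arrays)
        sidecar = {"config": asdict(self.config), "n_genes": self.n_genes,
                   "n_mirnas": self.n_mirnas}
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "SupraGNN":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            meta = json.load(fh)
        cfg = ModelConfig(**meta["config"])
        model = cls(cfg, meta["n_genes"], meta["n_mirnas"])
        npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
        with np.load(npz) as data:
            for name, t in model._named_parameters():
                t.data = data[name].astype(np.float64)
        return model

    def state_copy(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self._named_parameters()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for name, t in self._named_parameters():
            t.data = state[name].copy()


def expected_parameter_count(config: ModelConfig, n_genes: int,
                             n_mirnas: int) -> int:
    """Closed-form learnable-scalar count for a config and graph size.

    Used as an invariant: the count grows linearly in F and in N+M.
    """
    cfg = config
    f = cfg.F
    n_nodes = n_genes + n_mirnas
    flat_len = 2 * n_genes + n_mirnas
    total = (2 * f + f) + (1 * f + f)  # dimension-increase layers
    if cfg.gnn_type == "GCN":
        total += 2 * (cfg.K * f * f + f)
    else:
        total += cfg.heads * (f * f + 2 * f)              # layer 1
        total += cfg.heads * (f * cfg.heads * f + 2 * f)  # layer 2
    n_windows = math.ceil(n_nodes / cfg.pool_p)
    total += cfg.repr_dim * n_windows * f + cfg.repr_dim
    if cfg.include_parallel:
        total += (cfg.parallel_hidden * n_nodes * f + cfg.parallel_hidden
                  + cfg.repr_dim * cfg.parallel_hidden + cfg.repr_dim)
    if cfg.include_decoder:
        dec_in = cfg.repr_dim if cfg.decoder_input == "theta_local" else n_nodes * f
        total += (cfg.decoder_hidden * dec_in + cfg.decoder_hidden
                  + flat_len * cfg.decoder_hidden + flat_len)
    clf_in = cfg.repr_dim * (2 if cfg.include_parallel else 1)
    total += cfg.n_classes * clf_in + cfg.n_classes
    return total
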