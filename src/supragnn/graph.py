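"""Heterogeneous supra-graph construction.

Gene and miRNA nodes are embedded in a single block adjacency matrix: the
gene-gene interaction (GGI) network occupies the top-left block, the
miRNA-gene target network the off-diagonal blocks, and derived miRNA-miRNA
meta-path edges (two miRNAs sharing a target gene) the bottom-right block.
Every node carries a self-loop. Four ablation variants of the graph are
supported alongside the full supra-graph:

``full``
    all three blocks;
``intra_only``
    within-layer edges only (GGI + meta-paths, off-diagonal blocks zeroed);
``inter_only``
    between-layer edges only (target network, diagonal blocks reduced to
    the identity);
``gene_only`` / ``mirna_only``
    the single-layer graph of one node type.

The adjacency is normalized to a symmetric graph Laplacian and rescaled to
the spectral interval [-1, 1] for Chebyshev convolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

GRAPH_VARIANTS = ("full", "intra_only", "inter_only", "gene_only", "mirna_only")

EDGE_CLASS_GENE_GENE = "gene-gene"
EDGE_CLASS_GENE_MIRNA = "gene-miRNA"


class GraphValidationError(ValueError):
    """Raised when edge lists or blocks fail validation."""


@dataclass(frozen=True)
class NodeUniverse:
    """The frozen node ordering of the supra-graph: genes first, then miRNAs.

    The ordering matters downstream — max-pool readout windows are taken
    over this ordering — so it is fixed at construction and preserved in all
    exports.
    """

    gene_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "mirna_ids", tuple(self.mirna_ids))
        all_ids = self.gene_ids + self.mirna_ids
        if len(set(all_ids)) != len(all_ids):
            dupes = sorted({x for x in all_ids if all_ids.count(x) > 1})
            raise GraphValidationError(f"duplicate node identifiers: {dupes}")
        if len(all_ids) < 1:
            raise GraphValidationError("universe must contain at least one node")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_genes + self.n_mirnas

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def mirna_index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.mirna_ids)}


@dataclass(frozen=True)
class EdgeList:
    """An undirected, deduplicated edge list of one edge class.

    miRNA-gene target edges are stored with the gene first; directionality
    of the original target annotation is discarded because the supra-graph
    uses the target block and its transpose symmetrically.
    """

    edges: tuple[tuple[str, str], ...]
    edge_class: str

    def __post_init__(self):
        if self.edge_class not in (EDGE_CLASS_GENE_GENE, EDGE_CLASS_GENE_MIRNA):
            raise GraphValidationError(f"unknown edge class {self.edge_class!r}")
        seen = set()
        cleaned = []
        for u, v in self.edges:
            if u == v:
                raise GraphValidationError(f"self-pair {u!r} not allowed in input")
            key = frozenset((u, v))
            if key in seen:
                continue
            seen.add(key)
            cleaned.append((u, v))
        object.__setattr__(self, "edges", tuple(cleaned))

    def validate(self, universe: NodeUniverse) -> None:
        genes = set(universe.gene_ids)
        mirnas = set(universe.mirna_ids)
        for u, v in self.edges:
            for x in (u, v):
                if x not in genes and x not in mirnas:
                    raise GraphValidationError(f"unknown identifier {x!r}")
            if self.edge_class == EDGE_CLASS_GENE_GENE:
                if u not in genes or v not in genes:
                    raise GraphValidationError(
                        f"gene-gene edge ({u!r}, {v!r}) has a non-gene endpoint"
                    )
            else:
                in_g = (u in genes) + (v in genes)
                in_m = (u in mirnas) + (v in mirnas)
                if in_g != 1 or in_m != 1:
                    raise GraphValidationError(
                        f"gene-miRNA edge ({u!r}, {v!r}) must pair one gene "
                        "with one miRNA"
                    )


def build_block_adjacency(edges: EdgeList, universe: NodeUniverse) -> np.ndarray:
    """Binary adjacency block for one edge class (N×N or N×M), zero diagonal."""
    edges.validate(universe)
    gi = universe.gene_index()
    if edges.edge_class == EDGE_CLASS_GENE_GENE:
        n = universe.n_genes
        a = np.zeros((n, n))
        for u, v in edges.edges:
            a[gi[u], gi[v]] = 1.0
            a[gi[v], gi[u]] = 1.0
        return a
    mi = universe.mirna_index()
    a = np.zeros((universe.n_genes, universe.n_mirnas))
    for u, v in edges.edges:
        g, m = (u, v) if u in gi else (v, u)
        a[gi[g], mi[m]] = 1.0
    return a


def build_meta_path_adjacency(a_gene_mi: np.ndarray) -> np.ndarray:
    """miRNA-miRNA meta-path adjacency: edge iff two miRNAs share a target gene.

    Computed as the off-diagonal binarized support of Aᵀ A.
    """
    a = np.asarray(a_gene_mi, dtype=np.float64)
    if a.ndim != 2:
        raise GraphValidationError("gene-miRNA block must be a 2-d matrix")
    co = a.T @ a
    out = (co > 0).astype(np.float64)
    np.fill_diagonal(out, 0.0)
    return out


@dataclass(frozen=True)
class SupraAdjacency:
    """The (N+M)×(N+M) binary supra-graph adjacency with block bookkeeping."""

    matrix: np.ndarray
    n_genes: int
    n_mirnas: int
    variant: str

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def a_gene_gene(self) -> np.ndarray:
        return self.matrix[: self.n_genes, : self.n_genes]

    @property
    def a_gene_mi(self) -> np.ndarray:
        return self.matrix[: self.n_genes, self.n_genes:]

    @property
    def a_mi_mi(self) -> np.ndarray:
        return self.matrix[self.n_genes:, self.n_genes:]


def assemble_supra(a_gg: np.ndarray, a_gm: np.ndarray, a_mm: np.ndarray,
                   variant: str = "full") -> SupraAdjacency:
    """Assemble the supra-graph from its blocks and apply a variant mask.

    All variants receive a unit diagonal (self-loops) after masking.
    """
    if variant not in GRAPH_VARIANTS:
        raise GraphValidationError(f"unknown graph variant {variant!r}")
    a_gg = np.asarray(a_gg, dtype=np.float64)
    a_gm = np.asarray(a_gm, dtype=np.float64)
    a_mm = np.asarray(a_mm, dtype=np.float64)
    n, m = a_gm.shape if a_gm.ndim == 2 else (a_gg.shape[0], a_mm.shape[0])
    if a_gg.shape != (n, n):
        raise GraphValidationError(
            f"gene-gene block has shape {a_gg.shape}, expected {(n, n)}"
        )
    if a_gm.shape != (n, m):
        raise GraphValidationError(
            f"gene-miRNA block has shape {a_gm.shape}, expected {(n, m)}"
        )
    if a_mm.shape != (m, m):
        raise GraphValidationError(
            f"miRNA-miRNA block has shape {a_mm.shape}, expected {(m, m)}"
        )

    if variant == "gene_only":
        mat = a_gg.copy()
        n_genes, n_mirnas = n, 0
    elif variant == "mirna_only":
        mat = a_mm.copy()
        n_genes, n_mirnas = 0, m
    else:
        mat = np.zeros((n + m, n + m))
        if variant == "full":
            mat[:n, :n] = a_gg
            mat[:n, n:] = a_gm
            mat[n:, :n] = a_gm.T
            mat[n:, n:] = a_mm
        elif variant == "intra_only":
            mat[:n, :n] = a_gg
            mat[n:, n:] = a_mm
        else:  # inter_only: diagonal blocks reduce to identity (self-loops)
            mat[:n, n:] = a_gm
            mat[n:, :n] = a_gm.T
        n_genes, n_mirnas = n, m

    np.fill_diagonal(mat, 1.0)
    return SupraAdjacency(matrix=mat, n_genes=n_genes, n_mirnas=n_mirnas,
                          variant=variant)


def build_supra_graph(gene_edges: EdgeList, target_edges: EdgeList,
                      universe: NodeUniverse, variant: str = "full") -> SupraAdjacency:
    """End-to-end: edge lists → blocks → meta-paths → supra-adjacency."""
    a_gg = build_block_adjacency(gene_edges, universe)
    a_gm = build_block_adjacency(target_edges, universe)
    a_mm = build_meta_path_adjacency(a_gm)
    return assemble_supra(a_gg, a_gm, a_mm, variant=variant)


def normalize_laplacian(a, form: str = "standard") -> np.ndarray:
    """Graph Laplacian of a symmetric unit-diagonal adjacency.

    ``standard`` is the symmetric normalized Laplacian
    L = I − D^{-1/2} A D^{-1/2} whose spectrum lies in [0, 2] (the ChebNet
    convention). ``as_printed`` is the alternative form
    L = I + D^{-1/2} A D^{1/2}; it is provided for completeness but is not
    a normalized Laplacian and breaks the [0, 2] spectral bound.
    """
    mat = a.matrix if isinstance(a, SupraAdjacency) else np.asarray(a, dtype=np.float64)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise GraphValidationError("adjacency must be square")
    if not np.allclose(mat, mat.T):
        raise GraphValidationError("adjacency must be symmetric")
    deg = mat.sum(axis=1)
    if np.any(deg <= 0):
        raise GraphValidationError("zero-degree node; adjacency must have self-loops")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    if form == "standard":
        lap = np.eye(mat.shape[0]) - (d_inv_sqrt[:, None] * mat * d_inv_sqrt[None, :])
    elif form == "as_printed":
        d_sqrt = np.sqrt(deg)
        lap = np.eye(mat.shape[0]) + (d_inv_sqrt[:, None] * mat * d_sqrt[None, :])
    else:
        raise GraphValidationError(f"unknown laplacian form {form!r}")
    return lap


def largest_eigenvalue(lap: np.ndarray) -> float:
    """Largest eigenvalue of a symmetric matrix, sparse solver with dense fallback."""
    n = lap.shape[0]
    if n < 3:
        return float(np.linalg.eigvalsh(lap)[-1])
    try:
        val = spla.eigsh(sp.csr_matrix(lap), k=1, which="LA",
                         return_eigenvectors=False)
        return float(val[0])
    except (spla.ArpackNoConvergence, RuntimeError):
        return float(np.linalg.eigvalsh(lap)[-1])


def scale_laplacian(lap: np.ndarray, lambda_max: float | None = None) -> np.ndarray:
    """Rescale L to L̃ = 2L/λmax − I, mapping the spectrum into [−1, 1].

    A degenerate λmax (≤ 1e−12, e.g. a single isolated self-looped node)
    falls back to λmax = 2, the upper bound of the normalized-Laplacian
    spectrum.
    """
    lap = np.asarray(lap, dtype=np.float64)
    if not np.allclose(lap, lap.T):
        raise GraphValidationError("Laplacian must be symmetric")
    if lambda_max is not None and lambda_max <= 0:
        raise GraphValidationError("lambda_max must be positive")
    if lambda_max is None:
        lambda_max = largest_eigenvalue(lap)
        if lambda_max <= 1e-12:
            lambda_max = 2.0
    return 2.0 * lap / lambda_max - np.eye(lap.shape[0])


@dataclass(frozen=True)
class SpectralGraph:
    """Normalized and rescaled Laplacian of a supra-graph, ready for ChebNet."""

    laplacian: np.ndarray
    lambda_max: float
    laplacian_rescaled: np.ndarray
    adjacency: SupraAdjacency | None = field(default=None, repr=False)

    @classmethod
    def from_adjacency(cls, a: SupraAdjacency, form: str = "standard",
                       lambda_max: float | None = None) -> "SpectralGraph":
        lap = normalize_laplacian(a, form=form)
        if lambda_max is None:
            lam = largest_eigenvalue(lap)
            if lam <= 1e-12:
                lam = 2.0
        else:
            lam = float(lambda_max)
        return cls(laplacian=lap, lambda_max=lam,
                   laplacian_rescaled=scale_laplacian(lap, lam), adjacency=a)


# -- export ------------------------------------------------------------------


def export_supra(a: SupraAdjacency, universe: NodeUniverse, prefix: str | Path) -> None:
    """Write the supra-graph as a sparse triplet TSV plus a JSON sidecar.

    ``<prefix>.edges.tsv`` holds ``row	col	value`` triplets of the upper
    triangle (incl. diagonal); ``<prefix>.json`` records node order and
    variant so the matrix can be reconstructed exactly.
    """
    prefix = Path(prefix)
    rows, cols = np.nonzero(np.triu(a.matrix))
    with open(f"{prefix}.edges.tsv", "w") as fh:
        fh.write("row\tcol\tvalue\n")
        for r, c in zip(rows, cols):
            fh.write(f"{r}\t{c}\t{a.matrix[r, c]:g}\n")
    sidecar = {
        "variant": a.variant,
        "n_genes": a.n_genes,
        "n_mirnas": a.n_mirnas,
        "gene_ids": list(universe.gene_ids),
        "mirna_ids": list(universe.mirna_ids),
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def import_supra(prefix: str | Path) -> tuple[SupraAdjacency, NodeUniverse]:
    """Inverse of :func:`export_supra`."""
    prefix = Path(prefix)
    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    n = meta["n_genes"] + meta["n_mirnas"]
    mat = np.zeros((n, n))
    with open(f"{prefix}.edges.tsv") as fh:
        next(fh)
        for line in fh:
            r, c, v = line.split("\t")
            mat[int(r), int(c)] = float(v)
            mat[int(c), int(r)] = float(v)
    a = SupraAdjacency(matrix=mat, n_genes=meta["n_genes"],
                       n_mirnas=meta["n_mirnas"], variant=meta["variant"])
    universe = NodeUniverse(tuple(meta["gene_ids"]), tuple(meta["mirna_ids"]))
    return a, universe
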