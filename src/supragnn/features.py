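"""Omics matrix normalization, variance-based feature selection, and
assembly of per-sample node attributes for the supra-graph.

Gene nodes carry a 2-vector attribute (mRNA expression, CNV dosage); miRNA
nodes carry a scalar (miRNA expression). When an omic is excluded from a
combination its channel is zero-filled (genes) or its nodes dropped
(miRNAs), so layer shapes stay stable across omic combinations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import NodeUniverse

OMIC_NAMES = ("mRNA", "CNV", "miRNA")
OMIC_COMBOS = ("mRNA", "miRNA", "mRNA+CNV", "mRNA+miRNA", "mRNA+CNV+miRNA")


class FeatureError(ValueError):
    """Raised on inconsistent omics matrices or invalid selections."""


@dataclass
class OmicsMatrix:
    """A samples × features matrix for one omic layer."""

    values: pd.DataFrame  # index: sample ids, columns: feature ids
    omic: str

    def __post_init__(self):
        if self.omic not in OMIC_NAMES:
            raise FeatureError(f"unknown omic {self.omic!r}")
        if self.values.index.has_duplicates:
            raise FeatureError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise FeatureError("duplicate feature ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)


def normalize_within_omic(m: OmicsMatrix, train_samples: list[str] | None = None,
                          method: str = "zscore") -> OmicsMatrix:
    """Normalize each feature within its omic.

    Statistics (mean/sd for ``zscore``, min/max for ``minmax``) are estimated
    on ``train_samples`` when given — avoiding leakage from validation/test
    samples — and applied to all samples. Zero-variance (or zero-range)
    features map to all-zeros.
    """
    vals = m.values
    if not np.isfinite(vals.to_numpy()).all():
        bad = [c for c in vals.columns if not np.isfinite(vals[c].to_numpy()).all()]
        raise FeatureError(f"non-finite values in features: {bad}")
    fit = vals.loc[train_samples] if train_samples is not None else vals
    x = vals.to_numpy(dtype=np.float64)
    f = fit.to_numpy(dtype=np.float64)
    if method == "zscore":
        mu = f.mean(axis=0)
        sd = f.std(axis=0)  # population sd
        out = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    elif method == "minmax":
        lo, hi = f.min(axis=0), f.max(axis=0)
        rng = hi - lo
        out = np.where(rng > 0, (x - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    else:
        raise FeatureError(f"unknown normalization method {method!r}")
    return OmicsMatrix(pd.DataFrame(out, index=vals.index, columns=vals.columns),
                       m.omic)


def select_top_variance(m: OmicsMatrix, k: int,
                        train_samples: list[str] | None = None) -> OmicsMatrix:
    """Keep the k features with largest (population) variance, descending.

    Variance is computed on ``train_samples`` when given. Ties break by
    input feature order, making the selection deterministic.
    """
    if k > m.values.shape[1]:
        raise FeatureError(
            f"k={k} exceeds feature count {m.values.shape[1]}"
        )
    if k < 1:
        raise FeatureError("k must be positive")
    fit = m.values.loc[train_samples] if train_samples is not None else m.values
    var = fit.to_numpy(dtype=np.float64).var(axis=0)
    order = np.argsort(-var, kind="stable")[:k]
    return OmicsMatrix(m.values.iloc[:, order], m.omic)


def align_features(m: OmicsMatrix, feature_ids: list[str]) -> OmicsMatrix:
    """Reindex to a given feature set/order (e.g. apply the mRNA-selected
    gene set to CNV)."""
    missing = [f for f in feature_ids if f not in m.values.columns]
    if missing:
        raise FeatureError(f"features missing from {m.omic}: {missing}")
    return OmicsMatrix(m.values.loc[:, feature_ids], m.omic)


def _combo_parts(omic_combo: str) -> set[str]:
    if omic_combo not in OMIC_COMBOS:
        raise FeatureError(f"unknown omic combination {omic_combo!r}")
    return set(omic_combo.split("+"))


@dataclass
class NodeAttributeSet:
    """Per-sample node attributes aligned to the frozen supra-graph order.

    ``gene_attrs`` is (S, N, 2) — column 0 mRNA, column 1 CNV; ``mirna_attrs``
    is (S, M, 1). Flattening order is fixed: gene attributes row-major
    (mRNA_1, CNV_1, mRNA_2, CNV_2, …), then miRNA attributes — giving the
    length-(2N+M) reconstruction target vector per sample.
    """

    gene_attrs: np.ndarray
    mirna_attrs: np.ndarray
    sample_ids: list[str]
    omic_combo: str

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return self.gene_attrs.shape[1]

    @property
    def n_mirnas(self) -> int:
        return self.mirna_attrs.shape[1]

    @property
    def flat_length(self) -> int:
        return 2 * self.n_genes + self.n_mirnas

    def flatten(self) -> np.ndarray:
        """(S, 2N+M) array of per-sample flattened attribute vectors."""
        s = self.n_samples
        return np.concatenate(
            [self.gene_attrs.reshape(s, -1), self.mirna_attrs.reshape(s, -1)],
            axis=1,
        )

    @classmethod
    def unflatten(cls, flat: np.ndarray, n_genes: int, n_mirnas: int,
                  sample_ids: list[str], omic_combo: str) -> "NodeAttributeSet":
        flat = np.asarray(flat, dtype=np.float64)
        if flat.shape[1] != 2 * n_genes + n_mirnas:
            raise FeatureError("flattened length does not match 2N+M")
        s = flat.shape[0]
        return cls(
            gene_attrs=flat[:, : 2 * n_genes].reshape(s, n_genes, 2),
            mirna_attrs=flat[:, 2 * n_genes:].reshape(s, n_mirnas, 1),
            sample_ids=list(sample_ids),
            omic_combo=omic_combo,
        )

    def subset(self, idx: np.ndarray) -> "NodeAttributeSet":
        return NodeAttributeSet(
            gene_attrs=self.gene_attrs[idx],
            mirna_attrs=self.mirna_attrs[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            omic_combo=self.omic_combo,
        )


def assemble_node_attributes(mrna: OmicsMatrix | None, cnv: OmicsMatrix | None,
                             mirna: OmicsMatrix | None, universe: NodeUniverse,
                             omic_combo: str = "mRNA+CNV+miRNA") -> NodeAttributeSet:
    """Assemble per-sample node attributes for one omic combination.

    Required matrices must share a common sample set; features must match
    the universe's gene/miRNA ordering. Excluded omics are zero-filled
    (CNV channel) or produce zero miRNA nodes (miRNA).
    """
    parts = _combo_parts(omic_combo)
    need = {"mRNA": mrna if "mRNA" in parts else None,
            "CNV": cnv if "CNV" in parts else None,
            "miRNA": mirna if "miRNA" in parts else None}
    present = [m for m in need.values() if m is not None]
    if not present:
        raise FeatureError("no omics provided")
    for name in parts:
        if need[name] is None:
            raise FeatureError(f"combination {omic_combo!r} requires {name} data")

    sample_ids = present[0].sample_ids
    for m in present[1:]:
        if m.sample_ids != sample_ids:
            raise FeatureError(
                f"sample sets inconsistent between omics ({m.omic})"
            )
    s = len(sample_ids)
    n, m_ = universe.n_genes, universe.n_mirnas

    gene_attrs = np.zeros((s, n, 2))
    if "mRNA" in parts:
        if need["mRNA"].feature_ids != list(universe.gene_ids):
            raise FeatureError("mRNA features do not match universe gene order")
        gene_attrs[:, :, 0] = need["mRNA"].values.to_numpy(dtype=np.float64)
    if "CNV" in parts:
        if need["CNV"].feature_ids != list(universe.gene_ids):
            raise FeatureError("CNV features do not match universe gene order")
        gene_attrs[:, :, 1] = need["CNV"].values.to_numpy(dtype=np.float64)
    if "mRNA" not in parts:
        gene_attrs = np.zeros((s, 0, 2))  # miRNA-only: no gene nodes

    if "miRNA" in parts:
        if need["miRNA"].feature_ids != list(universe.mirna_ids):
            raise FeatureError("miRNA features do not match universe miRNA order")
        mirna_attrs = need["miRNA"].values.to_numpy(dtype=np.float64)[:, :, None]
    else:
        mirna_attrs = np.zeros((s, 0, 1))

    return NodeAttributeSet(gene_attrs=gene_attrs, mirna_attrs=mirna_attrs,
                            sample_ids=list(sample_ids), omic_combo=omic_combo)


def resolve_graph_variant(omic_combo: str, graph_variant: str) -> str:
    """Reduce a graph variant to the node types an omic combination provides.

    With no miRNA data there are only gene nodes, so ``full``/``intra_only``
    reduce to ``gene_only``; with only miRNA data they reduce to
    ``mirna_only``. ``inter_only`` needs both node types and is incompatible
    with single-layer combinations.
    """
    parts = _combo_parts(omic_combo)
    has_gene = "mRNA" in parts
    has_mirna = "miRNA" in parts
    if has_gene and has_mirna:
        return graph_variant
    if graph_variant == "inter_only":
        raise FeatureError(
            f"inter_only graph needs both node types; combination {omic_combo!r} "
            "provides only one"
        )
    if has_gene:
        if graph_variant == "mirna_only":
            raise FeatureError(f"mirna_only graph incompatible with {omic_combo!r}")
        return "gene_only"
    if graph_variant == "gene_only":
        raise FeatureError(f"gene_only graph incompatible with {omic_combo!r}")
    return "mirna_only"
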