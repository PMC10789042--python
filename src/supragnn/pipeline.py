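"""Glue from raw inputs (edge lists + omics + labels) to model-ready tensors.

The preparation order follows the framework's preprocessing: split, then
normalize each omic (statistics from the training samples by default), then
select the top-variance genes/miRNAs (the mRNA-selected gene set is applied
to CNV so both gene channels stay aligned), then restrict the knowledge
graphs to the selected nodes, build the supra-graph variant, and assemble
per-sample node attributes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import (NodeAttributeSet, OmicsMatrix, align_features,
                       assemble_node_attributes, normalize_within_omic,
                       resolve_graph_variant, select_top_variance)
from .graph import EdgeList, NodeUniverse, SpectralGraph, build_supra_graph
from .model import ModelConfig
from .training import SplitPlan, split_dataset


@dataclass
class Dataset:
    """Model-ready cohort: node attributes, encoded labels and index splits."""

    attrs: NodeAttributeSet
    labels: np.ndarray           # integer-encoded, aligned to attrs.sample_ids
    classes: list                # original label values, index = encoded label
    splits: dict[str, np.ndarray]
    universe: NodeUniverse

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def split_attrs(self, name: str) -> NodeAttributeSet:
        return self.attrs.subset(self.splits[name])

    def split_labels(self, name: str) -> np.ndarray:
        return self.labels[self.splits[name]]


def _filter_edges(edges: EdgeList, keep: set[str]) -> EdgeList:
    kept = tuple((u, v) for u, v in edges.edges if u in keep and v in keep)
    return EdgeList(kept, edges.edge_class)


def prepare_dataset(
    networks: tuple[EdgeList, EdgeList, NodeUniverse],
    omics: tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix],
    labels: pd.Series,
    config: ModelConfig,
    plan: SplitPlan | None = None,
    n_top_genes: int | None = None,
    n_top_mirnas: int | None = None,
    normalize_scope: str = "train_only",
    norm_method: str = "zscore",
    select_on: str = "raw",
    exclude_classes: tuple = (),
) -> tuple[Dataset, SpectralGraph]:
    """Full preprocessing pipeline; returns the dataset and its graph.

    ``normalize_scope`` chooses whether normalization statistics come from
    the training split only (default, leakage-free) or the whole cohort;
    ``select_on`` chooses whether variance ranking is computed on raw or
    normalized values. The default is raw: per-feature z-scoring flattens
    every feature's variance to 1, which would make a post-normalization
    ranking degenerate.
    """
    gene_edges, target_edges, universe = networks
    mrna, cnv, mirna = omics
    plan = plan or SplitPlan()

    if exclude_classes:
        keep = ~labels.isin(exclude_classes)
        labels = labels[keep]
    sample_ids = [s for s in mrna.sample_ids if s in set(labels.index)]
    labels = labels.loc[sample_ids]

    def restrict(m: OmicsMatrix) -> OmicsMatrix:
        return OmicsMatrix(m.values.loc[sample_ids], m.omic)

    mrna, cnv, mirna = restrict(mrna), restrict(cnv), restrict(mirna)

    classes = sorted(pd.unique(labels))
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.asarray([class_index[c] for c in labels], dtype=int)

    splits = split_dataset(y, plan)
    train_samples = [sample_ids[i] for i in splits["train"]]
    fit_samples = train_samples if normalize_scope == "train_only" else None

    def prep(m: OmicsMatrix, k: int | None) -> OmicsMatrix:
        normed = normalize_within_omic(m, train_samples=fit_samples,
                                       method=norm_method)
        if k is None:
            return normed
        src = normed if select_on == "normalized" else m
        selected = select_top_variance(src, k, train_samples=fit_samples)
        return align_features(normed, selected.feature_ids)

    mrna_p = prep(mrna, n_top_genes)
    cnv_p = align_features(normalize_within_omic(cnv, train_samples=fit_samples,
                                                 method=norm_method),
                           mrna_p.feature_ids)
    mirna_p = prep(mirna, n_top_mirnas)

    variant = resolve_graph_variant(config.omic_combo, config.graph_variant)
    has_gene = variant != "mirna_only"
    has_mirna = variant != "gene_only"
    sel_universe = NodeUniverse(
        tuple(mrna_p.feature_ids) if has_gene else (),
        tuple(mirna_p.feature_ids) if has_mirna else (),
    )
    keep = set(sel_universe.gene_ids) | set(sel_universe.mirna_ids)
    supra = build_supra_graph(
        _filter_edges(gene_edges, keep | set(mrna_p.feature_ids)),
        _filter_edges(target_edges,
                      set(mrna_p.feature_ids) | set(mirna_p.feature_ids)),
        NodeUniverse(tuple(mrna_p.feature_ids), tuple(mirna_p.feature_ids)),
        variant=variant,
    )
    graph = SpectralGraph.from_adjacency(supra, form=config.laplacian_form)

    attrs = assemble_node_attributes(
        mrna_p if "mRNA" in config.omic_combo else None,
        cnv_p if "CNV" in config.omic_combo else None,
        mirna_p if "miRNA" in config.omic_combo else None,
        NodeUniverse(tuple(mrna_p.feature_ids), tuple(mirna_p.feature_ids)),
        config.omic_combo,
    )

    dataset = Dataset(attrs=attrs, labels=y, classes=list(classes),
                      splits=splits, universe=sel_universe)
    return dataset, graph
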