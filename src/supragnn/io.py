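"""Readers and writers for the plain-text interchange formats.

Edge lists are two-column TSVs with a ``source<TAB>target`` header; omics
matrices are TSV/CSV with sample ids in the first column and features in
the remaining columns; labels are two-column TSVs ``sample_id<TAB>class``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .features import OmicsMatrix
from .graph import (EDGE_CLASS_GENE_GENE, EDGE_CLASS_GENE_MIRNA, EdgeList,
                    NodeUniverse)


def read_edge_list(path: str | Path, edge_class: str) -> EdgeList:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["source", "target"]:
        raise ValueError(f"{path}: expected header 'source\\ttarget'")
    edges = tuple(zip(df["source"], df["target"]))
    return EdgeList(edges, edge_class)


def read_gene_edges(path: str | Path) -> EdgeList:
    return read_edge_list(path, EDGE_CLASS_GENE_GENE)


def read_target_edges(path: str | Path) -> EdgeList:
    return read_edge_list(path, EDGE_CLASS_GENE_MIRNA)


def read_omics(path: str | Path, omic: str) -> OmicsMatrix:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return OmicsMatrix(df, omic)


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def read_node_list(path: str | Path) -> tuple[str, ...]:
    with open(path) as fh:
        return tuple(line.strip() for line in fh if line.strip())


def load_fixture(fixture_dir: str | Path):
    """Load a cohort directory written by :func:`supragnn.simulate.write_fixture`.

    Returns ``((gene_edges, target_edges, universe), (mrna, cnv, mirna),
    labels)``; the node universe is inferred from the omics column headers.
    """
    d = Path(fixture_dir)
    gene_edges = read_gene_edges(d / "ggi_edges.tsv")
    target_edges = read_target_edges(d / "target_edges.tsv")
    mrna = read_omics(d / "mrna.tsv", "mRNA")
    cnv = read_omics(d / "cnv.tsv", "CNV")
    mirna = read_omics(d / "mirna.tsv", "miRNA")
    labels = read_labels(d / "labels.tsv")
    universe = NodeUniverse(tuple(mrna.feature_ids), tuple(mirna.feature_ids))
    return (gene_edges, target_edges, universe), (mrna, cnv, mirna), labels


def write_jsonl(records: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
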