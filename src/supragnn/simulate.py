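"""Synthetic knowledge graphs and class-conditional multi-omics cohorts.

The generator emulates the statistical structure the framework assumes in
real data: an Erdős–Rényi gene-gene interaction network, a random bipartite
miRNA-gene target network, and a cohort in which each cancer subtype owns a
module of neighboring genes whose expression is shifted in that subtype's
samples. CNV tracks the expression signal with a configurable correlation
and is discretized to integer dosage calls in {−2..2}; miRNAs targeting a
module's genes are shifted in the repressor direction (−effect/2). All
randomness flows from a single seed, so identical specs regenerate
byte-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .features import OmicsMatrix
from .graph import (EDGE_CLASS_GENE_GENE, EDGE_CLASS_GENE_MIRNA, EdgeList,
                    NodeUniverse)


class SimulationError(ValueError):
    """Raised on invalid generator specifications."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic cohort generator.

    Defaults define the package's standard small cohort: 60 genes, 20
    miRNAs, 4 subtypes, 300 samples, an 8-gene module per subtype shifted
    by 3 noise-sd units.
    """

    n_genes: int = 60
    n_mirnas: int = 20
    gene_edge_prob: float = 0.08
    target_edge_prob: float = 0.10
    n_samples: int = 300
    n_classes: int = 4
    module_size: int = 8
    effect_size: float = 3.0
    noise_sd: float = 1.0
    cnv_expr_corr: float = 0.5
    class_proportions: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        for p in (self.gene_edge_prob, self.target_edge_prob):
            if not 0.0 <= p <= 1.0:
                raise SimulationError("edge probabilities must be in [0, 1]")
        if self.module_size > self.n_genes:
            raise SimulationError("module_size exceeds n_genes")
        if self.n_classes * self.module_size > self.n_genes:
            raise SimulationError(
                "n_classes * module_size exceeds n_genes; modules must be disjoint"
            )
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be non-negative")
        if self.class_proportions is not None:
            props = tuple(float(p) for p in self.class_proportions)
            if len(props) != self.n_classes:
                raise SimulationError("class_proportions length must equal n_classes")
            if abs(sum(props) - 1.0) > 1e-9 or min(props) < 0:
                raise SimulationError("class_proportions must be non-negative and sum to 1")
            object.__setattr__(self, "class_proportions", props)

    @property
    def proportions(self) -> np.ndarray:
        if self.class_proportions is None:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return np.asarray(self.class_proportions)


def generate_networks(spec: SyntheticSpec) -> tuple[EdgeList, EdgeList, NodeUniverse]:
    """Random GGI and target networks plus the node universe.

    Gene-gene edges are i.i.d. Bernoulli(gene_edge_prob) over unordered
    gene pairs; gene-miRNA edges Bernoulli(target_edge_prob) over all pairs.
    """
    rng = np.random.default_rng([spec.seed, 0])
    gene_ids = tuple(f"g{i:04d}" for i in range(spec.n_genes))
    mirna_ids = tuple(f"mir{i:03d}" for i in range(spec.n_mirnas))
    universe = NodeUniverse(gene_ids, mirna_ids)

    n = spec.n_genes
    upper = rng.random((n, n)) < spec.gene_edge_prob
    gg = [(gene_ids[i], gene_ids[j]) for i in range(n) for j in range(i + 1, n)
          if upper[i, j]]
    gm_mask = rng.random((n, spec.n_mirnas)) < spec.target_edge_prob
    gm = [(gene_ids[i], mirna_ids[j]) for i in range(n)
          for j in range(spec.n_mirnas) if gm_mask[i, j]]
    return (EdgeList(tuple(gg), EDGE_CLASS_GENE_GENE),
            EdgeList(tuple(gm), EDGE_CLASS_GENE_MIRNA),
            universe)


def _class_modules(spec: SyntheticSpec, gene_edges: EdgeList,
                   universe: NodeUniverse,
                   rng: np.random.Generator) -> list[list[int]]:
    """Disjoint gene modules, one per class: a seed gene plus GGI neighbors
    (breadth-first), padded with random unused genes when the neighborhood
    is too small."""
    g = nx.Graph()
    g.add_nodes_from(universe.gene_ids)
    g.add_edges_from(gene_edges.edges)
    gi = universe.gene_index()
    unused = list(universe.gene_ids)
    modules: list[list[int]] = []
    for _ in range(spec.n_classes):
        seed_gene = unused[rng.integers(len(unused))]
        module = [seed_gene]
        frontier = [seed_gene]
        used_set = set(module)
        while len(module) < spec.module_size and frontier:
            nxt = []
            for node in frontier:
                for nb in sorted(g.neighbors(node)):
                    if nb in unused and nb not in used_set:
                        module.append(nb)
                        used_set.add(nb)
                        nxt.append(nb)
                        if len(module) >= spec.module_size:
                            break
                if len(module) >= spec.module_size:
                    break
            frontier = nxt
        while len(module) < spec.module_size:  # fallback: random unused genes
            cand = unused[rng.integers(len(unused))]
            if cand not in used_set:
                module.append(cand)
                used_set.add(cand)
        unused = [u for u in unused if u not in used_set]
        modules.append(sorted(gi[x] for x in module))
    return modules


def generate_labeled_omics(
    spec: SyntheticSpec,
    networks: tuple[EdgeList, EdgeList, NodeUniverse],
) -> tuple[OmicsMatrix, OmicsMatrix, OmicsMatrix, pd.Series]:
    """Class-conditional mRNA/CNV/miRNA matrices and subtype labels.

    Samples of class c have the c-th gene module's expression shifted by
    ``effect_size``; CNV is ``cnv_expr_corr`` times the clean expression
    signal plus independent noise, discretized to {−2..2}; miRNAs targeting
    module genes are shifted by −effect_size/2 in that class.
    """
    gene_edges, target_edges, universe = networks
    rng = np.random.default_rng([spec.seed, 1])
    s, n, m = spec.n_samples, spec.n_genes, spec.n_mirnas

    labels = rng.choice(spec.n_classes, size=s, p=spec.proportions)
    modules = _class_modules(spec, gene_edges, universe, rng)

    # clean class signal on gene expression
    signal = np.zeros((s, n))
    for c, module in enumerate(modules):
        signal[np.ix_(labels == c, module)] = spec.effect_size

    mrna = signal + rng.normal(0.0, spec.noise_sd, size=(s, n))

    cnv_noise_sd = spec.noise_sd * np.sqrt(max(0.0, 1.0 - spec.cnv_expr_corr**2))
    cnv_raw = (spec.cnv_expr_corr * signal
               + rng.normal(0.0, 1.0, size=(s, n)) * cnv_noise_sd)
    cnv = np.clip(np.round(cnv_raw), -2, 2)

    mi = universe.mirna_index()
    gi = universe.gene_index()
    targets_of: dict[int, set[int]] = {j: set() for j in range(m)}
    for u, v in target_edges.edges:
        g_id, m_id = (u, v) if u in gi else (v, u)
        targets_of[mi[m_id]].add(gi[g_id])
    mirna_signal = np.zeros((s, m))
    for c, module in enumerate(modules):
        module_set = set(module)
        hit = [j for j in range(m) if targets_of[j] & module_set]
        if hit:
            mirna_signal[np.ix_(labels == c, hit)] = -spec.effect_size / 2.0
    mirna = mirna_signal + rng.normal(0.0, spec.noise_sd, size=(s, m))

    sample_ids = [f"s{i:04d}" for i in range(s)]
    idx = pd.Index(sample_ids, name="sample_id")
    return (
        OmicsMatrix(pd.DataFrame(mrna, index=idx, columns=universe.gene_ids), "mRNA"),
        OmicsMatrix(pd.DataFrame(cnv, index=idx, columns=universe.gene_ids), "CNV"),
        OmicsMatrix(pd.DataFrame(mirna, index=idx, columns=universe.mirna_ids), "miRNA"),
        pd.Series(labels, index=idx, name="class"),
    )


def generate_cohort(spec: SyntheticSpec):
    """Convenience: networks plus omics plus labels in one call."""
    networks = generate_networks(spec)
    mrna, cnv, mirna, labels = generate_labeled_omics(spec, networks)
    return networks, (mrna, cnv, mirna), labels


def write_fixture(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete cohort in the exact formats the pipeline reads.

    Emits ``ggi_edges.tsv``, ``target_edges.tsv``, ``{mrna,cnv,mirna}.tsv``,
    ``labels.tsv`` and a ``manifest.json`` recording the spec (so the files
    can be regenerated byte-identically from the seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (gene_edges, target_edges, universe), omics, labels = generate_cohort(spec)
    mrna, cnv, mirna = omics

    paths: dict[str, Path] = {}

    def write_edges(name: str, el: EdgeList):
        p = out / f"{name}.tsv"
        with open(p, "w") as fh:
            fh.write("source\ttarget\n")
            for u, v in el.edges:
                fh.write(f"{u}\t{v}\n")
        paths[name] = p

    write_edges("ggi_edges", gene_edges)
    write_edges("target_edges", target_edges)
    for name, om in (("mrna", mrna), ("cnv", cnv), ("mirna", mirna)):
        p = out / f"{name}.tsv"
        om.values.to_csv(p, sep="\t", float_format="%.10g")
        paths[name] = p
    p = out / "labels.tsv"
    labels.to_csv(p, sep="\t")
    paths["labels"] = p

    manifest = {"spec": asdict(spec)}
    mp = out / "manifest.json"
    with open(mp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = mp
    return paths
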