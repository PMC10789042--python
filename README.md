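# supragnn

Graph neural networks on a heterogeneous **supra-graph** for multi-omics
cancer subtype classification.

Molecular subtypes of cancer are defined by shared molecular profiles rather
than tissue of origin, and calling them from omics data benefits from prior
biological knowledge: which genes interact, and which genes each miRNA
targets. `supragnn` embeds that knowledge in a single block adjacency over
gene and miRNA nodes,

```
A_supra = [ A_gene-gene   A_gene-mi ]
          [ A_gene-miᵀ    A_mi-mi   ]
```

where `A_gene-gene` is a gene–gene interaction (GGI) network, `A_gene-mi` a
miRNA–gene target network, and `A_mi-mi` holds derived **meta-path** edges —
two miRNAs are connected when they target the same gene. Every node carries
a self-loop. Each sample becomes a graph signal: gene nodes carry a 2-vector
(mRNA expression, CNV dosage), miRNA nodes a scalar (miRNA expression).

The classifier is a four-module network:

1. **dimension increase** — parallel linear layers lift gene (ℝ²) and miRNA
   (ℝ¹) attributes to a common width F;
2. **GNN** — two graph layers, either order-K Chebyshev spectral
   convolutions `y = Σₖ Tₖ(L̃) X Bₖ` on the rescaled Laplacian
   `L̃ = 2L/λmax − I` (K = 5), or 8-head graph attention with masked-softmax
   coefficients `α_ij = softmax_{j∈NB(i)} LeakyReLU(aᵀ[Wx_i ‖ Wx_j])`;
   a max-pool over the frozen node order (window p = 8) plus one linear
   layer reads out a 64-d local representation θ_local;
3. **decoder** — a two-layer network reconstructing the flattened input
   attributes from θ_local;
4. **parallel branch** — a shallow two-layer network mapping the lifted
   attributes directly to a 64-d global representation θ_global.

A softmax layer on `[θ_local ‖ θ_global]` predicts the subtype. Training
minimizes `L = λ₁·L_ent + λ₂·L_recon + λ₃·L_reg` (cross-entropy, squared
reconstruction error, squared l² norm of all parameters). Ablation presets
cover graph variants (full / intra-only / inter-only / gene-only /
miRNA-only), omic combinations, both GNN types, and decoder/parallel on/off.

The model runs on a compact NumPy reverse-mode autodiff engine
(`supragnn.autodiff`) — no deep-learning framework required — and ships with
a synthetic cohort generator so the full pipeline is testable without any
data download.

## Worked example

```python
import supragnn as sg

# a synthetic cohort: 60 genes, 20 miRNAs, 4 subtypes, 300 samples,
# subtype modules of 8 neighboring genes shifted by 3 noise-sd units
spec = sg.SyntheticSpec()
networks, omics, labels = sg.generate_cohort(spec)

cfg = sg.ModelConfig(gnn_type="GCN", epochs=100, seed=0)
report, _ = sg.run_trials(networks, omics, labels, cfg, n_trials=5)
print(f"test accuracy {report.accuracy:.3f} ± {report.std['accuracy']:.3f}")
print(f"weighted F1   {report.f1_weighted:.3f}")
```

prints

```
test accuracy 0.987 ± 0.027
weighted F1   0.987
```

i.e. five trials (fresh split + fresh initialization each) recover the four
planted subtypes from held-out samples almost perfectly; the majority-class
baseline on this cohort is 0.28. The GAT preset
(`sg.ModelConfig(gnn_type="GAT", epochs=50)`) reaches 0.980 ± 0.027.

The same flow is available from the shell:

```bash
supragnn simulate --out cohort/
supragnn train --fixture cohort/ --trials 5 --out metrics.json
supragnn ablate --fixture cohort/ --out ablation.tsv
```

`ablate` runs the preset grid — {GCN, GAT} × {full, no-decoder, no-parallel,
neither} plus the five omic combinations × {intra-only, inter-only} graphs —
and writes one row of metrics per preset (incompatible combinations are
recorded as skipped).

## Layout

- `supragnn.graph` — edge-list validation, meta-path derivation,
  supra-adjacency assembly and variants, Laplacian normalization/rescaling
- `supragnn.features` — per-omic normalization, variance-based feature
  selection, node-attribute assembly
- `supragnn.model` — the four-module network and its layer primitives
- `supragnn.losses` — the three-term objective
- `supragnn.simulate` — knowledge-graph + class-conditional cohort generator
- `supragnn.pipeline` / `supragnn.training` — preprocessing, training loop,
  metrics, multi-trial aggregation, ablation presets
- `supragnn.cli` — the `supragnn` command

See `docs/methods.md` for the model details, generator design and numerical
choices.
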