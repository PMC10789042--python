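"""Splitting, training loop, metrics, multi-trial aggregation and the
ablation grid.

Training minimizes the three-term objective with Adam on the full training
batch; the parameters with the best validation accuracy are kept. Metrics
(accuracy, precision, recall, F1 — macro and weighted) are computed from
the argmax confusion matrix via scikit-learn. Results are averaged over
independent trials that re-seed both the parameter initialization and,
optionally, the data split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, precision_recall_fscore_support

from .autodiff import Adam, Tensor
from .losses import breakdown, cross_entropy, recon_loss, reg_loss
from .model import ModelConfig, SupraGNN

METRIC_NAMES = ("accuracy", "precision_macro", "recall_macro", "f1_macro",
                "precision_weighted", "recall_weighted", "f1_weighted")


class TrainingError(RuntimeError):
    """Raised on divergence or invalid training inputs."""


# -- splitting ----------------------------------------------------------------


@dataclass(frozen=True)
class SplitPlan:
    """Train/validation/test fractions with stratification and a seed."""

    train_frac: float = 0.8
    val_frac: float = 0.1
    test_frac: float = 0.1
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.train_frac, self.val_frac, self.test_frac) < 0:
            raise ValueError("split fractions must be non-negative")


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    base = np.floor(quotas).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(quotas - base), kind="stable")
        base[order[:short]] += 1
    return base


def split_dataset(labels: np.ndarray, plan: SplitPlan) -> dict[str, np.ndarray]:
    """Disjoint stratified train/val/test index sets covering all samples.

    Global split sizes are exact (largest-remainder rounding of n·frac);
    within classes the allocation is proportional, with at least one test
    sample per class whenever the test split is large enough. Classes with
    fewer than 3 samples get a best-effort assignment with a warning.
    """
    y = np.asarray(labels)
    n = y.size
    if n == 0:
        raise ValueError("no samples to split")
    rng = np.random.default_rng(plan.seed)

    n_test = int(round(n * plan.test_frac))
    n_val = int(round(n * plan.val_frac))
    n_train = n - n_test - n_val

    if not plan.stratified:
        perm = rng.permutation(n)
        return {"train": np.sort(perm[:n_train]),
                "val": np.sort(perm[n_train:n_train + n_val]),
                "test": np.sort(perm[n_train + n_val:])}

    classes, y_enc = np.unique(y, return_inverse=True)
    by_class = [rng.permutation(np.flatnonzero(y_enc == c))
                for c in range(classes.size)]
    counts = np.array([idx.size for idx in by_class])
    if (counts < 3).any():
        small = [str(classes[i]) for i in np.flatnonzero(counts < 3)]
        warnings.warn(
            f"classes with fewer than 3 samples get best-effort splits: {small}",
            stacklevel=2,
        )

    test_quota = _largest_remainder(counts * n_test / n, n_test)
    if n_test >= classes.size:  # every class represented in the test set
        deficit = (test_quota == 0) & (counts > 0)
        while deficit.any() and test_quota.sum() >= 0:
            take = np.flatnonzero(deficit)[0]
            give = int(np.argmax(test_quota))
            test_quota[take] += 1
            test_quota[give] -= 1
            deficit = (test_quota == 0) & (counts > 0)
    test_quota = np.minimum(test_quota, counts)
    remaining = counts - test_quota
    val_quota = np.minimum(_largest_remainder(remaining * n_val / max(remaining.sum(), 1),
                                              n_val), remaining)

    test_idx, val_idx, train_idx = [], [], []
    for idx, tq, vq in zip(by_class, test_quota, val_quota):
        test_idx.append(idx[:tq])
        val_idx.append(idx[tq:tq + vq])
        train_idx.append(idx[tq + vq:])
    return {"train": np.sort(np.concatenate(train_idx)),
            "val": np.sort(np.concatenate(val_idx)),
            "test": np.sort(np.concatenate(test_idx))}


# -- metrics ------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Classification metrics, optionally aggregated over trials (mean ± sd)."""

    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    per_class: dict[str, dict[str, float]] | None = None
    n_trials: int = 1
    std: dict[str, float] = field(default_factory=dict)

    def metric(self, name: str) -> float:
        return getattr(self, name)

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        d["n_trials"] = self.n_trials
        d["std"] = {k: self.std[k] for k in sorted(self.std)}
        if self.per_class is not None:
            d["per_class"] = self.per_class
        return d

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray,
                         classes: list | None = None) -> "MetricsReport":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.size == 0:
            raise ValueError("cannot evaluate an empty split")
        labels = (list(range(len(classes))) if classes is not None
                  else sorted(set(y_true) | set(y_pred)))
        acc = accuracy_score(y_true, y_pred)
        pm, rm, fm, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average="macro", zero_division=0)
        pw, rw, fw, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average="weighted", zero_division=0)
        pc, rc, fc, sup = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average=None, zero_division=0)
        names = [str(classes[i]) if classes is not None else str(lab)
                 for i, lab in enumerate(labels)]
        per_class = {
            name: {"precision": float(p), "recall": float(r), "f1": float(f),
                   "support": int(s)}
            for name, p, r, f, s in zip(names, pc, rc, fc, sup)
        }
        return cls(accuracy=float(acc), precision_macro=float(pm),
                   recall_macro=float(rm), f1_macro=float(fm),
                   precision_weighted=float(pw), recall_weighted=float(rw),
                   f1_weighted=float(fw), per_class=per_class)

    @classmethod
    def aggregate(cls, reports: list["MetricsReport"]) -> "MetricsReport":
        vals = {name: np.array([r.metric(name) for r in reports])
                for name in METRIC_NAMES}
        means = {k: float(v.mean()) for k, v in vals.items()}
        stds = {k: float(v.std()) for k, v in vals.items()}
        return cls(**means, per_class=None, n_trials=len(reports), std=stds)


# -- training loop ------------------------------------------------------------


def _forward_loss(model: SupraGNN, graph, attrs, labels, x_flat):
    cfg = model.config
    out = model.forward(attrs, graph)
    l_ent = cross_entropy(out.probabilities, labels)
    if cfg.include_decoder:
        l_rec = recon_loss(x_flat, out.x_hat, reduction=cfg.recon_reduction)
    else:
        l_rec = Tensor(0.0)
    l_reg = reg_loss(model.parameters())
    return out, breakdown(l_ent, l_rec, l_reg, cfg.lambdas)


def train(dataset, graph, config: ModelConfig) -> tuple[SupraGNN, list[dict]]:
    """Fit the model on the training split; keep the best-validation state.

    Minibatch Adam (``config.batch_size``; 0 trains full-batch) on the
    three-term objective. Returns the trained model and a per-epoch history
    (loss breakdown plus train/validation accuracy). ``config.epochs == 0``
    returns the initialization unchanged. Fully deterministic under
    ``config.seed``: the epoch shuffling rng is derived from it.
    """
    supra = graph.adjacency if hasattr(graph, "adjacency") else graph
    model = SupraGNN(config, supra.n_genes, supra.n_mirnas)
    opt = Adam(model.parameters(), lr=config.lr)

    train_attrs = dataset.split_attrs("train")
    y_train = dataset.split_labels("train")
    x_flat = train_attrs.flatten()
    val_attrs = dataset.split_attrs("val")
    y_val = dataset.split_labels("val")

    n_train = y_train.size
    bs = config.batch_size if config.batch_size and config.batch_size > 0 else n_train
    bs = min(bs, n_train)
    shuffle_rng = np.random.default_rng([config.seed, 7919])

    history: list[dict] = []
    best_state = model.state_copy()
    best_val = -1.0
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n_train) if bs < n_train else np.arange(n_train)
        n_correct = 0
        ent_sum = rec_sum = 0.0
        bd = None
        for start in range(0, n_train, bs):
            idx = order[start:start + bs]
            opt.zero_grad()
            out, (total, bd) = _forward_loss(
                model, graph, train_attrs.subset(idx), y_train[idx], x_flat[idx])
            if not np.isfinite(total.data):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: {bd.to_dict()}"
                )
            total.backward()
            opt.step()
            n_correct += int((out.probabilities.data.argmax(axis=1)
                              == y_train[idx]).sum())
            ent_sum += bd.l_ent * idx.size
            rec_sum += bd.l_recon

        lambdas = model.config.lambdas
        record = {
            "epoch": epoch,
            "l_ent": ent_sum / n_train,
            "l_recon": rec_sum,
            "l_reg": bd.l_reg,
            "total": (lambdas[0] * ent_sum / n_train + lambdas[1] * rec_sum
                      + lambdas[2] * bd.l_reg),
            "lambdas": list(lambdas),
            "train_accuracy": n_correct / n_train,
        }
        if y_val.size:
            val_pred = predict(model, val_attrs, graph)
            val_acc = float((val_pred == y_val).mean())
            record["val_accuracy"] = val_acc
        else:
            val_acc = record["train_accuracy"]
        if val_acc > best_val:
            best_val = val_acc
            best_state = model.state_copy()
        history.append(record)

    model.load_state(best_state)
    return model, history


def predict(model: SupraGNN, attrs, graph, chunk: int = 128) -> np.ndarray:
    """Argmax class predictions, evaluated in memory-bounded chunks."""
    preds = []
    for start in range(0, attrs.n_samples, chunk):
        idx = np.arange(start, min(start + chunk, attrs.n_samples))
        out = model.forward(attrs.subset(idx), graph)
        preds.append(out.probabilities.data.argmax(axis=1))
    return np.concatenate(preds)


def evaluate(model: SupraGNN, dataset, graph, split: str = "test") -> MetricsReport:
    """Metrics of the argmax predictions on one split."""
    attrs = dataset.split_attrs(split)
    if attrs.n_samples == 0:
        raise ValueError(f"split {split!r} is empty")
    y_true = dataset.split_labels(split)
    y_pred = predict(model, attrs, graph)
    return MetricsReport.from_predictions(y_true, y_pred, classes=dataset.classes)


# -- multi-trial aggregation and ablation -------------------------------------


def run_trials(networks, omics, labels, config: ModelConfig,
               plan: SplitPlan | None = None, n_trials: int = 5,
               vary_split: bool = True, split: str = "test",
               **prepare_kwargs) -> tuple[MetricsReport, list[MetricsReport]]:
    """Aggregate metrics over trials differing in seed.

    Each trial reinitializes the model (seed offset) and, when
    ``vary_split``, redraws the data split, mirroring averaged repeated
    experiments.
    """
    from .pipeline import prepare_dataset

    plan = plan or SplitPlan()
    reports = []
    for t in range(n_trials):
        cfg_t = replace(config, seed=config.seed + t)
        plan_t = replace(plan, seed=plan.seed + t) if vary_split else plan
        dataset, graph = prepare_dataset(networks, omics, labels, cfg_t,
                                         plan=plan_t, **prepare_kwargs)
        cfg_t = replace(cfg_t, n_classes=dataset.n_classes)
        model, _ = train(dataset, graph, cfg_t)
        reports.append(evaluate(model, dataset, graph, split=split))
    return MetricsReport.aggregate(reports), reports


@dataclass(frozen=True)
class AblationPreset:
    """A named set of config overrides (gnn type, modules, graph, omics)."""

    name: str
    deltas: dict

    def resolve(self, base: ModelConfig) -> ModelConfig:
        return replace(base, **self.deltas)


def module_presets() -> list[AblationPreset]:
    """{GCN, GAT} × {full, no-decoder, no-parallel, neither}."""
    out = []
    for gnn in ("GCN", "GAT"):
        for dec, par, tag in ((True, True, "Full"),
                              (False, True, "No Decoder"),
                              (True, False, "No Parallel"),
                              (False, False, "No Decoder & Parallel")):
            out.append(AblationPreset(
                f"{gnn} ({tag})",
                {"gnn_type": gnn, "include_decoder": dec,
                 "include_parallel": par}))
    return out


def omics_graph_presets() -> list[AblationPreset]:
    """The five omic combinations × {intra_only, inter_only} graphs.

    Combinations lacking one node type reduce to the single-layer graph for
    intra-omic edges and are incompatible with inter-only graphs (run_ablation
    records the skip).
    """
    combos = ("mRNA", "miRNA", "mRNA+CNV", "mRNA+miRNA", "mRNA+CNV+miRNA")
    out = []
    for combo in combos:
        for variant in ("intra_only", "inter_only"):
            out.append(AblationPreset(
                f"{combo} / {variant}",
                {"omic_combo": combo, "graph_variant": variant}))
    return out


def default_presets() -> list[AblationPreset]:
    return module_presets() + omics_graph_presets()


def run_ablation(networks, omics, labels, presets: list[AblationPreset] | None = None,
                 base_config: ModelConfig | None = None,
                 plan: SplitPlan | None = None, n_trials: int = 1,
                 vary_split: bool = False,
                 **prepare_kwargs) -> pd.DataFrame:
    """Run every preset over shared splits; emit a comparison table.

    Incompatible presets (e.g. inter-only graph with a single-layer omic
    combination) are skipped with the reason recorded in the ``status``
    column. The result is a flat DataFrame, one row per preset.
    """
    from .features import FeatureError

    presets = presets if presets is not None else default_presets()
    base_config = base_config or ModelConfig()
    rows = []
    for preset in presets:
        cfg = preset.resolve(base_config)
        row: dict = {"preset": preset.name, "gnn_type": cfg.gnn_type,
                     "omic_combo": cfg.omic_combo,
                     "graph_variant": cfg.graph_variant,
                     "include_decoder": cfg.include_decoder,
                     "include_parallel": cfg.include_parallel}
        try:
            report, _ = run_trials(networks, omics, labels, cfg, plan=plan,
                                   n_trials=n_trials, vary_split=vary_split,
                                   **prepare_kwargs)
        except FeatureError as exc:
            row["status"] = f"skipped: {exc}"
            rows.append(row)
            continue
        row["status"] = "ok"
        for name in METRIC_NAMES:
            row[name] = report.metric(name)
            row[f"{name}_sd"] = report.std.get(name, 0.0)
        row["n_trials"] = report.n_trials
        rows.append(row)
    return pd.DataFrame(rows)
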