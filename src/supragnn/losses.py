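"""Three-term training objective.

L = λ1·L_ent + λ2·L_recon + λ3·L_reg, where L_ent is the mean cross-entropy
of the class probabilities, L_recon the squared reconstruction error of the
flattened node attributes (summed over samples and elements by default, a
mean reduction is available for scale stability), and L_reg the squared l2
norm of all learnable parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

EPS = 1e-12  # probability clamp for log


@dataclass(frozen=True)
class LossBreakdown:
    l_ent: float
    l_recon: float
    l_reg: float
    total: float
    lambdas: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {"l_ent": self.l_ent, "l_recon": self.l_recon,
                "l_reg": self.l_reg, "total": self.total,
                "lambdas": list(self.lambdas)}


def cross_entropy(probabilities: Tensor, true_labels: np.ndarray) -> Tensor:
    """Mean negative log probability of the true class over the batch.

    Probabilities are clamped at 1e−12 before the log so a zero probability
    on a true class yields a large finite loss rather than an overflow.
    """
    probs = Tensor.as_tensor(probabilities)
    labels = np.asarray(true_labels, dtype=int)
    onehot = np.zeros(probs.shape)
    onehot[np.arange(labels.size), labels] = 1.0
    p_true = (probs * Tensor(onehot)).sum(axis=1)
    return -(p_true.clamp_min(EPS).log().mean())


def recon_loss(x: np.ndarray | Tensor, x_hat: Tensor,
               reduction: str = "sum") -> Tensor:
    """Squared reconstruction error Σ_j (x_j − x̂_j)²."""
    x = Tensor.as_tensor(x)
    x_hat = Tensor.as_tensor(x_hat)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    sq = (x - x_hat) ** 2
    if reduction == "sum":
        return sq.sum()
    if reduction == "mean":
        return sq.mean()
    raise ValueError(f"unknown reduction {reduction!r}")


def reg_loss(params: list[Tensor]) -> Tensor:
    """Squared l2 norm of every learnable scalar."""
    total = Tensor(0.0)
    for p in params:
        total = total + (p**2).sum()
    return total


def total_loss(l_ent: Tensor | float, l_recon: Tensor | float,
               l_reg: Tensor | float,
               lambdas: tuple[float, float, float]) -> Tensor:
    """Weighted sum of the three terms."""
    l1, l2, l3 = (float(v) for v in lambdas)
    if min(l1, l2, l3) < 0:
        raise ValueError("loss weights must be non-negative")
    return (l1 * Tensor.as_tensor(l_ent) + l2 * Tensor.as_tensor(l_recon)
            + l3 * Tensor.as_tensor(l_reg))


def breakdown(l_ent: Tensor, l_recon: Tensor | float, l_reg: Tensor,
              lambdas: tuple[float, float, float]) -> tuple[Tensor, LossBreakdown]:
    """Total loss tensor plus a float record for logging."""
    total = total_loss(l_ent, l_recon, l_reg, lambdas)
    return total, LossBreakdown(
        l_ent=float(Tensor.as_tensor(l_ent).data),
        l_recon=float(Tensor.as_tensor(l_recon).data),
        l_reg=float(Tensor.as_tensor(l_reg).data),
        total=float(total.data),
        lambdas=tuple(float(v) for v in lambdas),
    )
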