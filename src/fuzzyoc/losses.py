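"""Loss functions for fuzzy overclustering.

Three components:

* **cross-entropy** ``CE(p, q) = -sum_c p(c) ln q(c)`` -- the supervised loss
  of the normal (k_GT-way) heads;
* **inverse cross-entropy** ``CE^-1(p, q) = -sum_c p(c) ln(1 - q(c))`` -- the
  supervised loss of the overclustering heads.  It pushes two output
  distributions onto disjoint clusters and is zero exactly when their
  supports are disjoint.  ``1 - q`` is deliberately *not* renormalized into a
  distribution: renormalizing would penalize correct behaviour (a prediction
  split over two clusters against a third one-hot prediction would no longer
  reach zero loss) and would implicitly minimize the entropy of ``p``;
* **mutual information** of the symmetrized joint distribution
  ``P = (Q + Q^T)/2`` with ``Q = (1/n) sum_i phi(x1_i) phi(x2_i)^T``,
  maximized over pairs of views that should share a cluster.  We implement it
  as a *negated* quantity so every loss in the framework is minimized.

The total loss is the weighted sum ``L = lambda_s * Ls + lambda_u * Lu``.

All functions are pure numpy; the ``*_grad`` helpers return analytic
gradients used by the trainer's manual backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossWeights",
    "JointDistribution",
    "cross_entropy",
    "inverse_cross_entropy",
    "ce_inverse_triplet",
    "joint_distribution",
    "mutual_information",
    "combined_loss",
]

DEFAULT_EPS = 1e-6
#: tighter clamp inside the MI logs: joint entries scale like 1/k^2
MI_EPS = 1e-12


@dataclass(frozen=True)
class LossWeights:
    """Weights of the supervised (lambda_s) and unsupervised (lambda_u) terms."""

    lambda_s: float = 1.0
    lambda_u: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_s < 0 or self.lambda_u < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class JointDistribution:
    """Symmetric joint distribution P over cluster pairs, with its marginals."""

    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("P must be a square matrix")
        if np.any(P < -1e-12):
            raise ValueError("P has negative entries")
        if abs(P.sum() - 1.0) > 1e-6:
            raise ValueError("P does not sum to 1")
        if not np.allclose(P, P.T, atol=1e-9):
            raise ValueError("P is not symmetric")
        object.__setattr__(self, "P", P)

    @property
    def marginals(self) -> np.ndarray:
        return self.P.sum(axis=1)

    @property
    def k(self) -> int:
        return self.P.shape[0]


def _check_pair(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    return p, q


def cross_entropy(p_true, q_pred: np.ndarray, eps: float = DEFAULT_EPS) -> float:
    """-sum_c p_true(c) ln q_pred(c), with logs clamped at ``eps``.

    ``p_true`` may be a probability vector or an integer class index.
    """
    q_pred = np.asarray(q_pred, dtype=float)
    if np.isscalar(p_true) or np.ndim(p_true) == 0:
        idx = int(p_true)
        if not 0 <= idx < q_pred.shape[-1]:
            raise ValueError("class index out of range")
        p = np.zeros_like(q_pred)
        p[idx] = 1.0
        p_true = p
    p_true, q_pred = _check_pair(p_true, q_pred)
    return float(-(p_true * np.log(np.maximum(q_pred, eps))).sum())


def inverse_cross_entropy(
    p: np.ndarray, q: np.ndarray, eps: float = DEFAULT_EPS
) -> float:
    """CE^-1(p, q) = -sum_c p(c) ln(1 - q(c)), with 1-q clamped at ``eps``."""
    if not (0.0 < eps <= 1e-3):
        raise ValueError("eps must be in (0, 1e-3]")
    p, q = _check_pair(p, q)
    return float(-(p * np.log(np.maximum(1.0 - q, eps))).sum())


def ce_inverse_triplet(
    out1: np.ndarray,
    out2: np.ndarray,
    out3: np.ndarray,
    eps: float = DEFAULT_EPS,
) -> float:
    """0.5 CE^-1(out1, out3) + 0.5 CE^-1(out2, out3): the per-triplet loss."""
    return 0.5 * inverse_cross_entropy(out1, out3, eps) + 0.5 * inverse_cross_entropy(
        out2, out3, eps
    )


def joint_distribution(
    outputs_a: np.ndarray, outputs_b: np.ndarray
) -> JointDistribution:
    """Batch estimate of the joint cluster distribution of two sets of views.

    Q = (1/n) sum_i outer(a_i, b_i); symmetry is enforced as P = (Q + Q^T)/2.
    """
    a = np.atleast_2d(np.asarray(outputs_a, dtype=float))
    b = np.atleast_2d(np.asarray(outputs_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("outputs_a and outputs_b must have identical shapes")
    if a.shape[0] == 0:
        raise ValueError("empty batch")
    Q = a.T @ b / a.shape[0]
    return JointDistribution((Q + Q.T) / 2.0)


def mutual_information(P: JointDistribution | np.ndarray, eps: float = MI_EPS) -> float:
    """I(z, z') = sum_cc' P_cc' ln( P_cc' / (P_c P_c') ), 0 ln 0 := 0."""
    if not isinstance(P, JointDistribution):
        P = JointDistribution(P)
    M = P.P
    m = P.marginals
    logs = np.log(np.maximum(M, eps)) - np.log(np.maximum(np.outer(m, m), eps))
    return float((M * logs).sum())


def mutual_information_grad(P: np.ndarray, eps: float = MI_EPS) -> np.ndarray:
    """dI/dP for a symmetric normalized P (marginals treated as functions of P).

    dI/dP_ab = ln P_ab - ln P_a - ln P_b - 1.
    """
    m = P.sum(axis=1)
    return (
        np.log(np.maximum(P, eps))
        - np.log(np.maximum(m, eps))[:, None]
        - np.log(np.maximum(m, eps))[None, :]
        - 1.0
    )


def combined_loss(Ls: float, Lu: float, w: LossWeights = LossWeights()) -> float:
    """L = lambda_s * Ls + lambda_u * Lu."""
    return w.lambda_s * Ls + w.lambda_u * Lu


# ---------------------------------------------------------------------------
# batched values + gradients used by the trainer


def batch_cross_entropy(
    probs: np.ndarray, labels: np.ndarray, eps: float = DEFAULT_EPS
) -> tuple[float, np.ndarray]:
    """Mean CE over rows of ``probs`` against integer ``labels``; grad wrt probs."""
    n, _ = probs.shape
    picked = probs[np.arange(n), labels]
    loss = float(-np.log(np.maximum(picked, eps)).mean())
    grad = np.zeros_like(probs)
    # grad of the clamped log: zero where the clamp is active
    live = picked > eps
    grad[np.arange(n)[live], labels[live]] = -1.0 / (picked[live] * n)
    return loss, grad


def batch_cross_entropy_logits(
    probs: np.ndarray, labels: np.ndarray, eps: float = DEFAULT_EPS
) -> tuple[float, np.ndarray]:
    """Mean CE with the fused softmax gradient (probs - onehot) / n.

    Unlike the clamped probability-space gradient, the fused form never
    vanishes when a head saturates on the wrong class, so training can
    recover from confidently wrong predictions.
    """
    n, k = probs.shape
    picked = probs[np.arange(n), labels]
    loss = float(-np.log(np.maximum(picked, eps)).mean())
    grad_logits = probs.copy()
    grad_logits[np.arange(n), labels] -= 1.0
    return loss, grad_logits / n


def batch_inverse_cross_entropy(
    p: np.ndarray, q: np.ndarray, eps: float = DEFAULT_EPS
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean CE^-1 over paired rows; gradients wrt p and q."""
    n = p.shape[0]
    one_minus = np.maximum(1.0 - q, eps)
    log_om = np.log(one_minus)
    loss = float(-(p * log_om).sum() / n)
    grad_p = -log_om / n
    live = (1.0 - q) > eps
    grad_q = np.where(live, p / one_minus, 0.0) / n
    return loss, grad_p, grad_q


def batch_mi_loss(
    a: np.ndarray, b: np.ndarray, eps: float = MI_EPS
) -> tuple[float, np.ndarray, np.ndarray]:
    """Negated mutual information of the batch joint; gradients wrt a and b."""
    n = a.shape[0]
    Q = a.T @ b / n
    P = (Q + Q.T) / 2.0
    m = P.sum(axis=1)
    logm = np.log(np.maximum(m, eps))
    logs = np.log(np.maximum(P, eps)) - logm[:, None] - logm[None, :]
    mi = float((P * logs).sum())
    dI_dP = logs - 1.0
    # loss = -I; P = (Q + Q^T)/2 with dI/dP symmetric, so dL/dQ = -dI/dP
    dL_dQ = -dI_dP
    grad_a = b @ dL_dQ.T / n
    grad_b = a @ dL_dQ / n
    return -mi, grad_a, grad_b
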