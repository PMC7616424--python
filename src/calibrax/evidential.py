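"""Dirichlet-evidence classification head and its training loss.

An evidential classifier maps logits to nonnegative per-class *evidence*
``e``; the Dirichlet concentration parameters are ``alpha = e + 1`` and the
Dirichlet strength ``S = sum_k alpha_k``.  From these follow the belief
masses ``b_k = e_k / S``, the *vacuity* (total-ignorance uncertainty)
``u = K / S``, and the expected class probabilities ``p_k = alpha_k / S``.
By construction ``u + sum_k b_k = 1`` and ``sum_k p_k = 1``.

Training minimizes the expected mean-squared-error Bayes risk under the
Dirichlet plus an annealed KL penalty that pushes *misleading* evidence
(evidence for wrong classes) back toward the uniform Dirichlet.  The
annealing coefficient is ``lambda_t = min(1, epoch / annealing_factor)``;
an annealing factor of 0 disables annealing (``lambda_t = 1`` throughout).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special as sp

from .nn.autodiff import Tensor, as_tensor

__all__ = [
    "DirichletOutput",
    "EnnLossConfig",
    "evidence_from_logits",
    "kl_dirichlet_uniform",
    "enn_loss",
    "predict",
]


class DirichletOutput:
    """Per-sample Dirichlet evidence and its derived quantities.

    Fields are autodiff Tensors so losses built from them are
    differentiable; the ``*_np`` properties give plain arrays.
    """

    def __init__(self, evidence: Tensor):
        evidence = as_tensor(evidence)
        if evidence.ndim != 2:
            raise ValueError("evidence must have shape (n, K)")
        if np.any(evidence.data < 0):
            raise ValueError("evidence must be nonnegative")
        self.evidence = evidence
        self.num_classes = evidence.shape[1]
        self.alpha = evidence + 1.0
        self.strength = self.alpha.sum(axis=1, keepdims=True)  # (n, 1)
        self.belief = self.evidence / self.strength
        self.vacuity = float(self.num_classes) / self.strength  # (n, 1)
        self.expected_prob = self.alpha / self.strength

    @property
    def alpha_np(self) -> np.ndarray:
        return self.alpha.data

    @property
    def strength_np(self) -> np.ndarray:
        return self.strength.data.ravel()

    @property
    def belief_np(self) -> np.ndarray:
        return self.belief.data

    @property
    def vacuity_np(self) -> np.ndarray:
        return self.vacuity.data.ravel()

    @property
    def expected_prob_np(self) -> np.ndarray:
        return self.expected_prob.data

    def __len__(self) -> int:
        return self.evidence.shape[0]


@dataclass(frozen=True)
class EnnLossConfig:
    """Evidential-loss schedule.

    annealing_factor : number of epochs over which the KL weight ramps
        from 0 to 1; 0 means the KL term is active at full weight from the
        start.  This is the tunable "scaling factor" searched over [0, 40].
    """

    annealing_factor: float = 10.0
    current_epoch: int = 0
    loss_variant: str = "expected-mse"

    def annealing_coefficient(self) -> float:
        if self.annealing_factor < 0:
            raise ValueError("annealing_factor must be nonnegative")
        if self.annealing_factor == 0:
            return 1.0
        return min(1.0, self.current_epoch / self.annealing_factor)


def evidence_from_logits(logits) -> DirichletOutput:
    """Map raw logits to nonnegative evidence via softplus."""
    logits = as_tensor(logits)
    bad = ~np.isfinite(logits.data)
    if bad.any():
        idx = int(np.flatnonzero(bad.any(axis=tuple(range(1, logits.ndim))))[0])
        raise ValueError(f"non-finite logits at sample index {idx}")
    if logits.ndim != 2 or logits.shape[1] < 2:
        raise ValueError("logits must have shape (n, K) with K >= 2")
    return DirichletOutput(logits.softplus())


def kl_dirichlet_uniform(alpha: Tensor) -> Tensor:
    """Closed-form KL( Dir(alpha) || Dir(1, ..., 1) ), per sample.

    KL = ln Gamma(S) - sum_k ln Gamma(alpha_k) - ln Gamma(K)
         + sum_k (alpha_k - 1) (psi(alpha_k) - psi(S))
    """
    alpha = as_tensor(alpha)
    k = alpha.shape[1]
    s = alpha.sum(axis=1, keepdims=True)
    term = ((alpha - 1.0) * (alpha.digamma() - s.digamma())).sum(axis=1)
    return s.gammaln().reshape(-1) - alpha.gammaln().sum(axis=1) - float(sp.gammaln(k)) + term


def enn_loss(out: DirichletOutput, labels_onehot, cfg: EnnLossConfig) -> Tensor:
    """Expected-MSE evidential loss with annealed KL on misleading evidence.

    Per sample: sum_k (y_k - p_k)^2  +  sum_k p_k (1 - p_k) / (S + 1)
                + lambda_t * KL( Dir(alpha~) || Dir(1) ),
    where alpha~ = y + (1 - y) * alpha removes the true-class evidence so
    only evidence for wrong classes is penalized.  Returns the batch mean.
    """
    y = as_tensor(labels_onehot)
    if y.shape != tuple(out.expected_prob.shape):
        raise ValueError(
            f"labels shape {y.shape} does not match output shape {tuple(out.expected_prob.shape)}"
        )
    if cfg.loss_variant != "expected-mse":
        raise ValueError(f"unknown loss variant {cfg.loss_variant!r}")
    p = out.expected_prob
    s = out.strength
    err = ((y - p) ** 2).sum(axis=1)
    var = (p * (1.0 - p) / (s + 1.0)).sum(axis=1)
    lam = cfg.annealing_coefficient()
    data_term = (err + var).mean()
    if lam == 0.0:
        return data_term
    alpha_tilde = y + (1.0 - y) * out.alpha
    return data_term + lam * kl_dirichlet_uniform(alpha_tilde).mean()


def predict(out: DirichletOutput, true_labels) -> "PredictionSet":
    """Turn a Dirichlet output into a prediction set for the metrics layer.

    Predicted label is argmax of the expected probability (ties go to the
    lowest class index), confidence its max, uncertainty the vacuity.
    """
    from .metrics import PredictionSet

    p = out.expected_prob_np
    return PredictionSet(
        confidence=p.max(axis=1),
        predicted_label=p.argmax(axis=1),
        true_label=np.asarray(true_labels, dtype=np.int64),
        uncertainty=out.vacuity_np,
    )
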