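"""Accuracy-versus-Uncertainty Calibration (AvUC) auxiliary loss.

The loss partitions a batch into four soft counts — accurate-certain (nAC),
accurate-uncertain (nAU), inaccurate-certain (nIC), inaccurate-uncertain
(nIU) — using an uncertainty threshold u_th, and penalizes the probability
mass in the two miscalibrated cells:

    L_AvUC = log( 1 + (nAU + nIC) / (nAC + nIU) )

A well-calibrated batch (confident when right, uncertain when wrong) gives
zero loss.  The counts weight each sample by its confidence p and a tanh
squashing of its uncertainty u, keeping the loss differentiable in both.
The threshold defaults to the batch-mean uncertainty (self-adaptive), with
a fixed mode for reproducible evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn.autodiff import Tensor, as_tensor

__all__ = ["AvucInputs", "AvucConfig", "soft_counts", "avuc_loss", "uncertainty_for_head"]

_EPS = 1e-8


@dataclass
class AvucConfig:
    """AvUC hyperparameters: the loss weight beta (searched over [0, 4])
    and the thresholding rule for splitting certain from uncertain."""

    weight: float = 1.0
    threshold_mode: str = "batch-mean"
    fixed_threshold: float = 0.5

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("AvUC weight must be nonnegative")
        if self.threshold_mode not in ("batch-mean", "fixed"):
            raise ValueError("threshold_mode must be 'batch-mean' or 'fixed'")

    def threshold(self, uncertainty: np.ndarray) -> float:
        if self.threshold_mode == "fixed":
            return float(self.fixed_threshold)
        return float(np.mean(uncertainty))


class AvucInputs:
    """Per-sample confidence, uncertainty, correctness and the threshold.

    confidence and uncertainty may be autodiff Tensors (gradients flow
    through them); correctness is a fixed 0/1 indicator.
    """

    def __init__(self, confidence, uncertainty, correct, threshold: float):
        self.confidence = as_tensor(confidence)
        self.uncertainty = as_tensor(uncertainty)
        self.correct = np.asarray(correct, dtype=np.float64).ravel()
        self.threshold = float(threshold)
        n = self.correct.size
        if n == 0:
            raise ValueError("AvUC requires a non-empty batch")
        if self.confidence.size != n or self.uncertainty.size != n:
            raise ValueError("confidence, uncertainty and correct must share length n")
        if not np.all(np.isin(self.correct, (0.0, 1.0))):
            raise ValueError("correct must be a 0/1 indicator")
        c = self.confidence.data
        u = self.uncertainty.data
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(u))):
            raise ValueError("confidence/uncertainty must be finite")
        # 1e-9 slack absorbs round-off in entropies computed at the uniform limit
        if np.any(c <= 0) or np.any(c > 1 + 1e-9) or np.any(u < -1e-9) or np.any(u > 1 + 1e-9):
            raise ValueError("confidence must lie in (0,1] and uncertainty in [0,1]")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


def soft_counts(inp: AvucInputs) -> tuple[Tensor, Tensor, Tensor, Tensor]:
    """Soft cell counts (nAC, nAU, nIC, nIU).

    nAC = sum over correct, certain   of p * (1 - tanh u)
    nAU = sum over correct, uncertain of p * tanh u
    nIC = sum over wrong,   certain   of (1 - p) * (1 - tanh u)
    nIU = sum over wrong,   uncertain of (1 - p) * tanh u
    """
    p, u = inp.confidence.reshape(-1), inp.uncertainty.reshape(-1)
    acc = inp.correct
    certain = (u.data <= inp.threshold).astype(np.float64)
    tanh_u = u.tanh()
    n_ac = (p * (1.0 - tanh_u) * (acc * certain)).sum()
    n_au = (p * tanh_u * (acc * (1.0 - certain))).sum()
    n_ic = ((1.0 - p) * (1.0 - tanh_u) * ((1.0 - acc) * certain)).sum()
    n_iu = ((1.0 - p) * tanh_u * ((1.0 - acc) * (1.0 - certain))).sum()
    return n_ac, n_au, n_ic, n_iu


def avuc_loss(inp: AvucInputs) -> Tensor:
    """log(1 + (nAU + nIC) / (nAC + nIU + eps)); zero iff nAU + nIC = 0."""
    n_ac, n_au, n_ic, n_iu = soft_counts(inp)
    if all(float(t.data) == 0.0 for t in (n_ac, n_au, n_ic, n_iu)):
        warnings.warn("degenerate AvUC batch: all four soft counts are zero", stacklevel=2)
        return Tensor(0.0)
    return (1.0 + (n_au + n_ic) / (n_ac + n_iu + _EPS)).log()


def uncertainty_for_head(output) -> np.ndarray | Tensor:
    """Per-sample uncertainty in [0, 1] for either head.

    SoftMax head (probability array/Tensor of shape (n, K)): normalized
    predictive entropy H(p) / log K.  Evidential head (DirichletOutput):
    the vacuity u = K / S.
    """
    from .evidential import DirichletOutput

    if isinstance(output, DirichletOutput):
        return output.vacuity.reshape(-1)
    probs = as_tensor(output)
    if probs.ndim != 2:
        raise ValueError("probabilities must have shape (n, K)")
    k = probs.shape[1]
    p = probs.clip_min(1e-12)
    ent = -(p * p.log()).sum(axis=1) / np.log(k)
    return ent
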