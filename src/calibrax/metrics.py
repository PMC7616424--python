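"""Calibration metrics: ECE, adaptive (equal-mass) ECE, reliability diagrams.

A model is calibrated when its confidence matches its empirical accuracy:
among predictions made with confidence 0.8, about 80% should be correct.
Both metrics bin predictions by confidence and average the per-bin gap
|accuracy_b - mean_confidence_b| weighted by bin occupancy:

    ECE  — B equal-width bins partitioning (0, 1]
    AECE — B equal-mass bins: predictions sorted by confidence and split
           into contiguous groups whose sizes differ by at most one

Equal-mass binning keeps every bin populated, which matters when a model's
confidences concentrate near 1.  With B = 1 both metrics collapse to
|overall accuracy - overall mean confidence|.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PredictionSet",
    "CalibrationBin",
    "CalibrationReport",
    "accuracy",
    "ece",
    "adaptive_ece",
    "reliability_diagram",
    "report_from_table",
]


@dataclass
class PredictionSet:
    """Per-sample confidences, labels and (optionally) uncertainties."""

    confidence: np.ndarray
    predicted_label: np.ndarray
    true_label: np.ndarray
    uncertainty: np.ndarray | None = None

    def __post_init__(self):
        self.confidence = np.asarray(self.confidence, dtype=np.float64).ravel()
        self.predicted_label = np.asarray(self.predicted_label, dtype=np.int64).ravel()
        self.true_label = np.asarray(self.true_label, dtype=np.int64).ravel()
        n = self.confidence.size
        if n < 1:
            raise ValueError("a prediction set needs at least one sample")
        if self.predicted_label.size != n or self.true_label.size != n:
            raise ValueError("confidence and label arrays must share length")
        if np.any(self.confidence <= 0) or np.any(self.confidence > 1):
            raise ValueError("confidences must lie in (0, 1]")
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=np.float64).ravel()
            if self.uncertainty.size != n:
                raise ValueError("uncertainty must share length with confidence")

    @property
    def correct(self) -> np.ndarray:
        return (self.predicted_label == self.true_label).astype(np.float64)

    def __len__(self) -> int:
        return self.confidence.size

    def to_frame(self) -> pd.DataFrame:
        d = {
            "confidence": self.confidence,
            "predicted_label": self.predicted_label,
            "true_label": self.true_label,
        }
        if self.uncertainty is not None:
            d["uncertainty"] = self.uncertainty
        return pd.DataFrame(d)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PredictionSet":
        return cls(
            df["confidence"].to_numpy(),
            df["predicted_label"].to_numpy(),
            df["true_label"].to_numpy(),
            df["uncertainty"].to_numpy() if "uncertainty" in df else None,
        )


@dataclass(frozen=True)
class CalibrationBin:
    count: int
    mean_confidence: float
    accuracy: float
    lower_edge: float
    upper_edge: float


@dataclass
class CalibrationReport:
    bins: list[CalibrationBin]
    scalar_error: float
    scheme: str
    num_bins: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_index": np.arange(len(self.bins)),
                "lower_edge": [b.lower_edge for b in self.bins],
                "upper_edge": [b.upper_edge for b in self.bins],
                "count": [b.count for b in self.bins],
                "mean_confidence": [b.mean_confidence for b in self.bins],
                "accuracy": [b.accuracy for b in self.bins],
            }
        )


def accuracy(preds: PredictionSet) -> float:
    """Fraction of predictions whose label matches the truth."""
    return float(preds.correct.mean())


def _scalar_error(bins: list[CalibrationBin], n: int) -> float:
    return float(
        sum(b.count / n * abs(b.accuracy - b.mean_confidence) for b in bins if b.count)
    )


def ece(preds: PredictionSet, num_bins: int = 15) -> CalibrationReport:
    """Expected calibration error over equal-width confidence bins.

    Bins are the B intervals ((i)/B, (i+1)/B] partitioning (0, 1]; empty
    bins contribute zero to the scalar error.
    """
    if num_bins < 1:
        raise ValueError("num_bins must be >= 1")
    n = len(preds)
    conf, corr = preds.confidence, preds.correct
    # confidence c falls in bin ceil(c*B) - 1
    idx = np.clip(np.ceil(conf * num_bins).astype(int) - 1, 0, num_bins - 1)
    bins = []
    for b in range(num_bins):
        sel = idx == b
        cnt = int(sel.sum())
        bins.append(
            CalibrationBin(
                count=cnt,
                mean_confidence=float(conf[sel].mean()) if cnt else 0.0,
                accuracy=float(corr[sel].mean()) if cnt else 0.0,
                lower_edge=b / num_bins,
                upper_edge=(b + 1) / num_bins,
            )
        )
    return CalibrationReport(bins, _scalar_error(bins, n), "equal-width", num_bins)


def adaptive_ece(preds: PredictionSet, num_bins: int = 15) -> CalibrationReport:
    """Adaptive ECE: equal-mass bins over confidence-sorted predictions.

    The sort is stable, so samples tied in confidence at a bin boundary go
    to the earlier bin; bin sizes differ by at most one.
    """
    if num_bins < 1:
        raise ValueError("num_bins must be >= 1")
    n = len(preds)
    if n < num_bins:
        raise ValueError(
            f"adaptive ECE needs n >= num_bins (n={n}, num_bins={num_bins}); use fewer bins"
        )
    order = np.argsort(preds.confidence, kind="stable")
    conf = preds.confidence[order]
    corr = preds.correct[order]
    # first (n mod B) bins take the extra sample
    base, extra = divmod(n, num_bins)
    sizes = np.full(num_bins, base)
    sizes[:extra] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    bins = []
    for b in range(num_bins):
        a, z = edges[b], edges[b + 1]
        bins.append(
            CalibrationBin(
                count=int(z - a),
                mean_confidence=float(conf[a:z].mean()),
                accuracy=float(corr[a:z].mean()),
                lower_edge=float(conf[a]),
                upper_edge=float(conf[z - 1]),
            )
        )
    return CalibrationReport(bins, _scalar_error(bins, n), "equal-mass", num_bins)


def report_from_table(df: pd.DataFrame, scheme: str = "equal-mass") -> CalibrationReport:
    """Rebuild a report from its bin table (e.g. a reliability-diagram CSV)."""
    bins = [
        CalibrationBin(
            count=int(r["count"]),
            mean_confidence=float(r["mean_confidence"]),
            accuracy=float(r["accuracy"]),
            lower_edge=float(r["lower_edge"]),
            upper_edge=float(r["upper_edge"]),
        )
        for _, r in df.sort_values("bin_index").iterrows()
    ]
    n = sum(b.count for b in bins)
    return CalibrationReport(bins, _scalar_error(bins, n), scheme, len(bins))


def reliability_diagram(report: CalibrationReport, path: str | Path) -> tuple[Path, Path]:
    """Write a reliability diagram (PNG) and its bin table (CSV sidecar).

    Bars show per-bin accuracy at the bin's mean confidence; the diagonal
    marks perfect calibration.  The figure can be regenerated losslessly
    from the CSV via :func:`report_from_table`.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    csv_path = path.with_suffix(".csv")
    report.to_frame().to_csv(csv_path, index=False)

    fig, ax = plt.subplots(figsize=(4, 4))
    width = 0.9 / max(report.num_bins, 1)
    for b in report.bins:
        x = b.mean_confidence if b.count else (b.lower_edge + b.upper_edge) / 2
        ax.bar(x, b.accuracy, width=width, color="#4878cf", edgecolor="k", alpha=0.8)
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="perfect calibration")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("confidence")
    ax.set_ylabel("accuracy")
    ax.set_title(f"{report.scheme} ({report.num_bins} bins), error={report.scalar_error:.3f}")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path, csv_path
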