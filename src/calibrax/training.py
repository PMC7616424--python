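"""Model fitting, grid search and the noise-sweep experiment driver.

The surface follows the familiar model/results split: an
:class:`ImageClassifier` is built from data plus a :class:`TrainConfig`,
its :meth:`~ImageClassifier.fit` returns a :class:`TrainingResults` object
carrying the fitted network, the per-epoch loss log and evaluation helpers,
and :func:`grid_search` / :func:`noise_sweep` drive repeated fits.

The four method variants form a 2x2 design over {SoftMax, evidential} heads
and {without, with} the AvUC auxiliary term:

    baseline  = softmax head,    cross-entropy
    uvac      = softmax head,    cross-entropy + beta * AvUC
    enn       = evidential head, evidential loss
    enn_uvac  = evidential head, evidential loss + beta * AvUC
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .avuc import AvucConfig, AvucInputs, avuc_loss, uncertainty_for_head
from .evidential import EnnLossConfig, evidence_from_logits, kl_dirichlet_uniform
from .metrics import PredictionSet, accuracy, adaptive_ece, ece
from .nn import Adam, Tensor, build_model
from .synthetic import GeneratorSpec, LabelledImageSet, make_template_dataset

__all__ = [
    "METHODS",
    "TrainConfig",
    "ImageClassifier",
    "TrainingResults",
    "GridSearchResult",
    "grid_search",
    "ExperimentResult",
    "noise_sweep",
]

# the 2x2 design: method name -> (head, use_avuc)
METHODS: dict[str, tuple[str, bool]] = {
    "baseline": ("softmax", False),
    "uvac": ("softmax", True),
    "enn": ("evidential", False),
    "enn_uvac": ("evidential", True),
}


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    The defaults mirror the quick-experiment protocol (learning rate 1e-3,
    10 epochs, batch 128); :meth:`long_protocol` switches to the long-run
    values (1e-3, 200 epochs, batch 16).
    """

    head: str = "softmax"
    use_avuc: bool = False
    avuc_weight: float = 1.0
    avuc_threshold_mode: str = "batch-mean"
    avuc_fixed_threshold: float = 0.5
    enn_annealing_factor: float = 10.0
    capacity: str = "low"
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 128
    seed: int = 0
    num_classes: int = 4

    def __post_init__(self):
        if self.head not in ("softmax", "evidential"):
            raise ValueError("head must be 'softmax' or 'evidential'")
        if self.capacity not in ("low", "high"):
            raise ValueError("capacity must be 'low' or 'high'")
        if self.avuc_weight < 0 or self.enn_annealing_factor < 0:
            raise ValueError("loss hyperparameters must be nonnegative")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")

    @classmethod
    def for_method(cls, method: str, **kwargs) -> "TrainConfig":
        head, use_avuc = METHODS[method]
        return cls(head=head, use_avuc=use_avuc, **kwargs)

    @classmethod
    def long_protocol(cls, **kwargs) -> "TrainConfig":
        kwargs.setdefault("epochs", 200)
        kwargs.setdefault("batch_size", 16)
        return cls(**kwargs)

    @property
    def method(self) -> str:
        for name, (head, use_avuc) in METHODS.items():
            if (head, use_avuc) == (self.head, self.use_avuc):
                return name
        raise AssertionError("unreachable")


def _to_nchw(images: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(images.transpose(0, 3, 1, 2))


def _one_hot(labels: np.ndarray, k: int) -> np.ndarray:
    return np.eye(k)[labels]


class ImageClassifier:
    """A convolutional classifier bound to its training and validation data.

    Parameters
    ----------
    train_set, val_set : LabelledImageSet
    config : TrainConfig
    """

    def __init__(
        self,
        train_set: LabelledImageSet,
        val_set: LabelledImageSet | None,
        config: TrainConfig,
    ):
        if train_set.num_classes != config.num_classes:
            raise ValueError(
                f"config.num_classes={config.num_classes} but data has {train_set.num_classes}"
            )
        self.train_set = train_set
        self.val_set = val_set
        self.config = config
        h, w, c = train_set.images.shape[1:]
        self.input_shape = (h, w, c)

    # -- loss assembly --------------------------------------------------
    def _batch_loss(self, network, xb: np.ndarray, yb: np.ndarray, epoch: int):
        cfg = self.config
        k = cfg.num_classes
        y1h = _one_hot(yb, k)
        logits = network(Tensor(xb))
        kl_component = 0.0
        if cfg.head == "softmax":
            logp = logits.log_softmax(axis=1)
            base = -(Tensor(y1h) * logp).sum(axis=1).mean()
            probs = logp.exp()
            conf = probs.max(axis=1)
            unc = uncertainty_for_head(probs)
            pred = probs.data.argmax(axis=1)
        else:
            out = evidence_from_logits(logits)
            ecfg = EnnLossConfig(cfg.enn_annealing_factor, epoch)
            lam = ecfg.annealing_coefficient()
            p = out.expected_prob
            err = ((Tensor(y1h) - p) ** 2).sum(axis=1)
            var = (p * (1.0 - p) / (out.strength + 1.0)).sum(axis=1)
            data_term = (err + var).mean()
            if lam > 0:
                alpha_tilde = Tensor(y1h) + (1.0 - Tensor(y1h)) * out.alpha
                kl_term = lam * kl_dirichlet_uniform(alpha_tilde).mean()
                base = data_term + kl_term
                kl_component = float(kl_term.data)
            else:
                base = data_term
            conf = p.max(axis=1)
            unc = out.vacuity.reshape(-1)
            pred = p.data.argmax(axis=1)
        avuc_component = 0.0
        total = base
        if cfg.use_avuc and cfg.avuc_weight > 0:
            acfg = AvucConfig(cfg.avuc_weight, cfg.avuc_threshold_mode, cfg.avuc_fixed_threshold)
            u_th = acfg.threshold(unc.data)
            correct = (pred == yb).astype(float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                la = avuc_loss(AvucInputs(conf, unc, correct, u_th))
            total = base + cfg.avuc_weight * la
            avuc_component = float(la.data)
        return total, float(base.data), avuc_component, kl_component

    def fit(self, verbose: bool = False) -> "TrainingResults":
        """Train the network with Adam; returns the results object.

        Raises RuntimeError if the loss becomes non-finite, naming the
        epoch and offending component.
        """
        cfg = self.config
        # float32 end to end: halves the BLAS and copy cost of conv layers
        network = build_model(
            cfg.capacity, self.input_shape, cfg.num_classes, seed=cfg.seed, dtype=np.float32
        )
        opt = Adam(network.parameters(), lr=cfg.learning_rate)
        x_all = _to_nchw(self.train_set.images).astype(np.float32)
        y_all = self.train_set.labels
        n = len(y_all)
        rng = np.random.default_rng([cfg.seed, 977])
        rows = []
        t0 = time.perf_counter()
        network.train()
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            sums = np.zeros(4)
            nb = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                total, base_v, avuc_v, kl_v = self._batch_loss(
                    network, x_all[idx], y_all[idx], epoch
                )
                tv = float(total.data)
                for name, v in (("total", tv), ("base", base_v), ("avuc", avuc_v)):
                    if not np.isfinite(v):
                        raise RuntimeError(
                            f"training diverged at epoch {epoch}: non-finite {name} loss"
                        )
                opt.zero_grad()
                total.backward()
                opt.step()
                sums += (tv, base_v, avuc_v, kl_v)
                nb += 1
            rows.append(
                {
                    "epoch": epoch,
                    "total_loss": sums[0] / nb,
                    "base_loss": sums[1] / nb,
                    "avuc_loss": sums[2] / nb,
                    "kl_component": sums[3] / nb,
                }
            )
            if verbose:
                print(
                    f"epoch {epoch:3d}  total {rows[-1]['total_loss']:.4f}  "
                    f"base {rows[-1]['base_loss']:.4f}  avuc {rows[-1]['avuc_loss']:.4f}"
                )
        network.eval()
        return TrainingResults(
            model=self,
            network=network,
            log=pd.DataFrame(rows),
            fit_seconds=time.perf_counter() - t0,
        )


@dataclass
class TrainingResults:
    """Fitted classifier: network weights, training log and evaluation."""

    model: ImageClassifier
    network: object
    log: pd.DataFrame
    fit_seconds: float

    def predict(self, dataset: LabelledImageSet, batch_size: int = 256) -> PredictionSet:
        """Forward the dataset in evaluation mode and package predictions.

        Confidence is the max expected probability under the configured
        head; uncertainty is the normalized predictive entropy (SoftMax)
        or the Dirichlet vacuity (evidential).
        """
        cfg = self.model.config
        dtype = next(iter(self.network.parameters())).data.dtype
        x = _to_nchw(dataset.images).astype(dtype)
        confs, preds, uncs = [], [], []
        self.network.eval()
        for start in range(0, len(x), batch_size):
            logits = self.network(Tensor(x[start : start + batch_size]))
            if cfg.head == "softmax":
                probs = logits.log_softmax(axis=1).exp().data
                unc = uncertainty_for_head(probs)
                unc = unc.data if isinstance(unc, Tensor) else unc
            else:
                out = evidence_from_logits(logits.detach())
                probs = out.expected_prob_np
                unc = out.vacuity_np
            confs.append(probs.max(axis=1))
            preds.append(probs.argmax(axis=1))
            uncs.append(np.asarray(unc).ravel())
        return PredictionSet(
            np.concatenate(confs),
            np.concatenate(preds),
            dataset.labels,
            np.concatenate(uncs),
        )

    def evaluate(self, dataset: LabelledImageSet, num_bins: int = 15) -> dict:
        preds = self.predict(dataset)
        return {
            "accuracy": accuracy(preds),
            "aece": adaptive_ece(preds, num_bins).scalar_error,
            "ece": ece(preds, num_bins).scalar_error,
        }

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Image classifier fit",
            "=" * 44,
            f"method:           {cfg.method} (head={cfg.head}, avuc={cfg.use_avuc})",
            f"capacity:         {cfg.capacity} ({self.network.num_parameters():,} parameters)",
            f"epochs x batch:   {cfg.epochs} x {cfg.batch_size}  (lr={cfg.learning_rate:g})",
            f"fit time:         {self.fit_seconds:.1f} s",
            f"final loss:       total {self.log['total_loss'].iloc[-1]:.4f} "
            f"(base {self.log['base_loss'].iloc[-1]:.4f}, "
            f"avuc {self.log['avuc_loss'].iloc[-1]:.4f})",
        ]
        if self.model.val_set is not None:
            ev = self.evaluate(self.model.val_set)
            lines.append(
                f"validation:       acc {ev['accuracy']:.3f}, AECE {ev['aece']:.3f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# grid search over (AvUC weight, ENN annealing factor)
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    best_beta: float
    best_factor: float
    table: pd.DataFrame


def grid_search(
    config: TrainConfig,
    train_set: LabelledImageSet,
    val_set: LabelledImageSet,
    beta_grid,
    factor_grid,
    scorer=None,
) -> GridSearchResult:
    """Pick the (AvUC weight, annealing factor) pair maximizing validation
    accuracy over the Cartesian grid.

    Grid points must lie in [0, 4] x [0, 40].  Ties break toward the
    smaller weight, then the smaller factor.  ``scorer`` (a callable
    ``(beta, factor) -> float``) replaces the train-and-evaluate step,
    mainly for testing the selection logic.
    """
    beta_grid = sorted(float(b) for b in beta_grid)
    factor_grid = sorted(float(f) for f in factor_grid)
    if not beta_grid or not factor_grid:
        raise ValueError("grids must be non-empty")
    for b in beta_grid:
        if not 0.0 <= b <= 4.0:
            raise ValueError(f"AvUC weight {b} outside the search range [0, 4]")
    for f in factor_grid:
        if not 0.0 <= f <= 40.0:
            raise ValueError(f"annealing factor {f} outside the search range [0, 40]")

    rows = []
    best = None  # (score, beta, factor)
    for b in beta_grid:
        for f in factor_grid:
            if scorer is not None:
                score = float(scorer(b, f))
            else:
                cfg = replace(config, avuc_weight=b, enn_annealing_factor=f)
                res = ImageClassifier(train_set, val_set, cfg).fit()
                score = res.evaluate(val_set)["accuracy"]
            rows.append({"avuc_weight": b, "annealing_factor": f, "val_accuracy": score})
            if best is None or score > best[0]:
                best = (score, b, f)
    return GridSearchResult(best[1], best[2], pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# noise sweep: methods x noise levels x repeated runs
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Per-run records and mean +/- std aggregates of a noise sweep."""

    records: pd.DataFrame  # method, noise_std, seed, accuracy, aece
    runs: int

    def aggregates(self) -> pd.DataFrame:
        g = self.records.groupby(["method", "noise_std"])
        out = g.agg(
            accuracy_mean=("accuracy", "mean"),
            accuracy_std=("accuracy", lambda s: s.std(ddof=0)),
            aece_mean=("aece", "mean"),
            aece_std=("aece", lambda s: s.std(ddof=0)),
            n_runs=("accuracy", "size"),
        ).reset_index()
        return out


def noise_sweep(
    methods,
    noise_levels,
    runs: int,
    base_config: TrainConfig | None = None,
    generator_spec: GeneratorSpec | None = None,
    base_seed: int = 0,
    num_bins: int = 15,
    collect_predictions: bool = False,
) -> ExperimentResult:
    """Train and evaluate every method at every noise level, ``runs`` times.

    Run ``r`` uses seed ``base_seed + r`` for both data generation and
    weight initialization, so re-running the sweep reproduces the
    aggregates.  A failing run is recorded as a warning and excluded; the
    per-cell ``n_runs`` column in the aggregates reports the effective
    count.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    base_config = base_config or TrainConfig()
    generator_spec = generator_spec or GeneratorSpec(num_classes=base_config.num_classes)
    rows = []
    predictions = {}
    for noise in noise_levels:
        if noise < 0:
            raise ValueError("noise levels must be nonnegative")
        for r in range(runs):
            seed = base_seed + r
            spec = replace(generator_spec, noise_std=float(noise), seed=seed)
            train, val, test = make_template_dataset(spec)
            for method in methods:
                head, use_avuc = METHODS[method]
                cfg = replace(base_config, head=head, use_avuc=use_avuc, seed=seed)
                try:
                    res = ImageClassifier(train, val, cfg).fit()
                    preds = res.predict(test)
                    rows.append(
                        {
                            "method": method,
                            "noise_std": float(noise),
                            "seed": seed,
                            "accuracy": accuracy(preds),
                            "aece": adaptive_ece(preds, num_bins).scalar_error,
                        }
                    )
                    if collect_predictions:
                        predictions[(method, float(noise), seed)] = preds
                except Exception as exc:  # warn-and-exclude: sweeps stay resumable
                    warnings.warn(
                        f"run failed (method={method}, noise={noise}, seed={seed}): {exc}",
                        stacklevel=2,
                    )
    result = ExperimentResult(pd.DataFrame(rows), runs)
    if collect_predictions:
        result.predictions = predictions
    return result
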