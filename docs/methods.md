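# Methods

This note records what the toolkit computes, the parameter conventions, how
the synthetic generator is scoped, and the numerical choices that affect
results.

## Model and losses

### Evidential (Dirichlet) head

Logits are mapped to nonnegative evidence with the softplus,
`e = log(1 + exp(z))`. Dirichlet concentration `α = e + 1`, strength
`S = Σ_k α_k`, belief `b_k = e_k / S`, vacuity `u = K / S`, expected class
probability `p̂_k = α_k / S`. By construction `u + Σ b_k = 1` and
`Σ p̂_k = 1`; these identities are enforced by tests.

The training loss is the expected mean-squared-error Bayes risk under the
Dirichlet plus an annealed KL regularizer, averaged over the batch:

```
L_i = Σ_k (y_ik − p̂_ik)²  +  Σ_k p̂_ik (1 − p̂_ik) / (S_i + 1)
      + λ_t · KL( Dir(α̃_i) ‖ Dir(1,…,1) )
```

with `α̃ = y + (1 − y) ⊙ α` (true-class evidence removed, so only
*misleading* evidence is penalized) and `λ_t = min(1, epoch / a)` where `a`
is the annealing factor. `a = 0` is interpreted as "no annealing": the KL
term is active at full weight from epoch 0. The KL against the uniform
Dirichlet is evaluated in closed form via log-gamma and digamma functions;
the implementation is cross-checked in the tests against numerical
integration of the defining integral.

### AvUC auxiliary loss

For per-sample confidence `p`, uncertainty `u`, correctness `c ∈ {0,1}` and
threshold `u_th`, four soft counts are accumulated:

```
n_AC = Σ_{c=1, u ≤ u_th}  p · (1 − tanh u)      accurate & certain
n_AU = Σ_{c=1, u > u_th}  p · tanh u            accurate & uncertain
n_IC = Σ_{c=0, u ≤ u_th}  (1 − p) · (1 − tanh u)  inaccurate & certain
n_IU = Σ_{c=0, u > u_th}  (1 − p) · tanh u      inaccurate & uncertain
```

and the loss is `log(1 + (n_AU + n_IC) / (n_AC + n_IU + 1e-8))`. It is 0
for an all-accurate, fully certain batch and `log 2` when the "bad" and
"good" masses balance. The threshold is the batch mean uncertainty by
default (`threshold_mode="batch-mean"`) or a fixed value. Uncertainty is
the vacuity for the evidential head and the normalized predictive entropy
`H(p) / log K` for the softmax head. A batch in which all four counts
vanish (e.g. confidently wrong everywhere) yields a warning and a zero
loss rather than a division blow-up. The total loss is
`base + β · AvUC` with weight `β ≥ 0`; `β = 0` reduces bitwise to the
corresponding plain method, which is tested.

### Architectures and training protocol

Two capacities: `low` is a LeNet-style network (two 5×5 conv + max-pool
stages, three fully connected layers; needs inputs ≥ 12×12) and `high` an
18-layer residual network (4 stages × 2 basic blocks, widths 16–128,
batch norm, global average pooling). Optimization uses Adam. Protocol
defaults: learning rate 1e-3, 10 epochs, batch 128
(`TrainConfig.long_protocol()` switches to 200 epochs, batch 16). The
hyper-parameter grid search enumerates the Cartesian product of AvUC
weights in [0, 4] and annealing factors in [0, 40], selects by validation
accuracy, and breaks ties toward the smaller weight, then the smaller
factor.

## Calibration metrics

- **ECE** (equal-width): confidence `c ∈ (0, 1]` falls in bin
  `ceil(c·B) − 1` of `B` bins; the score is
  `Σ_b (n_b / n) · |acc_b − conf_b|`. Empty bins contribute zero.
- **AECE** (equal-mass / adaptive): samples are stable-sorted by
  confidence and split into `B` contiguous bins whose sizes differ by at
  most one (the first `n mod B` bins get the extra sample). `B = 1`
  reduces exactly to `|accuracy − mean confidence|`. Requires `n ≥ B`.
- Default `B = 15`. Both implementations are verified against per-sample
  loop oracles to 1e-12, and AECE is checked to shrink toward 0 on
  synthetic perfectly calibrated predictions as `n` grows.
- Reliability diagrams are bar charts of per-bin accuracy vs. mean
  confidence with the identity diagonal; each figure has a CSV sidecar
  (`bin_index, lower_edge, upper_edge, count, mean_confidence, accuracy`)
  from which the scalar error can be reconstructed losslessly.

## Synthetic data generator

The generator exists so that the full training/evaluation protocol can be
exercised and reproduced without external datasets. It is **not** a model
of any real imaging modality; it emulates only the structure the protocol
needs — a multi-class image classification task whose difficulty is
controllable.

- Each class `k` has a fixed oriented-bar template (Gaussian ridge,
  σ = 0.06 in unit coordinates) at angle `kπ/K`; odd classes additionally
  carry a ring (radius 0.3) so templates are not related by rotation
  alone.
- `class_separation ∈ (0, 1]` shrinks all templates toward their common
  mean, moving the classes closer together (1 = fully separated). It is a
  geometry change, not an amplitude change, because per-split intensity
  normalization would cancel pure amplitude scaling.
- Each sample gets ±10% random translation and ±10% amplitude jitter.
  Images are normalized to the *training* split's mean 0 / std 1, then
  i.i.d. Gaussian noise of the requested standard deviation is added,
  unclipped. Noise therefore is expressed in units of the clean signal's
  standard deviation.
- Splits draw from independent seeded substreams
  (`default_rng([seed, split_offset])`), so train/val/test are
  reproducible individually and the test split does not change when the
  training size does.
- A shift-searching nearest-template oracle (maximum Pearson correlation
  over the translation grid) provides a training-free reference: it is
  exact at noise 0 (correlation is invariant to the amplitude jitter) and
  degrades with noise, which bounds what a trained model can be expected
  to do.
- Datasets round-trip losslessly through `.npz`; the PNG-directory format
  quantizes to 16 bits and stores a `manifest.csv` plus `meta.json`.

## Study conditions

The in-repo experiment ("desk scale") uses 4 classes, 28×28 images, 2000
training / 500 validation / 500 test images, noise standard deviations
{0, 2, 4} and 3 seeds per cell. These sizes were chosen so that the full
4-method sweep finishes in ≈ 6–7 minutes on one CPU while still spanning
the interesting regime: at noise 0 the task is cleanly solvable
(baseline ≥ 95% accuracy is an acceptance criterion), at noise 4 accuracy
measurably degrades. The `--full-scale` CLI flag widens this to noise
levels {0, 1, 2, 4} with 10 runs per cell for tighter error bars.

## Numerical choices

- The autodiff engine (`calibrax.nn`) computes in float64 by default;
  training builds models and data in **float32**, which roughly halves the
  convolution (im2col/BLAS) cost with no measurable effect on the
  reported accuracies or AECEs at these problem sizes. Gradient
  correctness is verified in float64 against central finite differences
  (relative error < 1e-3 for losses, ~1e-6 for individual ops).
- Softplus is computed as `logaddexp(0, z)` to avoid overflow; entropies
  clip probabilities at 1e-12 before the log; the AvUC denominator adds
  1e-8.
- `argmax` ties resolve to the lowest class index; max-pool gradients
  split evenly among tied maxima, so gradients stay deterministic.
- Aggregates report population standard deviations (`ddof = 0`) across
  seeds, with the per-cell run count `n_runs` carried alongside.
- All randomness flows from user-provided integer seeds through
  `numpy.random.default_rng` with explicit substream keys; nothing reads
  global RNG state.

## Limitations

- The synthetic task is far easier than natural or medical images: at
  these sizes every method reaches near-perfect accuracy at low noise, so
  between-method calibration differences are small; the toolkit measures
  them but no claim is made that their ordering transfers to real data.
- The AvUC soft counts are piecewise in the threshold: a sample exactly
  at the threshold has a subgradient, and the batch-mean threshold makes
  the loss depend on batch composition.
- Training is single-threaded NumPy; the high-capacity residual network
  is provided and tested for correctness but is slow for sweeps —
  the study conditions use the low-capacity model.
- Long-protocol training (200 epochs, batch 16) is supported but not part
  of the in-repo experiment budget.
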