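# motionssl

Negative-sample-free contrastive self-supervised learning for multimodal
human action recognition from paired **skeleton sequences** (C×T×V joint
coordinates) and **inertial measurement unit signals** (T×S channels).

Labelled multimodal action data is expensive; unlabelled paired recordings
are not. This package learns action representations from unlabelled pairs
and needs labels only to fit a small frozen-encoder classifier head. It is
aimed at researchers in wearable-sensor and motion-capture machine
learning who want a complete, inspectable, CPU-scale implementation of the
negative-free contrastive family for this modality pair.

## The objectives

All losses act on an n×d batch of projected embeddings and avoid negative
pairs by regularising batch statistics instead:

* **Unimodal (redundancy reduction).** Two augmented views of each sample
  pass through a shared encoder and projection head. The between-view
  cross-correlation matrix `C_ij = Σ_b z_{b,i} z'_{b,j} / (‖z_i‖‖z'_j‖)`
  is driven toward the identity by
  `L = Σ_i (1 − C_ii)² + β Σ_{i≠j} C_ij²`.

* **Multimodal (variance / invariance / covariance).** One augmented view
  per modality, modality-specific encoders `f_s`, `f_i` and heads. With
  invariance `s = (1/N) Σ_j ‖z_j^s − z_j^i‖²`, a hinge
  `v(Z) = (1/d) Σ_j max(0, γ − √(Var(z^j)+ε))` keeping every embedding
  dimension's batch std near γ = 1, and the squared off-diagonal
  covariance `c(Z)`, the loss is
  `λ·s + μ·[v(Z^s)+v(Z^i)] + φ·[c(Z^s)+c(Z^i)]` (λ = μ = 25, φ = 1).

Encoders: a 1-D conv + transformer encoder for IMU streams and a
two-stream ("joint" + "motion") 2-D convolutional encoder for skeletons.
Everything — including reverse-mode autodiff, convolutions, attention and
Adam — runs on numpy; see `docs/methods.md` for the full model account.

## Worked example

Synthetic paired data with known class structure stands in for a real
benchmark (no downloads). Five classes, 100 samples each, cross-subject
split; multimodal pretraining with the desk-scale preset, then a frozen
linear evaluation:

```python
from motionssl.synthetic import GeneratorConfig, generate_dataset, split_dataset
from motionssl.pretrain import VICRegPretrainer
from motionssl.evaluate import linear_evaluate, FusionHeadConfig

samples = generate_dataset(GeneratorConfig(seed=28))       # 500 paired samples
train, test = split_dataset(samples, "odd_even_subjects")  # subjects 1,3,5,7 train

model = VICRegPretrainer(epochs=50, batch_size=32, seed=28).fit(train)
report = linear_evaluate(
    {"skeleton": model.encode_skeleton, "imu": model.encode_imu},
    train, test, FusionHeadConfig(),
)
zs, zi = model.embeddings(train)
print(f"accuracy  {report.accuracy:.3f}")
print(f"macro F1  {report.macro_f1:.3f}")
print(f"embedding std (skeleton, imu)  {zs.std(0, ddof=1).mean():.2f}, "
      f"{zi.std(0, ddof=1).mean():.2f}")
```

Output (about a minute on one CPU core):

```
accuracy  0.852
macro F1  0.851
embedding std (skeleton, imu)  1.01, 0.88
```

Accuracy 0.852 against a chance level of 0.20 shows the frozen multimodal
features separate the classes; the same budget with either modality alone
reaches 0.63 (skeleton) / 0.82 (IMU), so the fusion exceeds both. The
per-dimension embedding standard deviations near γ = 1 confirm the
variance term prevented collapse — dropping it (μ = φ = 0) sends them
to ≈ 0.01.

The same pipeline is available from the shell:

```bash
motionssl generate --out data.h5
motionssl pretrain --data data.h5 --mode multimodal --out ckpt/
motionssl evaluate --data data.h5 --ckpt ckpt/ --out report/
motionssl semisup  --data data.h5 --ckpt ckpt/ --out report/
motionssl zeroshot --data data.h5 --hidden 1,2,5 --out report/
motionssl selftest
```

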