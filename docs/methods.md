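# Methods

`motionssl` implements negative-sample-free contrastive self-supervised
learning for paired human-action data: skeleton sequences (C×T×V joint
coordinate tensors) and inertial-sensor signals (T×S channel matrices).
This note records the models, the numerical choices, and what the synthetic
study does and does not demonstrate.

## The two objectives

Both objectives act on an n×d batch of projected embeddings Z and avoid
negative pairs by regularising batch statistics.

**Redundancy reduction (unimodal).** Two augmented views of the same batch
pass through a shared encoder f and projection head g. With per-dimension
mean-centred embeddings, the cross-correlation matrix is

    C_ij = Σ_b z_{b,i} z'_{b,j} / (‖z_{·,i}‖ ‖z'_{·,j}‖),

and the loss is `Σ_i (1 − C_ii)² + β Σ_{i≠j} C_ij²` with β = 0.005 by
default. The diagonal term enforces augmentation invariance; the
off-diagonal term decorrelates embedding dimensions, which is what rules
out the constant (collapsed) solution. Column norms are floored at 1e-12
during training; the standalone operation raises on exact collapse when
called with `strict=True`. Mean-centring before the correlation is the
default and can be disabled (`center=False`) to evaluate the uncentred
variant.

**Variance / invariance / covariance (multimodal).** Each modality has its
own encoder and projection head (no weight sharing). Per batch:

* invariance `s(Z_s, Z_i) = (1/N) Σ_j ‖z_j^s − z_j^i‖²`,
* variance `v(Z) = (1/d) Σ_j max(0, γ − sqrt(Var(z^j) + ε))` with γ = 1,
  ε = 1e-4 and the unbiased (n−1) variance,
* covariance `c(Z) = (1/d) Σ_{i≠j} Cov(Z)_{ij}²`,

combined as `λ·s + μ·[v(Z_s)+v(Z_i)] + φ·[c(Z_s)+c(Z_i)]` with defaults
λ = μ = 25, φ = 1.

**Invariance scaling.** `vicreg_loss` exposes `invariance_scale`:
`"per_sample"` (the definition above; the default for the standalone
function) and `"per_element"`, which divides s by d (mean-squared-error
semantics, the convention of the joint-embedding literature this family of
losses comes from). The distinction matters: under per-sample scaling the
collapse pressure of the invariance term grows linearly with d, and at
d = 32 the equilibrium batch standard deviation settles far below γ — the
variance hinge loses and the embedding collapses. The training loop
(`VICRegPretrainer`) therefore defaults to per-element scaling, under
which the variance target is reached (final per-dimension std ≈ 0.9–1.0
versus ≈ 0.01 for an ablation with μ = φ = 0). Both scalings are tested
against naive reference implementations.

On the weights: φ is fixed at 1 and λ = μ > 1 is the operating condition;
a grid over λ = μ ∈ {5, 10, 25} can be run through the estimator
parameters. (Statements that appear in print as "λ = φ > 1" are treated
as referring to λ = μ, since φ = 1 by construction.)

## Encoders

**IMU encoder.** Three temporal 1-D convolution blocks (kernel 3, channels
[32, 64, 128], batch norm + ReLU), a fixed sinusoidal positional signal,
N = 2 pre-norm transformer blocks (2 heads, feed-forward width 2× the
model dimension), then global average pooling over time. Pre-norm residual
blocks (`x + MHSA(LN(x))`) were chosen over post-norm so that a block with
zeroed output projections is an exact identity — a testable contract.

**Skeleton encoder.** Two streams over (C, T, V) inputs: the *joint*
stream sees raw coordinates, the *motion* stream their temporal first
differences (edge-padded to keep length T). Each stream applies six 2-D
convolution blocks with channels [64, 32, 32, 64, 128, 256]; after block
three the joint axis is transposed into the channel dimension, so early
blocks encode each joint's point-level information independently and late
blocks (stride 2) aggregate across joints globally. The published block
diagram does not fully specify the transpose placement or strides; the
layout here is one consistent reading, fixed and regression-tested via
parameter counts. Streams are fused by concatenating the two pooled
256-vectors and mapping linearly to the hidden width (256 by default,
matching the final convolution width).

**Projection heads.** Linear → batch norm → ReLU → linear, default
[256, 128]; the final layer is purely linear.

## Preprocessing and augmentation

Sequences are linearly resampled onto a fixed 50-step grid (exact on
endpoints and idempotent on the grid). Skeletons are normalised to the
first frame: the reference joint's first-frame position becomes the
origin, and the RMS distance of first-frame joints to that joint becomes
the length unit (translation- and scale-invariant, raises on a degenerate
all-coincident pose). IMU channels are z-scored with training-split
statistics. Linear interpolation and the RMS scale are package choices
where the published procedure says only "resampling" and "scaling".

Skeleton augmentations: jitter (σ = 0.05), scale ([0.8, 1.2]), rotation
(±30° about the origin; random axis for C = 3), shear (±0.2
off-diagonal), temporal crop-and-resize (window ≥ 0.6 of T). IMU
augmentations: jitter, scale, per-triple 3-D rotation (accelerometer /
gyroscope triples), segment permutation (4 blocks), channel shuffle. Each
stage fires with probability 0.5. No magnitudes are prescribed in the
source material; these are conventional values for skeleton/wearable
self-supervision, all configurable.

Multimodal pretraining defaults to a gentler pipeline (probability 0.3,
jitter 0.02, scale [0.9, 1.1], rotation ±10°, shear ±0.1, crop ≥ 0.8):
when the two views are different modalities, the modality gap is already
the dominant view difference, and augmentation applied to one branch is
nuisance variance the other branch cannot mirror — it inflates the
irreducible invariance residual and, through the variance/invariance
balance, lowers the embedding spread. Unimodal two-view pretraining keeps
the stronger pipeline, since there augmentation is the *only* source of
view difference.

## Training

Adam (0.9/0.999, no weight decay, no schedule). Benchmark-scale presets
carry the published settings (unimodal: lr 1e-2, 100 epochs, batch 128;
multimodal: lr 1e-3, 200 epochs, batch 256; and the corresponding second
benchmark profile). The desk-scale preset used by the test suite and the
reproduction script is batch 32, 50 epochs, 32-dimensional embeddings,
learning rate 1e-2, with narrow encoders (IMU channels [16, 32, 64],
model dim 64; skeleton channels [8, 8, 8, 16, 16, 32], hidden 64;
projector [64, 32]) — sized so one pretraining run takes about a minute
on a single CPU core. The last incomplete batch of each epoch is dropped
because both losses are batch-statistics estimators. Labels are never
read during pretraining (enforced by a guard in the tests). All
randomness derives from the seed, so runs are bitwise reproducible;
checkpoints store weights, optimiser moments and the generator state, and
resuming reproduces uninterrupted training exactly.

## Fine-tuning and evaluation

Encoders are frozen; per modality a linear map to 256 with batch norm and
ReLU, concatenation, and a linear softmax classifier. The head trains for
100 epochs with Adam at one-tenth of the pretraining rate. Reported
metrics: accuracy, macro-averaged F1 (macro chosen as the standard for
imbalanced activity recognition; a weighted variant is available), and
the row-normalised confusion matrix (empty rows left zero). Accuracy is
cross-checked against the trace of the raw confusion counts in every
report.

Protocols: *linear evaluation* on the full labelled training split;
*semi-supervised* sweeps p ∈ {1, 5, 10, 25, 50}% with stratified label
draws (each class floored at one sample), 10 repeats by default, and
Student-t confidence intervals over repeats; *zero-shot class masking*
excludes the chosen classes (1-based ids, e.g. [1, 2, 5]) from
pretraining only — fine-tuning and testing see all classes — and
additionally reports recall on the hidden classes. Stratification and the
pretraining-only reading of the masking protocol are package decisions
where the published description is loose. 2-D scatter reporting delegates
to scikit-learn's t-SNE with a fixed seed.

## The synthetic study

Real benchmark data requires external downloads and GPU-scale training,
so the package ships a generator that emulates the *statistical* shape of
a paired-modality action benchmark: each class is a distinct latent
trajectory (sums of three sinusoids per latent channel, class-indexed
frequencies, per-sample phase and amplitude jitter), joints are a base
pose plus fixed linear projections of the latent, subjects add a constant
pose offset (making cross-subject splits meaningful), and IMU channels
are discrete second differences — an acceleration analogue — of a fixed
linear readout of the joint trajectories, with a gain that keeps the
clean signal near unit scale (sensor-calibration analogue), plus a
constant offset and Gaussian noise. With zero noise the IMU is an exact
second difference of a linear readout of the stored skeleton, which the
tests verify against a finite-difference oracle.

Default study conditions: 5 classes, 100 samples per class, 8 subjects,
T = 50, V = 8, C = 2, S = 6, noise σ = 0.25, phase jitter 0.9 rad,
amplitude jitter 0.35, subject offset σ = 0.3. At these settings a
regularised linear classifier on raw flattened skeletons reaches ≈ 0.90
cross-subject accuracy — classes are clearly recoverable but none of the
protocols saturate, so orderings (multimodal above unimodal, more labels
above fewer, non-collapse above ablation) are measurable rather than
degenerate. The generator emulates class structure, cross-modal coupling
and subject variation; it does not emulate biomechanics, forward
kinematics, sensor placement, missing frames or tracking failures, so
passing the suite demonstrates the correctness and qualitative behaviour
of the method, not benchmark-level performance on real recordings.

On one CPU core the full reproduction script (five pretraining runs plus
all evaluations) takes about five to eight minutes.

## Numerical choices and edge cases

Float64 throughout; gradients validated against central finite
differences at 1e-4 relative tolerance (losses, convolution, batch and
layer normalisation). Correlation denominators floored at 1e-12; variance
hinge stabilised by ε inside the square root; softmax max-shifted.
Degenerate inputs raise descriptive errors: sequences shorter than 2 for
resampling, coincident first-frame poses for normalisation, batches
smaller than 2 for any batch-statistic loss, IMU rotation with channel
count not divisible by 3, split rules that empty either side.

## Known limitations

The engine is single-threaded numpy and is not meant for benchmark-scale
training; there is no GPU path, no mixed precision, no learning-rate
schedules. The transformer uses fixed sinusoidal positions and no
dropout. The skeleton encoder layout is one reading of an underspecified
diagram. Zero-shot masking assumes hidden classes are absent from
pretraining but present in fine-tuning, which is one of two defensible
readings of the protocol.
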