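# Methods

## Problem setting

Hippocampal sharp-wave ripples (SWRs) are brief 120–200 Hz oscillations
recorded in CA1 local field potentials. A common analysis task is to decide,
for each detected ripple, whether it was generated before or after an animal
learned a task (the BL/AL session labels). Those session labels are noisy
proxies for what the experimenter actually cares about — whether the ripple
itself was transformed by learning — because memory reactivation before a
session and learning-insensitive ripples after it both decouple the session
of origin from the ripple's intrinsic class. `ripplelabel` implements a
label-noise-correction pipeline for this setting: learn a representation of
the raw windows without using any labels, re-partition the data by
clustering that representation, and measure how much classification accuracy
the new labels restore.

## Synthetic ripple model

Each synthetic window (an RCI, ripple-centered interval) is 512 samples at
2 kHz (256 ms). Its components:

* **Ripple**: `a · g(t) · sin(2π f t + φ)`, where `g` is a Gaussian
  envelope with unit peak at the ripple midpoint and standard deviation
  `duration/6`, so the oscillation visibly rises and decays inside its
  span. Duration is drawn per ripple from 150–200 samples.
* **Background**: one delta sinusoid (1–3 Hz) and one low-gamma sinusoid
  (20–40 Hz) spanning the whole window, each with amplitude 0.3 × the base
  ripple amplitude. The value 0.3 keeps the background visible but
  non-dominant; no measurement constrains it more tightly, so it is a
  declared default (configurable in `SimConfig`).
* **White noise** over the whole window with per-ripple standard deviation
  `0.1 × noise factor`. A `dual_noise` switch additionally re-noises the
  ripple span for users who read the construction as two applications.

Two ripple classes differ only through multiplier ranges applied to the
base frequency (160 Hz), base amplitude (1.0) and base noise (0.1):

| | frequency | amplitude | noise |
|---|---|---|---|
| Class 1 (learning-unaffected) | 0.8–1.2 | 0.8–1.2 | 1.0–1.5 |
| Class 2 (learning-transformed) | 1.1–1.3 | 0.95–1.05 | 0.5–1.0 |

Every "value in a range" is drawn from a normal with mean at the range
midpoint and σ = range/6, truncated to the range (±3σ coverage). All phases
are uniform on [0, 2π).

**A consequence worth stating plainly:** the class noise-factor ranges are
disjoint (1–1.5 vs 0.5–1), and the white-noise level of a 512-sample window
can be estimated very precisely from its high-frequency content. The
two classes are therefore almost perfectly separable by construction, and a
competently trained classifier reaches ≈ 0.99 true-class accuracy on clean
labels at every scale we ran. The pipeline's behaviour under label noise
(degradation, recovery, the high-noise failure regime) does not depend on
where this clean ceiling sits, but absolute clean-label accuracies from
this simulator should be read as a property of the generator, not of the
classifier.

## Label noise

The observed labels BL/AL start equal to the true classes. Mixing at
proportion ρ moves exactly `round(ρ·n)` uniformly chosen Class-1 rows from
BL to AL and the same number of Class-2 rows the other way, so the printed
compositions hold exactly: BL contains (1−ρ) Class 1 + ρ Class 2 and AL the
mirror image, with group sizes unchanged. ρ ranges over [0, 0.5]; at 0.5
the observed labels carry zero information about the true class.

## Self-supervised relabeler

Two stochastic views of each window feed a contrastive model:

* weak view: scale by U(0.9, 1.1) and add N(0, 0.05) jitter;
* strong view: split into 4–8 contiguous segments at uniform cut points,
  permute the segments, add N(0, 0.1) jitter.

The encoder is a three-block 1-D convolutional stack (16/32/32 channels,
kernels 7/5/3, max-pool 4/4/2) mapping 512 samples to T = 16 latent steps of
dimension 32. A single-layer GRU (hidden 64) summarizes a latent sequence
into a context vector.

Two losses are minimized jointly (weights λ₁ = 1, λ₂ = 0.7, adopted from
the temporal/contextual contrasting line of work):

* **Temporal contrasting.** At a random step t, the context of one view
  predicts the other view's latents at t+1 … t+K (K = 4) through per-horizon
  linear heads; each prediction is scored against the whole batch by dot
  product and penalized with softmax cross-entropy. Both directions are
  averaged. Because the GRU is causal, the state at step t of a full-length
  pass equals the context of a truncated pass, so one GRU pass per view
  serves every t.
* **Contextual contrasting.** The two views' contexts pass through a
  two-layer projection head; an NT-Xent loss (temperature 0.2) over cosine
  similarities pulls the 2N projections of the same window together and
  pushes different windows apart.

Training uses Adam (3 × 10⁻⁴), batch 128 (64 at desk scale), and never
reads the observed labels; full-protocol default is 500 epochs.

## Label generation

After training, each window is embedded once in evaluation mode and k-means
with k = 2 (10 restarts, best inertia) partitions the embeddings into G1/G2.
Two design choices here were settled by pilot experiments and deserve
explanation:

* **Embedding space.** The default embedding is the encoder's latent
  sequence averaged over time rather than the GRU context. In pilots the
  context-space clustering was unstable across training stages — the same
  run could yield 0.99 or 0.50 agreement with the hidden truth depending on
  the epoch at which training stopped — while the pooled convolutional
  features clustered reproducibly (≥ 0.99 agreement in every pilot at
  ≥ 400 windows). The context space remains available
  (`embed(..., space="context")`).
* **Whitening.** k-means is run on the top 8 PCA-whitened components of the
  embeddings. Raw contrastive embeddings concentrate most variance on
  directions that do not separate the classes (overall amplitude, phase
  residue); whitening a small leading subspace lets cluster geometry rather
  than raw variance decide the partition, and capping the subspace at 8
  dimensions keeps the distance from being swamped by noise directions when
  only a few hundred windows are available. `whiten_components=None`
  restores plain k-means.

Clusters are renamed so G1 holds the majority of BL rows (ties keep index
order); the 2×2 composition table is reported with both row and column
margins since either normalization is meaningful. The intersection subset
is the rows whose aligned group agrees with their observed label.

## Classifier and evaluation protocol

The supervised model is a 1-D CNN: conv blocks (conv → batch-norm → ReLU →
max-pool 2) followed by dropout 0.5, a dense ReLU layer and a 2-way softmax.
Full-protocol default: 64/128/256 filters with kernels 7/5/3, dense 128,
200 epochs, Adam 10⁻³, batch 128.

Every arm runs inside the same stratified 5-fold cross-validation (folds
stratified on the observed labels): training labels come from the arm —
original BL/AL, clean true-class (ideal arm), aligned G1/G2, or the
intersection rows with their agreed label — and the held-out fold is always
scored against the *original observed labels*, so arms are comparable and
relabeling cannot grade itself. Note the consequence: at mixing proportion
ρ, even a perfect classifier of the true class scores only 1−ρ against the
observed labels; accuracy-versus-truth is reported separately
(`agreement_with_truth`) so the ceiling is measurable rather than implied.

Arms are compared with Welch's unequal-variance two-sided t-test on the
five fold accuracies (or on per-replicate means in the sweep), starred at
0.05/0.01/0.001/0.0001. SEM denotes the standard error over folds.

## Experiments

* **Three-arm comparison** at fixed ρ: noisy, SSL-relabeled and
  intersection arms, all tested on the noisy labels, plus a clean-label
  baseline.
* **Noise sweep** over ρ = 0, 0.1, …, 0.5: an ideal arm (trained on clean
  class labels, tested against labels at ρ — its decay with ρ is purely the
  test-label degradation), the noisy arm, and the SSL arm.

## Desk-scale parameters

All numbers in the test suite and `scripts/acceptance.py` come from reduced
runs chosen so every ratio of the protocol is preserved while a full run
fits on one CPU core:

* fixed-ρ comparisons: 400 windows per class, SSL 25 epochs (batch 64),
  CNN with 4/8/16 filters, dense 32, 25 epochs (batch 32, Adam 3 × 10⁻³);
* noise sweep: 200 windows per class, five replicates per ρ, same SSL
  budget with the CNN trimmed to 20 epochs.

The smaller batch sizes keep the number of gradient updates high enough at
small n for both models to leave their underfit regime; the 25-epoch CNN
budget is long enough that the network substantially fits the flipped
training labels (train accuracy ≈ 0.95–1.0 on mixed labels), which is the
regime in which label noise actually damages held-out accuracy — with
shorter training the small CNN is noise-robust and the degradation the
protocol studies never appears. The `--scale` option of the CLI applies the
same proportional shrinkage to any factor of the full protocol.

## What the simulator does and does not emulate

It reproduces the features the method relies on: a band-limited oscillation
with variable duration inside a fixed analysis window, slow background
rhythms, broadband noise, class structure expressed as distributional
shifts rather than template differences, and exactly controlled label
mixing. It does not attempt sharp-wave deflections, multi-channel
structure, non-stationary background states, artifacts, or inter-animal
variability — so passing results demonstrate that the pipeline recovers
distributional class structure under label noise, not that it handles every
pathology of recorded LFP.

## Numerical infrastructure

The two networks are implemented on a small reverse-mode automatic
differentiation core written on numpy (`ripplelabel.autodiff`,
`ripplelabel.nn`): convolution as shifted GEMMs in channels-last layout
(with an im2col path when the input-feature count is small), tournament
max-pooling, fused batch-norm, a GRU with batched input projections, and
Adam. Gradients of every layer are verified against central finite
differences in the test suite. Training is single-threaded and fully
deterministic given the configuration seeds; k-means and fold splitting use
seeded scikit-learn estimators.

## Known limitations

* The clean-label ceiling of the simulator sits near 1.0 (see above), so
  absolute accuracies are not comparable with recorded-data studies; the
  noise-degradation and recovery *differences* are the meaningful outputs.
* Cluster-based relabeling presumes exactly two groups whose structure
  dominates the embedding geometry; it will mislead when the dominant
  structure is not the label-relevant one, and the whitening default only
  mitigates, not removes, that risk.
* The detection module's thresholds (3 SD detect, 1 SD boundary, 20 ms
  minimum) are standard ripple-detection practice but should be re-tuned
  per recording setup.
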