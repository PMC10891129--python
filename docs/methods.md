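# Methods

## Generative functions and regression data

Four benchmark target functions drive the optimizer study: a line
(F₁ = 0.5 + 0.79x + ε), a saturating exponential (F₂ = 1 − e^(−1/(2x))),
a quadratic (F₃ = 0.7 + 3x² + ε) and the Forrester function
(F₄ = (6x−2)² + sin(12x−4)). The abscissa is drawn i.i.d. uniform and kept
strictly inside (0, 1) so F₂'s domain (x > 0) is always respected.
Gaussian noise with standard deviation 0.2 is added exactly where the
generative definitions carry an error term — F₁ and F₃ — while F₂ and F₄
are deterministic curves. The sample size m defaults to 100: large enough
for stable fits and tight moment checks, small enough that a full
four-function study runs in seconds. Regeneration with the same
(function, m, noise, seed) is bit-identical.

## The three optimizers

All three fitters minimise Q(θ₀, θ₁) = (1/m)Σ(θ₀ + θ₁xᵢ − yᵢ)² from a
U(0,1)² initialisation, with learning rate η = 0.001, at most 3000 epochs,
and termination once the full-data gradient norm ‖∇Q‖ falls to 0.001
(checked before the first epoch and after each epoch).

* **SGD** shuffles the data every epoch and performs one update per
  example, with both parameters updated simultaneously from the
  start-of-step θ. (The update rules are sometimes written as sequential
  assignments; the simultaneous form is the standard reading and the one
  whose expansion matches the per-step residual.)
* **RMSprop** uses shuffled mini-batches of 16, a squared-gradient
  accumulator v ← 0.9·v + 0.1·g² per coordinate, and the step
  θ ← θ − η·g/√(v + ε) with ε = 10⁻⁶ read as an additive guard inside the
  square root.
* **Adam** uses the same batching with first/second-moment accumulators
  (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸) and two bias-correction modes:
  `paper_literal` divides the accumulators by the constants (1−β₁), (1−β₂);
  `time_scaled` divides by (1−β₁ᵗ), (1−β₂ᵗ) as in the standard
  formulation. The modes coincide at t = 1; afterwards the literal mode's
  effective step is smaller by a factor approaching
  √(1−β₂)/(1−β₁) ≈ 0.32. The literal mode is the default.

The inner loops are JIT-compiled (numba) with a fixed scalar operation
order; the test suite locks every step against an independent pure-Python
transcription of the update rules to 10⁻¹⁰ per parameter. Shuffle
randomness is pre-drawn outside the kernels from a dedicated stream, so
initialisation and shuffling are independently reproducible. Non-finite
parameters abort the fit with an error naming the epoch.

## Conformance protocol and what it actually shows

Per study: 9 runs, each with a fresh dataset shared by the three
optimizers, each optimizer with its own initialisation and shuffle
substream derived from the study seed. Conformance between two fitted
models is d(a,b) = √Σᵢ[(xᵢᵃ−xᵢᵇ)² + (zᵢᵃ−zᵢᵇ)²]; with a shared abscissa
the x-terms vanish and d reduces to the Euclidean distance between
prediction vectors (both code paths agree to 10⁻¹², and the general form
is kept for robustness). The two distance samples d_SA and d_SR are
compared with a two-sided Welch t-test — no equal-variance assumption is
defensible for them — with documented conventions for degenerate
zero-variance samples (p = 1 on equal means, p = 0 otherwise).

Measured behaviour at the defaults, which the acceptance suite asserts
per function and which shapes how the results should be read:

* **F1, F3** — all three optimizers reach the ‖∇Q‖ ≤ 10⁻³ stopping
  region of the same least-squares optimum. Both distances are then
  ~10⁻² stopping jitter along the tolerance ellipse, with no systematic
  ordering: across replications d_SA < d_SR holds only about half the
  time and the Welch test is rarely significant. (In the literal Adam
  mode F3 additionally shows Adam *slower* to the boundary — it often
  exhausts the epoch budget — making d_SA modestly larger.)
* **F2** — the ordering d_SA < d_SR with p < 0.05 reproduces in
  essentially every replication: RMSprop systematically stops farther
  from the SGD endpoint on this curve.
* **F4** — the least-squares optimum lies ~11 units from the U(0,1)
  initialisation. RMSprop's normalised step travels ≈ η per update and
  ends 2–3 units short after the 3000-epoch budget; literal-mode Adam
  travels ≈ 0.32η per update and ends 7–9 units short. The ordering
  therefore *reverses* robustly (d_SA ≫ d_SR), and switching Adam to
  `time_scaled` only brings the two shortfalls level, not ordered.

In short, the protocol's conformance ordering is a property of stopping
geometry and per-step travel, not of the optimizers' limiting solutions:
when every optimizer converges, the distances are noise; when none does,
the slower mover loses. The package reports whatever the seeded protocol
produces rather than targeting a particular ordering, and the boxplot and
distance tables make the per-run structure visible.

## Synthetic image corpus

The binary corpus emulates a balanced set of network drawings: per image,
a preferential-attachment (Barabási–Albert) graph with 25–40 nodes, class
distinguished by the attachment parameter (healthy: 2 edges per new node;
T2D: 4 — denser and more hub-dominated; mean edge counts ≈ 62 vs 116, a
classifier-free separability gap that is monotone in the attachment
difference). Layouts come from a spring embedding; nodes and edges are
drawn at 4× resolution and Lanczos-downscaled to a 64×64 anti-aliased
grey raster on white, replicated to 3 channels, values in [0, 1]. The
default corpus holds 224 images, 112 per class; generation is
bit-reproducible under its seed and the corpus round-trips through a
PNG + CSV-manifest layout (8-bit quantisation).

The 4-class source corpus cycles through structurally distinct
generators (trees, dense preferential attachment, Erdős–Rényi,
small-world) and stands in for large-scale natural-image pretraining at
desk scale. What the generator does *not* emulate: the visual texture of
real regulatory-network renderings (edge bundling, node size encoding,
community colouring), biological label noise, or any expression-derived
structure. Passing results show the transfer protocol's mechanics —
freeze semantics, head adaptation, evaluation bookkeeping — and the
benefit of a genuinely pretrained base on *this* family of drawings;
they say nothing about absolute accuracy on real SCGRN data.

## Small CNN and transfer protocol

The backbone is a compact NumPy CNN: three conv blocks (8/16/32 filters,
3×3 kernels, ReLU, 2×2 max pool), global average pooling, one hidden
dense layer of 32 units, dropout 0.5 on that last fully-connected layer,
and a softmax output head; categorical cross-entropy loss. He-normal
initialisation per weight seed. Images enter as ink density
(1 − intensity): with raw near-white inputs the network's activations
are tiny and dropout noise dominates early training, whereas the
inverted input trains reliably within the short budget. Forward and
backward passes are exact im2col/col2im convolutions with max-pool
argmax routing; the test suite checks them against an independent
correlation oracle and numeric gradients.

Transfer regimes: **TFE** freezes every conv block and trains a fresh
2-class head; **TFT** freezes the bottom 2 of 3 blocks (configurable);
**SCRATCH** reinitialises everything. Frozen layers never receive
updates, so their tensors are bit-identical before and after training —
an asserted contract, and in the TFE case the implementation trains the
head on once-extracted features (the identical computation minus
redundant frozen-base passes). Head adaptation replaces the dense head
with a freshly seeded one of the requested width while leaving the conv
base untouched. Predictions map the softmax healthy-class score through
a strict 0.5 threshold (score > 0.5 → healthy, else T2D); the class
order (T2D = 0, healthy = 1) fixes which output is thresholded.

Training budgets: the evaluation protocol's reference settings are 10
epochs, batch 32, categorical cross-entropy; the reference learning rate
of 10⁻⁵ targets very large pretrained backbones, so the small CNN uses
10⁻³ in the same budget (`small_cnn_training`). Source-task pretraining
runs 40 epochs at 10⁻³ on a 240-image 4-class corpus
(`source_training`), long enough for source accuracy to plateau well
above the 0.25 chance level (~0.83); a barely-trained source base would
make "transfer" an empty control. The trainers implement mini-batch
SGD/RMSprop/Adam with standard accumulator constants; training is
deterministic under its seed.

## Evaluation

Confusion matrices take healthy as the positive class. BAC, ACC, PRE,
REC and F1 follow their standard formulas exactly; any metric with a
zero denominator is reported as NaN and named in an `undefined` set,
never silently zeroed (visible in practice when an SGD-trained head
predicts no positives in a fold). Five-fold cross-validation assigns
images to folds by a uniform random permutation chunked into sizes
differing by at most one (224 → 45/45/45/45/44); an optional stratified
mode exists but is off by default. Each fold serves once as the test
set; fold metrics are averaged arithmetically and fold confusion
matrices sum to a combined matrix whose total equals the corpus size —
each image tested exactly once. The seed-averaged transfer-benefit
comparison evaluates one held-out fold per seed (`holdout_bac`) for
TFE vs SCRATCH over three seeds.

## Numerical and design notes

* Problem sizes throughout (m = 100, 9 runs, 224 images at 64 px, 240
  source images) are the study's defaults, chosen so every analysis runs
  in minutes on one CPU core.
* Seed handling uses `numpy` `SeedSequence` substreams: every dataset,
  initialisation, shuffle, layout and training run has its own
  reproducible stream derived from one base seed.
* Degenerate inputs are rejected loudly: m < 2 regression datasets, odd
  balanced corpus sizes, images under 32 px, empty corpora, invalid
  dropout rates, TFT freeze counts that would freeze everything, and
  scores outside [0, 1] all raise errors.
* Known limitations: the CNN has no batch-norm or augmentation and is
  not meant to approach state-of-the-art image classification; the
  corpus's class gap is deliberately generous, so scratch training also
  scores highly and the transfer comparison is read as "at least as
  good", not as a large-margin claim; and the conformance ordering, as
  analysed above, is reproduced as a robust property only for F₂.
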