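# Methods

`cardiosemi` implements a semi-supervised training framework for 2-D
multi-class segmentation built from four cooperating pieces: a mean-teacher
pair of U-Nets, a dynamic pseudo-label threshold map (DPTM) that decides
which teacher predictions may supervise the student, a robust
(confidence-weighted) pseudo-label loss, and a contrastive consistency
regulariser on encoder embeddings. Everything runs on CPU on a built-in
synthetic cardiac phantom task, so each equation in the pipeline is
exercised and testable end-to-end without external data.

## Model

**Teacher–student coupling.** Two structurally identical U-Nets. The
student is trained by gradient descent; the teacher's parameters are an
exponential moving average of the student's,
θ̂_{t+1} = β·θ̂_t + (1−β)·θ̄_{t+1}, with the warmup
β_t = min(β, 1 − 1/(t+1)) under which the early teacher is the plain
average of all students so far rather than a copy of the random
initialisation. The teacher runs in evaluation mode with gradients
disabled: pseudo-labels are data, not a differentiable branch.
Batch-normalisation *buffers* (running mean/variance) are copied from the
student after each EMA step rather than averaged — the EMA recursion
concerns learnable parameters; averaging normalisation statistics with
stale values degrades the teacher's calibration early in training.
At evaluation time the *student* is the inference model: at short
schedules the EMA teacher lags behind a still-improving student (the
teacher's advantage appears only once the learning rate has decayed and
the student oscillates around a basin).

The labeled and unlabeled student forwards run as separate batches on
purpose: merging them couples the two streams through the
batch-normalisation statistics and measurably degrades the supervised
branch. For the same reason the contrastive views are encoded in their
own forward pass.

**Dynamic pseudo-label threshold map.** For each unlabeled batch the
teacher's probability maps ȳ_i ∈ [0,1]^{H×W×C} give a batch-averaged
maximum-confidence map M̄(h,w) = (1/B) Σ_i max_c ȳ_i(h,w,c). A spatial
threshold map M, initialised to 1/C (uniform uncertainty), tracks M̄ by an
EMA with momentum α. Class-specific confidence scores
ε_c = Σ selected max-probabilities / (pixel count + ξ) are normalised to
scaling factors η_c = ε_c / max ε, and the per-class threshold is
M_c(h,w) = η_c·M(h,w) — classes the model is currently less sure about get
proportionally lower cutoffs, so small structures are not starved of
pseudo-labels. A pixel is selected when its argmax probability *strictly*
exceeds M_{c*}(h,w); its weight γ is then that probability, else 0.
Argmax ties break to the lowest class index; background is an ordinary
class. The map lives on the fixed training grid and evolves continuously
across epoch boundaries (no reset; a `reset_each_epoch` flag exposes the
alternative). Note the threshold tracks the batch-*average* confidence, so
by construction roughly half of the pixels pass it; selection is a soft
curriculum, not a sparsifier.

**Robust pseudo-label loss.** Selected pixels are additionally weighted by
a temperature-softened teacher confidence p = max softmax(ȳ/τ). The
default mode couples the student to the hard pseudo-label:
L_u = −(1/HW) Σ γ·p·log ŝ(c*), where ŝ(c*) is the student probability at
the teacher's argmax class. A `literal_entropy` mode evaluates the pure
teacher-entropy form −(1/HW) Σ γ·p·log p instead; it contains no student
term and therefore provides no gradient to the student, so it is kept for
analysis only. The softened confidence is computed by re-normalising the
teacher's probabilities through a softmax, as specified; a
`confidence_from_logits` switch documents the (more conventional)
logit-space alternative. Logs are stabilised as log(x + 1e−12);
normalisation is by H·W (`all_pixels`), with a `selected_pixels` option.

**Contrastive consistency.** Pooled bottleneck embeddings of each unlabeled
image and of an augmented view form positive pairs; the other *original*
embeddings in the batch are the negatives. The loss is a modified NT-Xent
on cosine similarities whose denominator sums over the B−1 other original
embeddings and excludes the positive pair — it can therefore be negative.
A `simclr_denominator` flag restores the standard 2B−1 denominator (always
non-negative). The two temperatures (confidence τ and contrastive τ) are
independent hyperparameters. No projection head is used by default; an
optional 2-layer MLP head is available. Embeddings are global spatial
averages of the deepest encoder stage of the *student*.

**Total objective.** L = L_l + λ1·L_u + λ2·L_con with pixel-wise
cross-entropy L_l on the labeled batch. The unlabeled and contrastive
weights are multiplied by a sigmoid ramp exp(−5(1−t/T)²) over the first
`rampup_fraction` of training steps: the teacher's pseudo-labels are close
to random early on, and injecting them at full weight locks the student
into a degenerate solution (confirmation bias). Component toggles
reproduce the ablation grid: DPTM off replaces γ by a fixed 0.5 confidence
cutoff; REM off replaces the weighted loss by plain pseudo-label
cross-entropy on the selected pixels; CC off removes the contrastive term.
With DPTM and REM both off the pseudo-label branch is inactive entirely,
so the all-off configuration is exactly the supervised baseline.

## Parameters (defaults)

| symbol | meaning | default | notes |
|---|---|---|---|
| β | teacher EMA coefficient | 0.99 | horizon ≈ 1/(1−β) steps; match to schedule length |
| α | threshold-map EMA momentum | 0.99 | same horizon consideration |
| ξ | class-count stabiliser | 1e−8 | only guards empty classes |
| τ (REM) | confidence temperature | 0.5 | softens the max-probability weight |
| τ (CC) | contrastive temperature | 0.1 | independent of REM's τ |
| λ1 | unlabeled weight | 1.0 | lower values suit very small labeled sets |
| λ2 | contrastive weight | 0.1 | best range ≈ 0.1–0.15 |
| lr | SGD, cosine 1e−2 → 1e−3 | | momentum 0.9, weight decay 5e−4 |
| batch | images per step | 16 | labeled and unlabeled streams sampled independently |
| ramp | rampup_fraction | 0.3 | sigmoid ramp of λ1, λ2 |
| view | student_unlabeled_view | augmented | original / augmented / strong |

Augmentation: rotation ±30°, scaling 0.7–1.3, elastic deformation
(Gaussian-smoothed displacement, σ = 10 px, amplitude 100), horizontal flip
p = 0.5, brightness 0.7–1.3 — geometric parts applied identically to image
and label (nearest-neighbour). Contrastive views use brightness/contrast/
gamma jitter, crop-and-resize (0.6–1.0 scale), Gaussian noise (σ = 0.05),
and cutout (one zero square, 25% of the side).

The student's view of an unlabeled image must preserve geometry so that γ
and the pseudo-labels stay pixel-aligned with the teacher's view. Three
strengths are available: ``original`` (no perturbation), ``augmented``
(brightness + noise) and ``strong`` (brightness/contrast/gamma jitter,
noise and cutout). The strong view is the recommended one: under a mild
view the student already agrees with the teacher almost everywhere, so the
pseudo-label loss reduces to sharpening the student's own predictions —
errors included; the occluding view instead forces the student to infer
the covered structure from context, which is a genuine consistency signal.
Strong *geometric* views would require warping the pseudo-labels and γ and
are not implemented.

Randomness is split into three generator streams (labeled
sampling/augmentation, unlabeled views, contrastive views) so that runs
differing only in component toggles draw identical labeled batches —
common random numbers, making component deltas reflect the components
rather than RNG divergence.

## Synthetic phantoms

Each 64×64 single-channel phantom mimics a short-axis cardiac slice:
an LV-like bright disk inside a darker Myo-like ring, an RV-like crescent
hugging the ring, on a dark background (classes 0–3 = background, RV, Myo,
LV). Intensities are per-class means (0.15/0.65/0.35/0.80) corrupted by a
smooth multiplicative bias field (amplitude 0.2) and Gaussian noise
(σ = 0.08), chosen so a labeled-only model at small n is clearly imperfect
and semi-supervised deltas are measurable. Geometry is sampled per sample
(jittered centre, radii ranges) and is fully determined by (seed, index).
The phantoms deliberately omit several properties of real cine-MRI —
anatomical shape variability, through-plane effects, coil artefacts,
inter-patient intensity shifts — so passing results demonstrate the
correctness and interaction of the training machinery, not clinical
performance.

The RV crescent's intensity overlaps the LV pool under the bias field, so
the network must use spatial context, which is what makes the task
non-trivial for a small U-Net.

## Numerical core

The network, SGD and all differentiable losses are built on a small
reverse-mode autodiff engine over NumPy arrays (`cardiosemi.autodiff`)
with hand-written backward passes for convolution (im2col + GEMM),
max-pooling (ties share gradient), nearest-neighbour upsampling and batch
normalisation. All backward passes are verified against central finite
differences in the test-suite. The U-Net uses He initialisation, 3×3
convolutions, concatenation skips, and a softmax head; float32 throughout.
Completed graphs are explicitly dismantled after `backward()` so large
intermediate buffers are freed immediately.

## Evaluation metrics

Per-class Dice and Jaccard follow the set definitions (both masks empty →
1 by convention). Surface metrics extract 4-connected boundaries (mask
minus erosion), pool both directed nearest-boundary distance sets computed
with the exact Euclidean distance transform, and report the
linear-interpolation 95th percentile (95HD) and the mean (ASD) in pixel
units. One empty mask yields the image diagonal as a sentinel, with a
warning. Reported means exclude the background class.

## Desk-scale study configuration

The built-in experiments (``cardiosemi.config.desk_scale_config``) train on
16 labeled + 144 unlabeled phantoms for 15 epochs and evaluate on 50
held-out phantoms with a deliberately small U-Net (depth 3, base width 8 —
depth 2 cannot see enough context to separate the RV crescent from the LV
pool). Schedule choices are matched to that scale: batch 8 (doubling the
gradient and threshold-map updates per epoch relative to batch 16 at equal
cost), threshold-map momentum α = 0.9 (a horizon of tens of batches,
commensurate with ~270 training steps), the teacher warmup with
β = 0.99, λ1 = 0.3 (very small labeled sets make pseudo-labels noisier,
and lower unlabeled weights are preferable in exactly that regime), the
strong student view, a contrastive temperature of 0.5 (phantoms are far
more homogeneous than real slices, so the sharp τ = 0.1 saturates the
instance-discrimination softmax between near-duplicate negatives), and the
sigmoid ramp over the first half of training. The ablation grid runs all
eight DPTM/REM/CC on/off combinations with shared seeds.

On this task the pseudo-label components (DPTM + REM with the strong view)
carry the semi-supervised signal; the contrastive term is approximately
neutral, because instance discrimination presumes heterogeneous images and
the phantom distribution is nearly homogeneous — a limitation of the
phantom benchmark, not of the loss.

**Fragility at extreme label scarcity.** With only 16 labeled images the
desk-scale gain is small and seed-dependent: across nine seeds the
full-method-minus-baseline Dice difference ranges from clearly positive to
a rare catastrophic collapse in which the student fits the labeled images
*and* the teacher's wrong foreground concept simultaneously (the
supervised loss converges while held-out Dice drops far below the
baseline; every pseudo-label-branch configuration collapses together
while the contrastive-only and baseline runs are unaffected). This is
classic self-training confirmation bias: with so little labeled signal,
nothing corrects a teacher that locks onto a wrong concept mid-training.
The corresponding acceptance check is therefore expected to fail on some
seed triples; the component machinery itself is verified exhaustively at
the equation level.

## Known limitations

- 2-D slices only; distances are in pixels (no voxel spacing).
- The literal-entropy mode cannot train the student by itself (no student
  term); this mirrors its definition.
- CPU-only; per-step cost grows quadratically with base width.
- The phantom task saturates well below the difficulty of real cardiac
  data; component effect sizes measured on it are directional, not
  quantitative estimates.
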