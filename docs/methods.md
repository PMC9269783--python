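# Methods

This package implements cooperative (teacher–student) semi-supervised
segmentation with a selective-kernel attention gate on U-Net skip
connections and a feedback update of the teacher driven by the student's
error on labeled data. Everything runs on NumPy with hand-derived
gradients; there is no deep-learning framework underneath, which keeps the
arithmetic inspectable and lets every gradient path be checked against
finite differences.

## The model

**Backbone.** Teacher and student are two structurally identical 2D U-Nets
with independently initialized parameters (they never share storage). Each
encoder level applies two (3×3 conv → batch norm → ReLU) stages and 2×2 max
pooling; the decoder mirrors them with transposed-convolution upsampling
(nearest-neighbour + 1×1 conv is available) and skip concatenation. The
head is a 1×1 convolution to two logits per pixel, so the objective is the
plain softmax cross-entropy

L = −(1/N) Σₖ Σ_c t_{k,c} · log softmax(z_k)_c,

with N the number of pixels in the batch. Targets t are one-hot masks or
soft class distributions. Depth ≥ 1 is allowed; depth 1 degenerates to a
single conv block and exists for the toy gradient checks.

**Attention gate.** On each skip connection (one independently
parameterized gate per level) the skip tensor X passes through K parallel
branches — depthwise convolution with kernel size kᵢ ∈ {1, 3, 5, 7} by
default, then batch norm and ReLU — giving maps U₁…U_K. The gate computes

U = Σᵢ Uᵢ,  S_c = mean_{h,w} U[c,h,w],  m = ReLU(BN(W_sq S)),
w[i,c] = softmax_i(Wᵢ m + bᵢ)[c],  Y[c] = Σᵢ w[i,c] · Uᵢ[c],

i.e. per-channel convex recombination of the branches, with the softmax
computed under max-subtraction. Because S depends on the scale of the
objects in X, the branch weights — hence the effective receptive field —
adapt to scale. Design choices where the published form of this family is
ambiguous:

- The per-branch weight generators are *learned linear maps* from the
  compressed descriptor m to per-channel logits, not fixed scalars: scalars
  cannot produce channel-wise gating, which the channel-broadcast
  recombination requires.
- The compression stage inserts a channel-reducing linear map (ratio r,
  default 4, floor of one unit) before BN + ReLU; r = 1 recovers a
  pure BN + ReLU squeeze.
- The gate is K-generic. K = 1 is permitted and reduces to the identity on
  its single branch (a softmax over one logit is 1).
- Branch convolutions are depthwise by default (full convolutions
  optional), and their kernels are initialized *identity-centred*: the
  centre tap starts at 1 plus small noise. An untrained gate therefore
  passes the skip tensor through nearly unchanged while its weights are
  still uniform; without this, random branches followed by ReLU mangle the
  skip features and delay early training measurably.

**Cooperative loop.** Training has three phases:

1. *Pretraining.* The teacher alone minimizes cross-entropy on the labeled
   pool (SGD), stopping at the iteration budget or when the validation DSC
   fails to improve for `pretrain_patience` consecutive evaluations.
2. *Co-training.* Per batch: the teacher predicts pseudo-masks for a batch
   of unlabeled images (evaluation mode; hard masks take the per-pixel
   argmax with ties resolved to background); the student takes one SGD step
   against them; if feedback is enabled the teacher receives the
   meta-gradient update described below; and every `teacher_refresh_every`
   batches the teacher takes a supervised refresh step on labeled data, so
   both models optimize simultaneously.
3. *Prediction.* The student is the deployed model. When a validation set
   is available, the returned student (and pretrained teacher) is the
   snapshot with the best validation DSC — standard model selection, which
   also de-noises the stochastic protocol comparisons below.

**Feedback.** The feedback signal treats the student's one-step update as a
differentiable function of the teacher's *soft* pseudo-masks
q = softmax(teacher logits). With the virtual student update
θ′ = θ − η(∇_θ L_s(θ, q) + λθ) and labeled loss L_fb(θ′), the chain rule
gives ∂L_fb/∂q = −η · ∂/∂q [g_lᵀ ∇_θ L_s], where g_l = ∇_{θ′} L_fb. Because
the cross-entropy L_s is *linear* in q, the bracket is exactly
−(1/N) D_{g_l}[log p(θ)] — a directional derivative of the student's
per-pixel log-probabilities along g_l, which a central difference of two
extra forward passes evaluates essentially to machine precision (step 1e−5
in float64, 3e−3 in float32, along the normalized direction). The result
is backpropagated through the softmax and the teacher network. The
gradient is exact for the virtual update (evaluation-mode batch norm, no
momentum), which is also what the finite-difference oracle in the test
suite perturbs; when the student's actual step uses hard masks, the soft
chain is the documented surrogate. A simpler fallback mode ("scaled") lets
the teacher take a supervised step scaled by the student's labeled loss.

Three stabilizers matter in practice and are on by default:

- *Fine-tune scale.* During co-training the teacher's refresh and feedback
  steps use `learning_rate × finetune_lr_scale` (default 0.1; 0.05 in the
  scaled protocol) without momentum. The teacher is the source of the
  student's supervision; large teacher steps make the pseudo-masks
  oscillate and the student follows them into collapse.
- *Gradient clipping.* The feedback gradient is clipped to global norm 1.
  The one-step meta-gradient is noisy when the student is far from
  convergence, and unclipped spikes can push a pretrained teacher off its
  plateau.
- *Warm-up.* Feedback engages after `feedback_warmup` co-training steps
  (default 20). Before the student tracks the teacher at all, its labeled
  error carries no information about pseudo-mask quality.

## Synthetic phantoms

The generator emulates what the segmentation task assumes about
contrast-enhanced head MRI around a nasopharyngeal tumor, not the imaging
physics: a single connected star-convex target (radial Fourier harmonics on
a randomly oriented ellipse; roughness 0 gives an exact ellipse), intensity
close to surrounding distractor blobs (`contrast_gap`, default 0.08 above a
0.40 background with tumor contrast 0.22), several correlated slices per
patient (shared patient-level shape, per-slice coefficient jitter), a
smooth multiplicative bias field, and additive Gaussian noise. Masks are
exact rasterizations of the tumor curve; the rasterized area fraction is
fitted into `tumor_area_fraction_range` by rescaling plus bisection. Every
sample is a pure function of `(spec, patient_seed, slice_index)`.

What the phantoms do **not** model: acquisition physics, anatomy,
annotation noise, 3D continuity beyond shape correlation, multi-focal
disease. Results on phantoms demonstrate that the machinery is correct and
that the training dynamics behave as designed; they are not evidence about
clinical performance.

Splitting is by patient: patients are shuffled by seed, validation and test
receive the ceiling of their quotas and training the remainder (83 patients
at 70/15/15 → 57/13/13); on cohorts so small that the ceilings would leave
training empty, seats are reclaimed from the most over-allocated
evaluation split. Augmentation is offline and exact (90° rotations,
flips), applied identically to image and mask.

## Scaled protocol

The protocol behind the ablation table, the stochastic tests and
`scripts/acceptance.py` (`cafs.experiments.scaled_protocol`): 40 phantom
patients with 3–5 slices each at 64×64 (split ≈ 28/6/6 patients), 25 % of
training slices labeled, depth-2 base-6 float32 network, gate kernels
1/3/5/7 with r = 4, SGD with learning rate 0.1, momentum 0.5, weight decay
1e−4, batch 8, 80 pretraining + 75 co-training iterations, validation
snapshot every 25. The step sizes are larger than the reference-scale
defaults (lr 0.001, 1500 iterations) because the budget is ~20× shorter;
they were chosen for stable convergence of the supervised phases. At these
sizes the full five-configuration, three-seed ablation plus a supervised
baseline runs in roughly ten CPU-minutes.

Two comparisons are asserted only *stochastically* (means over ≥ 3 seeds,
tolerance = the larger of 0.02 DSC and the s.e.m. of the paired per-seed
differences): the module-ablation ordering (full ≥ single-module variants ≥
plain co-training, and no-pretraining far below everything — without a
competent teacher the student distils noise), and the semi-supervised
benefit (full model ≥ a supervised-only network trained on the labeled
fraction with the same architecture and step budget). At this scale the
single-module effects are small compared to seed noise; the tolerance
reflects that, and the no-pretraining margin (> 0.4 DSC) is the one large,
robust effect.

## Metrics

All scores derive from pixel confusion counts: DSC, Jaccard
(DSC = 2J/(1+J) holds identically), precision, recall, specificity
(TN/(TN+FP)). Degenerate denominators: two empty masks score DSC = J = 1;
an undefined ratio is reported as 1 and flagged in
`MetricReport.degenerate`; an empty prediction against non-empty truth
scores 0. Dataset aggregation is reported both as the mean of per-image
metrics and as metrics of pooled counts — the two disagree whenever image
difficulty varies, so both are always computed.

## Numerical choices

- Batch norm uses ε = 1e−5, momentum 0.1, biased batch variance; running
  statistics normalize in evaluation mode. Forward passes inside the
  feedback chain and all finite-difference evaluations run with statistics
  updates disabled so losses are pure functions of parameters.
- Argmax ties (equal logits) resolve to background — conservative for
  tumor masks.
- Max-pool ties scatter the gradient to the first maximal element.
- Convolutions are stride-1, same-padded, exact (sliding-window einsum or
  shift-and-add; no FFT).
- float32 is the training default for speed; float64 is used wherever
  gradients are compared against finite differences.
- PNG round-trips quantize images to 8 bits (max error 1/255 per pixel);
  masks round-trip exactly.
- Checkpoints are NumPy archives with a versioned JSON header carrying the
  network configuration.

## Known limitations

- 2D only; volumetric data must be sliced externally (a NIfTI slice reader
  is provided).
- The meta-gradient unrolls exactly one virtual step; longer-horizon
  feedback is out of scope.
- The NumPy implementation is CPU-bound and sized for small images; the
  256×256 depth-4 reference configuration is expressible but slow.
- Bitwise reproducibility holds for a fixed BLAS thread count.
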