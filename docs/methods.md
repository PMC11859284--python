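# Methods

## Problem setting

`clumm` targets camera-based human-motion recognition in settings (e.g.
manufacturing workstations, ergonomics studies) where raw video is abundant
but activity labels are scarce and backgrounds are distracting. Instead of
learning from pixels, each video frame is reduced to the estimated positions
of ten body joints — left/right shoulder, elbow, wrist, hip, and knee
(BlazePose indices 11–16, 23–26) — in normalized image coordinates. The
(x, y, z) triplets of those ten joints, concatenated in that fixed order,
form a 30-element feature vector per frame; missing joints contribute
(0, 0, 0). A recording of m frames is the m × 30 dataset matrix.

The pipeline has four stages:

1. **Contrastive pretraining.** Each minibatch row V is augmented into a
   positive pair: view 1 is V + ε with ε i.i.d. N(0, 0.5²) per coordinate
   (jitter, t1), view 2 is η·V with a single scalar η ~ N(1, 0.2²)
   (scaling, t2). Views are encoded by f(·), projected by a two-linear-layer
   ReLU head g(·) into 128 dimensions, and scored with the NT-Xent loss

       L_i = −log  exp(cos(ψ_i, ψ_pos(i))/τ) / Σ_{k≠i} exp(cos(ψ_i, ψ_k)/τ),

   averaged over all 2b anchors of a batch of b pairs (τ = 0.5 by default).
   Training uses AdamW (lr 0.005, cosine decay, batch 64, 500 epochs at full
   scale). After training g is discarded.
2. **Frozen-probe classification.** A multinomial logistic-regression head
   p(y=k|h) = softmax(Wh + b)_k is trained on the frozen encoder output h by
   full-batch Adam on the mean negative log-likelihood (lr 0.01, 100 epochs,
   multistep decay ×0.1 at epochs 50 and 75), evaluated with stratified
   5-fold cross-validation and accuracy plus macro precision/recall/F1.
3. **Outlier audit.** Feature vectors are clustered with K-Means (c = 3 by
   default, one cluster per expected motion). With d(V) the Euclidean
   distance of V to its nearest centroid, the threshold is t = μ_d + 2σ_d
   (σ_d the population standard deviation); points with d(V) > t (strictly)
   are flagged. Per-cluster mean and maximum member distances summarize
   cluster tightness. A penalized NT-Xent variant that adds λ·δ·ω_i to a
   flagged anchor's denominator is provided as a diagnostic of how outliers
   inflate the contrastive objective; training always uses the unpenalized
   loss.
4. **Contamination experiment.** Frames of an out-of-distribution motion are
   appended to the *pretraining* data (the labeled probe data stays clean);
   the pipeline is rerun per contamination level and the audit plus held-out
   metrics are reported.

## Design choices where the procedure was open

* **Scaling-factor centre.** A literal zero-mean scaling factor annihilates
  the sample in expectation and makes the positive pair uninformative, so
  the default is η ~ N(1, 0.2²); the zero-centred variant remains available
  via `AugmentConfig(paper_literal_scaling=True)` and its factor moments are
  exercised in the tests. View assignment is deliberately asymmetric
  (view 1 jittered, view 2 scaled) rather than sampling both transforms from
  a shared family.
* **Input standardization is part of the pretrained artifact.** Raw landmark
  vectors share a large common "mean pose" component (‖V‖ ≈ 2.7 against
  class-signal scale ≈ 0.2), so every pairwise cosine similarity is ≈ 0.995
  and the NT-Xent gradient is vanishingly small at initialization — pretrained
  image backbones avoid the analogous problem by bundling dataset-statistics
  input normalization. `pretrain()` therefore fits a per-coordinate
  standardizer on its (unlabeled) training matrix, applies it *after*
  augmentation (t1/t2 act in raw coordinate space, as defined), and freezes
  it into the encoder checkpoint. An encoder that never went through
  pretraining — e.g. the random frozen encoder used as the transfer
  baseline — has no fitted statistics and encodes raw features.
* **NT-Xent reduction.** The per-anchor loss is averaged over all 2b anchors
  (both orderings of every pair). The final incomplete minibatch is dropped:
  at b = 1 the denominator contains only the positive and the loss is
  identically zero. Zero-norm projections receive cosine similarity 0 by
  convention (ε-guarded norms in the differentiable path).
* **Encoder input layout.** Convolutional encoders receive the 30-vector as
  a single-channel 10 × 3 grid (landmarks × coordinates), preserving
  landmark locality along one axis. Because the grid is tiny, the residual
  stem uses a 3×3 / stride-1 / pad-1 convolution with no initial pooling,
  stages downsample by stride-2 convolutions, and global average pooling
  absorbs the final feature map. Blocks are conv–ReLU–conv with identity or
  1×1-projection shortcuts (φ = F(ξ, W) + ξ); no normalization layers are
  used at this scale, keeping inference exactly deterministic and
  batch-size-independent. The `mlp` encoder (30→256→256→128, ReLU) is the
  desk-scale default. `adapt_first_conv` folds externally supplied RGB
  first-layer kernels to one channel by channel averaging; no weights are
  downloaded or bundled, so `pretrained_init=True` raises with instructions.
* **Probe details.** Macro averaging for precision/recall/F1 (balanced,
  small-K reporting); stratified folds; probe weights start at zero (the
  objective is convex); the probe consumes h, never the projector output.
* **Outlier machinery.** σ_d is the population standard deviation; boundary
  points (d = t exactly) are inliers; per-landmark audits run the same
  distance/threshold computation on each landmark's 3-coordinate sub-vector,
  and the aggregate "percentage of outlier landmarks" is the mean flagged
  fraction over the ten audits; the reported mean/max outlier distances
  summarize all flagged landmark observations. The audit accepts a cluster
  model fitted on reference data: with heavy *concentrated* contamination an
  in-sample c = 3 fit can dedicate a centroid to the contaminant blob and
  hide it, so fit-on-clean / score-on-candidate is the recommended form when
  clean data exist. K-Means itself is Lloyd's algorithm with k-means++
  seeding, best of 10 restarts (scikit-learn).
* **Eq-12 penalty** is applied per anchor; both views of a flagged sample
  share its indicator.
* **Randomness.** All stages draw from named substreams of one run seed
  (epoch shuffling from (seed, 1, epoch); per-step augmentation from
  (seed, 2, epoch, step)), making every result bit-reproducible.
* **Networks and optimizers** are implemented on a small NumPy reverse-mode
  autodiff core (`clumm._autograd`); every primitive and the full
  encoder–projector–loss path are verified against central finite
  differences in the test suite.

## Synthetic data: what it emulates, and what it does not

The generator stands in for recordings of a person performing workplace
motions in front of a fixed camera. Each motion class is a smooth
phase-parameterized trajectory of the ten landmarks around a plausible
standing anchor pose (image y grows downward):

* `idle` — standing with ±0.012 lateral sway and slight arm drift;
* `lift` — a cyclic crouch–grasp–raise: hips drop ~0.10 into a squat,
  wrists reach knee height, then rise to chest height;
* `bend` — cyclic forward trunk flexion between mild and deep (shoulders
  travel up to +0.20 down and +0.08 forward), arms hanging; the trunk never
  fully straightens, as in continuous bending work, so the class stays
  distinct from idle;
* `overhead_reach` — the default out-of-distribution motion (wrists well
  above the shoulders, a posture none of the three classes visits).

Frames sample the phase uniformly; per-coordinate Gaussian estimation noise
(default sd 0.02) mimics pose-backend jitter, and whole-landmark dropout
(default rate 0.05) mimics a backend losing a joint, which quantizes to a
zero triplet — at the default rate about 40% of frames carry at least one
zeroed landmark, which is the main source of difficulty. The three class
trajectories are pairwise disjoint (minimum cross-class frame distance
≈ 0.16 at zero noise) but not linearly separable in raw coordinates, so the
probe genuinely tests the learned representation.

The generator does **not** emulate temporal frame-to-frame correlation,
multi-person scenes, occlusion-correlated dropout (dropout is independent
per landmark), camera motion, or anthropometric variation between subjects.
Passing tests therefore demonstrate the correctness and behaviour of the
learning machinery under the assumed statistical structure, not performance
on real video.

## Scaled-down study conditions

Desk-scale experiments (test suite and the acceptance script) use 3 classes
× 200 frames, the `mlp` encoder, 50 pretraining epochs at batch 64, the
full 100-epoch probe with 5-fold CV, and 5 independent seeds; the
contamination study uses 0/20/50 injected `overhead_reach` frames on the
600-frame base. These sizes keep a full run in minutes on one CPU while
leaving the accuracy ordering (pretrained > random encoder; contaminated ≤
clean, with a saturating drop) stable across seeds.

## Numerical notes and limitations

* Log-sum-exp stabilization everywhere (softmax, NT-Xent); NT-Xent excludes
  the self-term via additive masking; the probability-simplex sum error is
  below 1e-12.
* K-Means with duplicate rows can return fewer distinct clusters; empty
  clusters report zero spread with a warning.
* The conv encoders are exact but slow relative to the MLP; at full
  (500-epoch, resnet) scale a GPU-backed framework would be the practical
  choice. The NumPy stack is intended for method study and CPU-scale data.
* Probe learning-rate milestones (50, 75) and τ = 0.5 are defaults, not
  tuned values; both are configurable.
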