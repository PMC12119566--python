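# Methods

`cardseg` implements a multi-view semi-supervised attention framework for
3D cardiac image segmentation and makes it runnable end to end on a single
CPU using synthetic cardiac phantoms.  This note records the model, its
assumptions, the parameters that matter, and the design decisions taken
where the design was genuinely open.

## The segmentation problem and the semi-supervised setting

The target task is voxel-wise binary segmentation of a bright cardiac
structure (a chamber body with protruding vessel-like appendages) in 3D
grayscale volumes, with only a small fraction of the training volumes
carrying labels.  Training follows the mean-teacher pattern: a *student*
network is optimized by SGD, while a *teacher* network — an exponential
moving average (EMA) of the student — supplies pseudo-labels for the
unlabeled volumes and is used for prediction.

The total training objective is

    L_total = L_sup + L_semi + λ(t) · L_unsup

* **L_sup** — weighted cross-entropy plus weighted Dice (equal weights)
  against ground truth on labeled patches.
* **L_semi** — the same combination against teacher pseudo-labels (hard
  argmax, no confidence threshold) on unlabeled and CutMix-mixed patches.
* **L_unsup** — uncertainty-rectified multi-scale consistency on the
  student's own prediction pyramid (below).

The per-voxel weights w_i in both weighted losses come from the
multi-view slice-confidence map.  Both weighted losses are normalized by
Σw_i, so they are invariant to uniform rescaling of the weight map, and
with uniform weights they reduce exactly to their standard forms.

## Multi-view slice-confidence supervision

Confidence is assigned per slice in two views: transverse (slices stacked
along z) and coronal (along y).  The source slice — by default the middle
slice of each view — has confidence 1; a slice at integer distance d has
confidence `decay_weight^d` (exponential decay).  The two per-view maps
are fused voxelwise; the default rule is the product (a voxel is
confidently supervised only where *both* views are confident), with `max`
and `mean` available.  `decay_weight` defaults to 0.95 per view; the value
and the fusion rule are configurable because neither is canonical.
Slice-position variants — an edge source slice, a contiguous middle band
(`band_width`), a single middle slice, or no slice weighting at all
(`source_index: none` or `decay_weight: 1`) — are supported so their
effect can be measured on phantoms.  Distance is measured in slice
indices, not millimetres.

## CBAP-VNet

The backbone is a VNet: residual convolution stages (3×3×3 convolutions,
instance normalization, PReLU), strided 2×2×2 convolutions for
downsampling, transposed 2×2×2 convolutions for upsampling, and skip
concatenations; channel widths double per level from `base_channels`.
Instance normalization was chosen because training uses batch size 2
(one labeled + one unlabeled patch), where batch statistics would be
meaningless.

Two attention mechanisms are added:

* **Adaptive channel attention** at the input: the input is globally
  average-pooled per channel, passed through a sigmoid, and multiplied
  elementwise back onto the input.  The block is parameter-free and a
  strict contraction (gate ∈ (0,1)).  We read the "element-wise
  convolution" of the original description as elementwise multiplication.
* **CBAM** after each downsampling stage (default): channel attention
  (a shared two-layer MLP applied to the global-average and global-max
  pooled descriptors, summed, sigmoid) followed by spatial attention
  (a 7×7×7 convolution over the channelwise mean and max maps, sigmoid).
  The MLP bottleneck uses `reduction_ratio` 16, clamped to the channel
  count for narrow test networks; its hidden activation has a small leaky
  slope (0.01) because a 1-unit bottleneck with a hard ReLU can go dead
  and silently stop adapting.

`make_variant(1..5)` reproduces the placement ablation: (1) CBAM on all
four down stages, no input attention; (2) input attention + CBAM on three
down stages; (3) input attention + CBAM on all four down stages — the
full CBAP-VNet; (4) input attention + CBAM on the four up stages;
(5) the plain VNet.

**Prediction pyramid.** Decoder stages at full, 1/2, 1/4, ... resolution
each feed a 1×1×1 classifier head; coarse heads are trilinearly upsampled
to full resolution and softmax-normalized, giving S scale predictions
p_0..p_{S−1} and their voxelwise average p_c.  S defaults to 4 when the
network has 4 levels (2 at desk scale); the exact head placement is not
canonical and follows the established multi-scale-consistency design.

## Uncertainty-rectified consistency

Scale uncertainty is the KL divergence of each scale from the consensus:
D_s[v] = Σ_j p_s^j[v]·log(p_s^j[v]/p_c^j[v]) ≥ 0.  The consistency loss is

    L_unsup = (1/S) Σ_s [ Σ_v ‖p_s − p_c‖² · w_s^v / Σ_v w_s^v ]
            + (1/S) Σ_s mean_v (D_s^v)²

with rectification weights w_s^v = exp(−D_s^v): voxels where a scale
disagrees strongly with the consensus are down-weighted in the
consistency term (they are probably near ambiguous boundaries) while the
minimization term pushes their uncertainty down.  The second term is
averaged over voxels so the loss is resolution-independent.  The weight
λ(t) follows the standard Gaussian ramp `λ_max · exp(−5(1 − t/T)²)` with
peak 0.1 and ramp length T = 40 iterations (`linear` and `constant`
schedules are available); the ramp keeps early, meaningless consistency
targets from dominating.

Probabilities are floored at ε = 1e-7 inside logarithms and KL terms; all
losses are differentiable away from the floor and vanish jointly at the
perfect-prediction / perfect-consistency fixed point.

## 3D CutMix

λ ~ Beta(α, α) with α = 1 (uniform on (0,1)) is the fraction of voxels
kept from sample A.  The cut region is a single axis-aligned box with
side lengths `shape·(1−λ)^(1/3)` (the 2D area-fraction rule extended to
volume fraction), placed uniformly at random fully inside the grid, so
the realized kept-fraction is deterministic given the rounded sides; the
realized fraction is what gets recorded.  Labels are mixed with the same
binary mask, so mixed labels stay hard.  During training CutMix replaces
batch items in place with probability 0.5: labeled patches mix with
labeled partners (ground-truth labels mixed by the mask), unlabeled
patches mix with unlabeled partners and their pseudo-label is the
teacher's pseudo-labels of the two sources mixed by the same mask.
Mixing across pools is not done.

## Training loop

Each iteration samples one labeled and one unlabeled patch at random
corners (batch size 2).  The teacher sees its unlabeled input with
additive Gaussian noise (σ = 0.1 after per-volume z-score normalization).
The student takes one SGD step (momentum 0.9, weight decay 1e-4, base LR
0.01 with polynomial decay, power 0.9) on the total loss; then the
teacher is updated as θ_t ← a·θ_t + (1−a)·θ_s with
`a = min(1 − 1/(t+1), ema_decay)` — the canonical mean-teacher warm-up,
under which the early teacher is a plain running average of the student
rather than being anchored at the random initialization.

`ema_decay` defaults to **0.95**.  The common value 0.99 implies an
averaging horizon of ~100 steps, appropriate for runs of thousands of
iterations; at desk scale (300 iterations) such a teacher lags a
still-improving student by several Dice points and degrades both
pseudo-labels and the final prediction.  A horizon of ~20 steps matches
run lengths of a few hundred iterations; 0.99 remains available in the
configuration for long runs.

Prediction uses the teacher by default (a flag switches to the student):
sliding-window patches with stride of half the patch size (the stride is
not canonical and is configurable), mean fusion of overlapping
full-resolution probabilities, then argmax.

All randomness — initialization, patch corners, CutMix draws, teacher
noise — flows from a single seeded generator; runs are bit-reproducible,
and checkpoints carry the generator state so runs can be resumed.

## Synthetic phantoms

The generator emulates a single bright, roughly ellipsoidal chamber with
tubular appendages protruding radially from its surface — a left-atrium-
like body with vessel-like attachments — at configurable grid sizes.  The
intensity model is two class means (default 0.75 foreground / 0.25
background), multiplied by a smooth random quadratic bias field (peak
deviation `bias_field_strength`, default 0.15, mimicking MRI
inhomogeneity) plus additive Gaussian noise (σ default 0.05).  The
foreground is a single 26-connected component occupying 2–40% of the
grid; the generator rejects specifications outside that band.

What the phantoms do *not* emulate: multi-structure anatomy, ultrasound
speckle, motion, partial-volume effects, or anisotropic voxels.  Passing
the benchmark therefore shows that the pipeline's mechanics (supervision
weighting, mixing, consistency, attention, fusion) behave correctly and
that the framework is not inferior to plain supervision on an easy task —
it does not certify clinical-grade accuracy on real MRI or echo data.

## Desk-scale problem sizes

Defaults are sized so that the complete benchmark (simulate → train →
predict → evaluate, twice: full framework and supervised-only baseline)
runs in a few minutes on one CPU: 32×32×24 phantom grids, 2 labeled +
8 unlabeled training volumes, 2 held-out test volumes, a 2-level network
with `base_channels` 4, 16³ patches, 300 iterations.  The full-scale
settings (112×112×80 patches, 4-level network, `base_channels` 16,
thousands of iterations) remain ordinary configuration values.

The supervised-only baseline used for comparison disables the semi
losses, CutMix, and slice weighting, and uses the plain VNet — i.e., it
isolates everything the framework adds.

## Numerical choices

* Tensors are float32 throughout the network; loss formulas preserve
  float64 when given float64 inputs, which is how the formula tests reach
  1e-9 agreement with scalar oracles.
* Probability floor ε = 1e-7; KL values are clipped at 0 (flooring can
  produce −1e-9-scale artifacts).
* Weighted-Dice with an empty foreground *and* an all-zero prediction is
  defined as 0 with a warning.
* Surface metrics: surfaces are foreground voxels with a face-adjacent
  background neighbor (volume borders count as background); distances are
  exact Euclidean distance transforms, pooled over both directions; 95HD
  uses linear interpolation between order statistics.  Spacing-aware when
  the header provides spacing; unit spacing reproduces voxel units.
* Patch grids shift the last window inward so patch shape is always
  honored without padding; overlap fusion is the arithmetic mean.
* Axis convention: arrays are (x, y, z), 0-based, z the transverse
  stacking axis.  NRRD (SimpleITK's (z, y, x) memory order) is transposed
  on read/write.

## Known limitations

* The NumPy network engine is single-threaded apart from BLAS; it is
  sized for desk-scale experiments, not for the full-resolution regime.
* Binary segmentation only (`num_classes` is plumbed through but the
  Dice loss uses the foreground channel).
* The phantom benchmark saturates quickly; differences between the full
  framework and the baseline are small by construction, and the benchmark
  is read as a non-inferiority check plus a mechanism exercise, not as a
  reproduction of real-data gains.
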