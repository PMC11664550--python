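# Methods

This note describes the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
test harness does and does not establish.

## Problem setting

The package implements a single-stage, anchor-free object detector for the
five strawberry growth stages (Flowering, Young Fruit, Fruit Expansion,
Color Turning, Maturation), built to be light enough for portable hardware:
roughly 5.9 M parameters and 14.7 GFLOPs at a 640×640 input. Because
greenhouse imagery of this kind is not freely redistributable, every part
of the pipeline — training included — is exercised on synthetically
rendered scenes (below).

## Numerical core

All network computation runs on a small in-repo reverse-mode automatic
differentiation layer over NumPy (`sgsnet._tensor`). Convolution is
evaluated by `im2col` + `einsum` and differentiated with an explicit
`col2im` scatter; bilinear grid sampling, overlapping-patch extraction,
max-pooling and training-mode batch normalization carry hand-written
adjoints (the batch-norm adjoint differentiates through the batch
statistics). Every primitive is checked against central finite differences
in the test suite. Computation is float32; gradient checks run in float64.

## Architecture

**Backbone (GrowthNet).** A 3×3 stride-2 stem convolution followed by four
stages of Universal Inverted Bottleneck (UIB) blocks — pointwise expand →
BN → ReLU → depthwise (3×3 or 5×5) → BN → ReLU → pointwise project → BN,
with an identity shortcut when stride 1 and matching widths. Stage widths
are 128/256/512/1024 and the stages downsample by 2 each, so levels P3/P4/P5
(strides 8/16/32) are tapped after stages 2–4. There is no fully connected
head; a global-average-pool utility exists off the detection path. Stage
depths and expansion factors are under-determined by the published
description (which fixes the widths, the 3×3/5×5 kernel menu and a 16-conv
budget), so they are configuration; the frozen schedule in
`configs/sgsnet_full.yaml` was calibrated with the package's own analytic
audit so that total complexity meets the published budget (5.857 M
parameters, 14.64 GFLOPs at 640²) while keeping exactly 16 convolution
layers in the backbone (stem + 5 blocks × 3 convs). Convolutions carry no
bias where batch normalization follows.

**Neck.** Three fusion paths. The deepest level passes through SPPELAN
(1×1 reduce, three sequential stride-1 5×5 max-pools, concatenation, 1×1
fuse). Going up, DySample upsamples by 2: a linear (1×1) projection of the
feature map produces per-pixel offsets (4 offset groups, 2·g·s² channels,
pixel-shuffled to the output grid and scaled by 0.25), which are added to
the regular bilinear grid under the half-pixel-center convention; the map
is then resampled bilinearly with border clamping. Upsampled features are
concatenated with the lateral level and fused by a dual-stream block:

* stream A — RepNCSPELAN4: 1×1 widen, two chained reparameterizable
  3×3+1×1 stages on one half, concatenation of all four partial maps, 1×1
  fuse. The multi-branch convolutions merge into a single kernel for
  deployment; train and deploy modes agree to float tolerance because the
  map is linear in the input.
* stream B — iRMB: windowed multi-head self-attention where queries come
  from non-overlapping 7×7 tiles and keys/values from expanded windows
  (tile + half-window halo, so neighbouring tiles overlap), with halo
  positions outside the map masked out of the softmax; attention output is
  refined by a 3×3 depthwise convolution and a pointwise projection with a
  residual shortcut.

The streams combine as (λ⊙A + 1) + (μ⊙B + 1) with trainable per-channel
weights λ, μ (initialized at 1), followed by a confidence-gated pointwise
refinement convolution. The gate compares the mean absolute activation with
a threshold τ; the default τ = 0 keeps the refinement always on so the path
is deterministic under test. The published description mentions a
"dot-product fusion" in prose but its combination formula contains no
product term; we implement the formula as printed and realize the extra
interaction only as the gated refinement. Downsampling returns through
strided 3×3 AConv blocks and plain RepNCSPELAN4 fusions.

**Heads.** Decoupled per-level branches: a 3×3 regression stem feeding a
1×1 conv that predicts a 16-bin discretized distribution per box side
(distances to the four sides in stride units), and a 3×3 classification
stem feeding 1×1 class (5 logits) and objectness convs. Decoupling matters
at desk scale: with the box term weighted 7.5 against 0.5 for
classification, a shared stem lets box gradients monopolize the features
and classification converges far more slowly. Class/objectness biases are
initialized to a 1% prior; regression biases to a small-box prior (~3 bins).
Boxes decode at each cell as the distribution mean times the stride, around
half-pixel cell centers.

## Inner-IoU loss

Both boxes are rescaled about their centers by `ratio` before the
intersection-over-union is computed; the loss is 1 − IoU of the auxiliary
boxes, and `ratio = 1` reduces exactly to the standard IoU loss. The
published intersection formula prints only the horizontal extents; an area
requires both axes, so the vertical term mirrors the horizontal one (the
accompanying figure shows two-dimensional auxiliary boxes). Default
`ratio = 0.75` (the source never states a value); shrunken auxiliary boxes
steepen the loss near convergence, and a gradient-descent experiment in the
test suite confirms faster median convergence than ratio 1 for
well-initialized boxes. A zero-area input yields IoU 0 with a warning.

## Assignment and composite loss

Candidate cells for each ground-truth box are those whose centers fall
inside it (any scale; the nearest cell is adopted if none do). Candidates
are ranked by the task-alignment score cls_prob^0.5 · IoU^6 between the
decoded prediction and the box; the top 10 become positives, subject to a
minimum-IoU floor of 0.2 — except that the best candidate is always kept,
so freshly initialized models (whose boxes are all below the floor) still
receive a signal. A cell serves at most one object (highest score wins,
ties to the earlier object).

The total is 7.5·box + 0.5·cls + 0.7·obj + 1.5·dfl:

* box — mean Inner-IoU loss over positives;
* cls — binary cross-entropy of all 5 class logits against one-hot targets,
  averaged over positives × classes;
* obj — binary cross-entropy of the objectness logit. Targets at positive
  cells are soft: the decoded box's IoU with its assigned object (clipped
  below at 0.05), so poorly regressed cells learn lower confidence and rank
  below well-fitted ones at evaluation. Positives are under 2% of cells, so
  the term averages the positive-cell and negative-cell means rather than a
  plain mean that would starve positives of gradient;
* dfl — distribution loss on the discretized side distances: cross-entropy
  against the two bins bracketing the true distance, linearly weighted.

Decoding applies a confidence threshold (0.001 for evaluation, 0.25 for
demo inference) and greedy per-class NMS at IoU 0.7.

## Metrics and audit

Matching is greedy in score order: a detection is a true positive if its
best same-class unmatched ground truth reaches IoU 0.5. AP integrates the
precision envelope of the PR staircase over recall (all-point
interpolation, not 11-point); mAP@0.5 averages AP over classes with at
least one annotated instance. 0/0 ratios are defined as 0.

The complexity audit walks the layer graph analytically (no forward pass):
per convolution, parameters are K_h·K_w·C_in·C_out (/groups; +C_out with
bias) and FLOPs the same quantity times the output map area, counted as
multiply–accumulate pairs without the ×2 convention, since the published
14.7 figure is tied to that counting. Batch-norm parameters (2C),
attention matrix-product MACs, bilinear-resampling MACs and the fusion
weights are itemized separately. The audit total is asserted equal to the
instantiated model's true trainable-parameter count. "Conv layer" counts
are reported under both conventions (blocks, and every conv separately).

Grad-CAM++ heatmaps use the closed-form coefficients
α = g² / (2g² + Σ_ij A · g³) on the ReLU'd gradients of an
objectness-weighted class score with respect to a neck level (default P3,
where small objects live), min–max normalized and bilinearly resized to the
input.

## Training

Plain SGD (momentum 0.937, weight decay 5e-4), learning rate 0.01 with a
linear warmup over 3 epochs from 0.1× the initial rate and momentum 0.8,
constant afterwards (the final rate equals the initial one). Warmup
interpolates per optimizer step across the 3 epochs. Everything is seeded —
initialization, batch order — so identical seeds give identical loss
traces. No EMA, mosaic or multi-scale jitter.

Desk-scale experiments use the `tiny` preset (widths 16/32/64/128, one UIB
per stage, a reduced neck) at 320 px with batch 4; the full 640-px
configuration is retained for the audit. The overfit experiment — 8
rendered scenes, 200 iterations, 3 seeds — reaches train-set mAP@0.5 ≈
0.96–1.0 with monotone loss decrease, in a few minutes per seed on one CPU.

## Synthetic scenes

`render_scene` draws 1–12 elliptical objects on a textured green
background: per-stage body palettes (white petals with a yellow center;
small green; larger pale-white; pink with a partial red flank; saturated
red), achene speckles, a calyx wedge, radial shading, and a tight box from
the rendered object mask. Object radii are 2–7% of the image side depending
on stage. Augmentation follows the photometric equations exactly as
written, in RGB, clipping to [0, 255] after each operator (the equations
are unclipped but 8-bit storage forces a choice); defaults s=40 for
brightness/darkness and 0.4 for chroma. The default catalog (vertical
flip, mirroring, brightness, darkness, chroma) expands a dataset 6×; the
published per-stage augmented counts imply a non-integer expansion policy
that is not reconstructible, so multiplicity is explicit configuration.

These scenes are caricatures: uniform backgrounds, no occlusion by
foliage, no lighting gradients, no camera noise, axis-aligned ellipses.
Passing the suite demonstrates that the detector, losses, metrics and
training loop are implemented correctly and can fit data whose class
structure matches the stage phenotypes — not that the architecture reaches
any particular accuracy on real greenhouse imagery.

## Known limitations

* CPU-bound NumPy execution: full-size 640-px training is out of reach;
  the full configuration is exercised analytically (audit) and the tiny
  preset empirically.
* The stage-depth/expansion schedule matches the published complexity
  budget but is not guaranteed to match the original network layer-for-layer.
* The loss reported during training is the weighted composite; the
  cross-entropy term is also reported separately since the published
  "loss" column's convention is ambiguous.
* Multi-stage scenes are supported implicitly (any class mix per scene);
  there is no separate image-level "Multi-Stages" detector class — the
  detector's classes are the five stages.
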