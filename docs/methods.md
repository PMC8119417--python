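# Methods

## Problem and approach

`tomoinpaint` localizes abnormalities in 2-D grayscale slices (the target
application is reconstructed digital breast tomosynthesis) using *only
normal images for training*.  The premise: normal breast tissue has a
learnable, predictable structure, while lesions are rare, localized and
texturally distinct.  A generative inpainting network is trained to
complete deliberately removed square regions of normal slices.  At test
time, a window slides over the image; the center square of each window is
removed, re-synthesized from its surroundings, and the completion error is
recorded.  Locations the model cannot complete well — because nothing like
them appeared in normal training data — light up in the resulting heatmap.

## Model

The generator is the coarse-to-fine contextual-attention inpainting
architecture: a coarse stage of stride-2 encoders and dilated-convolution
blocks (rates 2/4/8/16 at full scale) produces a blurred prediction of the
masked square; a refinement stage with two parallel branches — one dilated
convolutional, one using *contextual attention* (patch-wise cosine
similarity between each location's features and all known-region 3×3
feature patches, softmax temperature 10, weight-blended overlap-add
reconstruction) — sharpens it.  All activations are ELU, the output is
tanh in the [-1, 1] network domain, and the mask is supplied as a second
input channel with mid-gray fill.  Two critics score realism for the
Wasserstein objective: the local critic sees a fixed-size crop centered on
the mask, the global critic the full field of view; at a 512-px field of
view the global critic gains one extra stride-2 input convolution so its
flattened feature length matches the 256-px case.  Channel widths follow
the usual contextual-attention inpainting configuration's shape, scaled by
a single `width` multiplier (24 at full scale; 8 in the desk-scale `tiny`
preset).  No normalization layers are used.

Because no deep-learning framework is part of the package's dependency
set, the networks run on a small reverse-mode autodiff engine
(`tomoinpaint.autodiff`) written for this package: convolutions are
composed of `im2col`/`col2im` (mutually adjoint linear maps) and `matmul`,
and every operation's backward pass is itself expressed in differentiable
primitives, so the second-order gradients required by the WGAN-GP penalty
are exact.  ELU and tanh use first-order-exact constant backward factors;
second derivatives are only ever taken through the critics, which are
piecewise-linear (leaky ReLU), so the penalty's parameter gradient is
exact.

## Losses

    total = a_mask * L_mask + a_fov * L_fov + a_gan * L_wgan_g
            + L_wgan_d + lambda * L_gp

with weights (a_mask, a_fov, a_gan, lambda) = (1.2, 1.2, 0.001, 10).
`L_mask` is the mean spatially-discounted L1 error of the coarse plus the
fine prediction over the masked region; `L_fov` the same (undiscounted)
over the known region.  The discount is `0.99^l` where `l` is the
Chebyshev distance of a mask pixel to the nearest known pixel (a
border mask pixel has l = 1); Chebyshev is chosen because it is separable,
flip-symmetric, and matches corner adjacency.  Wasserstein terms:
critic loss `mean(fake) - mean(real)` and generator loss `-mean(fake)`,
summed over the two critics with equal weight; the gradient penalty
`lambda * E[(||grad D(x_hat)|| - 1)^2]` interpolates real/fake pairs at
independent uniform positions.  L1 terms are means, not sums, so loss
magnitudes are comparable across mask sizes.

## Training

Alternating updates (one critic step, one generator step per iteration)
with Adam at learning rate 1e-4, betas (0.5, 0.9) — the usual WGAN-GP
setting, since only the optimizer name and rate are fixed by the design.
Full-scale defaults: batch 9, field of view 256 or 512, training mask side
uniform on [16, 128], patch sampling constrained to crops with at least
10% tissue (the tissue-overlap threshold is a package choice; only
"thresholding non-zero pixels" is prescribed).  One iteration = one batch
of freshly sampled patches.  Runs are bit-exactly reproducible and
resumable: checkpoints store weights, Adam moments, config and the
sampler RNG state.

The local critic needs a fixed input size while training masks vary, so
it sees a fixed `local_crop_side` window (default = the largest training
mask side) centered on the mask and clipped to the patch — a package
design choice where the design was open.

## Scoring and evaluation

Sliding-window scoring uses stride 8 at full scale, center mask, and
writes each window's scalar score over the *mask footprint* (not a single
point and not the whole window): later windows overwrite earlier ones in
the plain heatmap; the averaged heatmap accumulates on the footprint and
divides by per-pixel coverage.  Footprint (rather than full-window)
accumulation is deliberate: only the masked square is actually
re-synthesized, so spreading its score over context pixels the model saw
would smear localization.  Metrics: `MSE` (mean squared completion error
over the mask, [0,1] intensity units), `DISCR` (softplus of the negated
global-critic score — the raw Wasserstein score is unbounded and
sign-ambiguous, and softplus preserves its ranking while guaranteeing a
positive factor), and `DMSE = MSE * DISCR`.  The global critic is used for
`DISCR` because the quantity of interest is the consistency of the filled
region within the whole field of view.

Evaluation computes, per test image, the mean heatmap value inside the
union of ground-truth boxes divided by the mean over the remaining valid
tissue (heatmap-covered, strictly positive pixels); box pixels outside
tissue count in neither region.  Images whose box lies within 128 px of an
image edge are excluded (the border band is never covered by a center
mask).  The aggregate reports the arithmetic mean and, by default, the
population standard deviation of per-image ratios (sample std is one flag
away; the choice is not prescribed anywhere).  A mean ratio above 1 means
completion error localizes abnormalities.

## Synthetic phantoms

The phantom generator emulates the statistics the method relies on:
a half-elliptic tissue region flush against one image edge with exact-zero
background, band-limited texture (Gaussian-filtered white noise rescaled
to [0.2, 0.8]), brighter curvilinear vessels (smoothed random walks with a
fixed-width profile), a thin bright skin-edge band, and — in abnormal
images — one spiculated blob (sinusoidally perturbed radius) of elevated
contrast with a tight bounding box.  It does *not* model X-ray physics,
reconstruction artifacts, calcification clusters, clips, or 3-D structure;
passing tests therefore demonstrate that the pipeline detects localized,
texturally distinct departures from learned normal structure, not clinical
performance on real tomosynthesis data.

## Desk-scale study conditions

All experiments bundled with the package run on one CPU in minutes, not
on a GPU for days, so the clinical-scale operating point (256/512-px
fields of view, millions of iterations, tens of thousands of training
slices) is replaced by a fixed desk-scale configuration chosen once: `tiny` model (fov 64,
width 8, dilation rates 2/4/8, local crop 16), masks 8–16 px in training
and 16 px in scoring, 200 normal 192×192 phantoms for training, 500
training iterations at batch 4, and evaluation on 20 held-out 352×352
phantoms with one inserted anomaly each, scored at stride 16.  The
352-px evaluation side is forced by keeping the 128-px edge-exclusion
margin; stride 16 (instead of 8) keeps the sweep proportionate to the
smaller mask.  The deterministic mean-fill inpainter (mask replaced by the
mean of the known pixels) provides a non-learned reference under the same
evaluation.

## Numerical choices and degenerate cases

* Stored intensities live in [0, 1]; integer images scale by the format
  maximum (v / 255 or v / 65535), preserving zeros exactly.
* MSE is computed in the network domain and divided by 4 to express it in
  [0,1]-intensity units; with the perfect-completion reference the
  difference is exactly zero, so MSE and DMSE heatmaps are identically
  zero rather than rounding noise.
* A heatmap whose outside-tissue mean is zero yields an undefined ratio;
  the image is reported as degenerate and excluded from aggregation
  instead of dividing by zero.
* The gradient-penalty norm adds 1e-16 inside the square root to keep the
  constant-critic gradient finite; the perturbation is below the closed
  form's 1e-6 comparison tolerance.
* Patch sampling rejects at most 64 random draws before switching to an
  exact enumeration of admissible origins (integral-image tissue counts),
  so the uniform-over-admissible-origins contract holds even for images
  whose tissue is a single corner.
* Masks are solid axis-aligned squares only; mask side is structurally
  constrained to the field of view, while paper-scale ranges (16–128
  training, 64/128 scoring) are configuration defaults rather than hard
  validation, so the desk-scale 16-px scoring mask remains expressible.

## Known limitations

Phantom realism is deliberately minimal (see above).  The autodiff engine
implements exactly the operations these networks need; it is not a
general framework and keeps whole graphs in memory (fine at desk scale).
Training at the full 256/512-px operating point is supported by the code
but not exercised by the bundled experiments: clinical-scale results
require a clinical dataset and millions of iterations, both out of scope
for the bundled runs.
Bit-exact determinism holds per machine/BLAS build, not across platforms.
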