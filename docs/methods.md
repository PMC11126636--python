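# Methods

## Model

The classifier is a four-branch convolutional network for multi-label
images. An input batch (N×3×H×W, H and W divisible by 32) passes through
a 7×7/stride-2 stem convolution and a 3×3/stride-2 max pool, then four
stages of bottleneck residual blocks (1×1 reduce, 3×3 spatial, 1×1
expand ×4; 3/4/6/3 blocks with mid-widths 64/128/256/512; projection
shortcut and stride 2 at each stage entry except the first). The stage
outputs F1..F4 form a feature pyramid: 256×56×56, 512×28×28, 1024×14×14,
2048×7×7 at 224×224 input.

**Attention.** After the 3×3 convolution of every block sits a
coordinate-attention gate: per-channel mean pooling along width (C×H×1)
and along height (C×1×W), concatenation of the two descriptors along the
pooled axis, a shared biased 1×1 convolution to hidden width
max(8, C/32) with batch-norm and ReLU, a split back into the two
directions, two biased 1×1 convolutions back to C channels, and two
sigmoid gate maps that are both multiplied into the input. This
configuration (reduction 32, hidden floor 8, biased convolutions,
batch-norm on the squeezed representation) is fixed because it is the
unique standard parameterisation consistent with the architecture's
published per-component parameter totals: one CA block holds
C·Cm+Cm + 2Cm + 2(Cm·C+C) parameters with Cm = max(8, C/32), i.e.
1,688 / 3,352 / 6,680 / 25,648 at C = 64/128/256/512, and the 16 blocks
total 135,496 (0.1355 M). The plain backbone with a 14-way fully
connected head totals 23,536,718 (23.54 M); adding CA gives 23.67 M.
SE (reduction 4 on mid-channels, bias-free two-layer bottleneck) and
CBAM (SE-style channel gate on avg+max descriptors plus a biased 7×7
spatial gate) are provided as ablation variants; their internal layouts
reproduce the published counts only approximately (the closest SE
reconstruction differs by 64 parameters from the printed 0.6288 M), so
they are documented as approximate and are not part of the exact
accounting.

**Fusion.** Each Fi is projected by a biased 1×1 convolution to a common
width D (default 256, the customary pyramid width; the source
architecture does not pin it) and merged top-down: P4 = lateral(F4),
Pi = lateral(Fi) + upsample(P(i+1)). Upsampling is bilinear with the
half-pixel (align_corners = false) convention, implemented as two
precomputed row-stochastic interpolation matrices so the operation is
exactly linear and cheap to differentiate. No post-merge 3×3 smoothing
by default (a flag adds it).

**Heads and decision fusion.** Each fused level feeds a class-specific
residual attention head: a bias-free 1×1 projection to d score maps
(d = 14 classes), then per class

    y^k = (1/hw) Σ_i X_i^k + λ Σ_i softmax(T X^k)_i X_i^k

with a numerically stabilised softmax over the h·w positions. λ is
0.5/0.4/0.3/0.1 for branches 1..4 — larger on the fine, spatially rich
levels — and T = 1, fixed (an opt-in mode makes it trainable). The
branch outputs are treated as logits (the second term makes them
unbounded); probabilities appear only in the decision fusion
y_final = σ(Σ w_i y_i). The branch weights w_i are not published; the
package defaults to the uniform w_i = 1/4, the unique symmetric choice,
with an optional trainable mode (softplus-reparameterised to stay
positive). Heads read the fused maps F1′..F4′; a compatibility flag puts
them on the raw pyramid for ablation.

**Loss.** Binary targets are smoothed to 1−α (positives) and α/K
(negatives) — note α/K, not α/(K−1), implemented exactly as specified —
with α = 0.1 and K = 14 by default; the loss is the mean over the K
classes and then over the batch of the binary cross-entropy against the
smoothed targets, with predictions clamped to [1e-7, 1−1e-7] before the
logarithms. At α = 0 this reduces exactly to plain multi-label BCE.

## Numerical core

All layers run on a tape-based reverse-mode autodiff engine over numpy
arrays written for this package: convolution by im2col plus BLAS matmul
(the input gradient folds columns back with a kh·kw loop of strided
slice-adds), max pooling with argmax scatter, batch-norm composed from
differentiable primitives with running statistics for evaluation mode,
and the bilinear operator above. Gradients of every composite are
verified against central finite differences in the test suite
(tolerance 1e-7 on float64). Parameters are float32 by default; modules
can be cast to float64 where tests compare against step-by-step
references at 1e-6. Optimisation is Adam (bias-corrected moments,
classic L2 weight decay added to the gradient). Forward passes are
deterministic given weights; training is deterministic given the seed,
which drives initialisation (Kaiming fan-out for convolutions), shuffle
order, and augmentation.

## Training protocol

Full-scale defaults: Adam lr 1e-4, betas (0.9, 0.999), eps 1e-8, weight
decay 1e-5, batch 64, up to 60 epochs. The learning rate is divided by
10 when the monitored validation metric has not improved for 5 epochs,
and training stops after 5 epochs without improvement. Both counters use
patience 5; they only coexist usefully because the early-stopping
counter resets on *any* improvement, so a post-drop recovery extends
training — this disambiguation is deliberate and implemented as stated.
The monitored metric is validation mean AUC (it is also the
model-selection criterion; a switch monitors loss instead). The best
checkpoint by validation mean AUC is retained, as a single file holding
the weights, an echo of the resolved configuration, and the library
version.

Preprocessing: resize to 256, crop to 224, ImageNet channel
normalisation; training adds a random horizontal flip. The published
evaluation protocol uses a *random* crop at test time as well; the
package's default evaluation phase is a centre crop so that metrics are
reproducible, with an `eval_paper` phase reproducing the random-crop
protocol. Grayscale inputs are replicated to three channels.

Uncertain (−1) entries in per-class label tables are remapped by policy
(U-Ones → 1, U-Zeros → 0); blanks count as negative and remaps are
logged. Ratio-based splits group by patient before splitting so no
patient straddles train/validation/test; grouping is the leakage-safe
completion of a plain 7:1:2 ratio split and can be bypassed with
official id lists.

## Metrics

Per-class ROC points are (FPR, TPR) at every distinct threshold with
endpoints (0,0) and (1,1); AUC uses the Mann-Whitney convention (ties
half credit) and is computed through scikit-learn, with an exhaustive
pair-enumeration reference in the tests. The mean AUC averages evaluable
classes unweighted; classes whose labels are constant in a split are
excluded and reported rather than zero-filled. Grad-CAM heatmaps
rectify the channel-importance-weighted activation sum at the final
backbone stage (fused levels selectable), normalise the maximum to 1
(all-zero maps stay zero), and upsample bilinearly to the input size;
the backward pass runs from the pre-sigmoid fused logit of the chosen
class.

## Synthetic data

The generator emulates the statistical structure the model assumes:
K = 14 independent Bernoulli labels with per-class prevalences decaying
geometrically from 0.40 to 0.05 (matching the severe imbalance of public
radiograph datasets), and one localised additive motif per positive
class on a noisy low-contrast background (base intensity 0.35, Gaussian
noise sd 0.10, a random smooth illumination gradient). Each class has a
characteristic shape family (filled ellipse, ring, oriented bar, cross),
a characteristic grid position, and a characteristic scale, with
randomised jitter in position (sd 3% of image size), scale (±15%), and
amplitude (0.40–0.60). Outputs are byte-identical across runs with the
same seed and round-trip exactly through the standard CSV reader.

What this emulates: localised, class-characteristic evidence; label
imbalance; background nuisance. What it does not: inter-class label
correlation, overlapping or mutually occluding lesions, anatomical
context, acquisition artefacts, and label noise. Passing the synthetic
experiment therefore demonstrates that the pipeline can learn localised
multi-label structure under imbalance — not clinical-level performance.

## Scaled experiment sizes

The end-to-end experiment used by the tests and the acceptance script
runs at desk scale: 1,500 training and 300 validation images at 64×64,
a width- and depth-reduced model (stem 16, mid-widths 8/16/32/64, two
blocks per stage, fusion width 32, all four branches, CA on, α = 0.1,
λ = (0.5, 0.4, 0.3, 0.1)), trained from scratch for at most 5 epochs.
From-scratch training of this small model uses Adam lr 3e-3 with batch
16 — the full-scale defaults (1e-4, batch 64) are a fine-tuning protocol
for a pretrained backbone and make too little progress in a 5-epoch
budget; the smaller batch and larger step are the package's own choice
for this regime. Under these conditions the validation mean AUC exceeds
0.99 with the training loss falling throughout.

## Known limitations

- No pretrained weights are bundled; full-scale results on real
  radiograph collections require training from external data.
- The numpy core is single-device and unsuited to datasets beyond
  desk scale.
- SE/CBAM parameter layouts are approximate reconstructions (see above).
- The published full-model and fusion-only parameter totals could not be
  reconciled with any standard pyramid/head parameterisation (the
  lateral width is not stated); the fusion width is therefore
  configurable and those two totals are not part of the exact
  accounting.
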