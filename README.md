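# mbranet

Multi-branch residual attention network for multi-label chest-radiograph
classification.

A chest radiograph can show any subset of 14 pathologies at once, with
lesions of very different sizes occupying characteristic regions of the
image, and public label sets are severely imbalanced (some findings appear
in under 1% of images). `mbranet` implements a full pipeline built around
an architecture that targets exactly these three problems — multi-scale
lesions, spatial localisation, and class imbalance:

1. **Coordinate-attention backbone.** A 50-layer bottleneck residual
   extractor (stages of 1×1–3×3–1×1 blocks, `H(x) = F(x) + x`) with a
   coordinate-attention (CA) block after every 3×3 convolution. CA pools
   each channel along the horizontal and the vertical direction
   separately, squeezes the two descriptors through a shared 1×1
   convolution, and emits two direction-aware sigmoid gate maps — so the
   gating retains *where* along each axis the evidence sits. SE and CBAM
   gates are available as ablation variants. The extractor emits four
   scales F1..F4 (256×56×56 … 2048×7×7 at 224×224 input).
2. **Pyramid fusion.** 1×1 lateral projections to a common width plus a
   top-down pathway with bilinear upsampling and element-wise addition
   (the FPN recipe), giving fused maps F1′..F4′ that mix semantically
   deep and spatially fine information.
3. **Multi-branch CSRA classifier.** Each fused scale gets a
   class-specific residual attention head: a bias-free 1×1 projection to
   one score map per class, pooled per class as

   y^k = (1/hw) Σᵢ Xᵢᵏ + λ · Σᵢ softmax(T·Xᵏ)ᵢ · Xᵢᵏ,

   i.e. the plain average score plus a softmax-attention-weighted score
   (λ = 0.5, 0.4, 0.3, 0.1 for branches 1..4, temperature T = 1). The
   four branch logit vectors are combined by y_final = σ(Σᵢ wᵢ yᵢ).
4. **Label-smoothed multi-label BCE.** Hard targets are replaced by
   ŷ = 1 − α (positives) and α/K (negatives) with α = 0.1, K = 14, and
   the loss is the mean binary cross-entropy against ŷ over classes and
   batch — a guard against overconfidence on rare classes.

The package includes readers for both common label-CSV dialects (pipe-
separated finding labels; per-class 1/0/−1/blank columns with U-Ones /
U-Zeros uncertainty policies), patient-grouped or official-list splits,
a deterministic synthetic generator of multi-label motif images for
testing the pipeline end to end, per-class ROC/AUC evaluation, Grad-CAM
heatmaps, and a CLI. All network layers run on a small numpy-based
reverse-mode autodiff core shipped with the package (`mbranet.nn`), so
training and inference need no GPU framework.

## Worked example

Train a width-reduced model on synthetic 64×64 motif images, where each
of the 14 classes is a localised shape at a class-characteristic
position, with class prevalences decaying from 0.40 to 0.05:

```python
from mbranet import (SyntheticSpec, generate_synthetic_dataset,
                     read_chestxray14_csv, split_records, TrainConfig)
from mbranet.training import train, evaluate

csv = generate_synthetic_dataset(
    SyntheticSpec(n_images=400, image_size=64, seed=11), "demo")
records = read_chestxray14_csv(csv)
train_recs, val_recs, test_recs = split_records(records, seed=11)

config = TrainConfig.scaled_synthetic(seed=11, max_epochs=3)
model, log = train(config, train_recs, val_recs)
print(log.to_dataframe().to_string(index=False))
```

```
 epoch  train_loss  val_loss  val_mean_auc    lr
     0    1.377681  0.625511      0.538510 0.003
     1    0.647656  0.558778      0.607095 0.003
     2    0.571984  0.836258      0.618649 0.003
```

The training loss falls as the model starts picking up the motifs; the
validation mean AUC (the headline metric — the unweighted mean of the
per-class areas under the ROC curve) climbs away from the 0.5 chance
level. `evaluate` then scores a held-out split per class:

```python
print(evaluate(model, test_recs, config).head(4).to_string(index=False))
```

```
       class      auc  evaluated
 Atelectasis 0.809896       True
Cardiomegaly 0.636040       True
    Effusion 0.680667       True
Infiltration 0.458855       True
```

Three epochs on 280 images is only a taste: the scaled experiment in
`scripts/acceptance.py` (1,500 training images, 5 epochs) reaches a
validation mean AUC above 0.99 on the same task. Full-scale training on
real radiographs uses `TrainConfig()` defaults (lr 1e-4, batch 64, up to
60 epochs, plateau-scheduled lr and early stopping on validation mean
AUC).

Parameter accounting of the full-size architecture, per component:

```
$ mbranet count-params --attention ca
  backbone:   23,508,032  (23.5080 M)
 attention:      135,496  (0.1355 M)
    fusion:      984,064  (0.9841 M)
     heads:       14,336  (0.0143 M)
  decision:            0  (0.0000 M)
     total:   24,641,928  (24.6419 M)
```

The CLI also offers `make-synthetic`, `train`, `evaluate`, `predict`
(top-6 table per image) and `heatmap` (Grad-CAM overlay PNG).

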