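# Methods

## Scientific problem

Tongue diagnosis pipelines classify tongue *shape* (thin / normal / bulgy)
from photographs. Two couplings make this hard for a plain CNN classifier:
the tongue must first be separated from lips and skin of very similar hue,
and the classifier should be told which pixels belong to the tongue. This
package implements a two-level nested model:

1. **RCA-UNet** — an attention U-Net that segments the tongue;
2. **RCA-Net** — a dilated-stem CNN that classifies tongue shape;
3. **IF-RCNet** — the nesting of the two, coupled by *mixed input* (the
   predicted mask joins the image at the classifier's input) and *feature
   fusion* (a pooled encoder feature vector joins the classifier's head).

## Model components

### Attention blocks

**RCBAM** is a residual channel + spatial attention block:

```
out = x + (x ⊙ CAM(x)) ⊙ SAM(x ⊙ CAM(x))
```

CAM produces per-channel sigmoid weights from a shared two-layer bottleneck
(reduction 16) applied to both the average-pooled and max-pooled channel
descriptors. SAM produces per-pixel sigmoid weights from a 7×7 convolution
over the channel-mean and channel-max planes. The residual wrapper means a
closed gate passes `x` through unchanged and fully open gates produce `2x`;
both limits are tested.

**MSAG** (multiscale attention gate) filters a skip feature through three
parallel convolutions (1×1, 3×3, dilated 3×3), concatenates them, batch
normalizes, reduces to a one-channel sigmoid gate `g` with a 1×1 "vote"
convolution, and returns `x + x⊙g`.

### RCA-UNet

Four encoder stages (dual 3×3 conv → BN → ReLU, then RCBAM, then 2×2 max
pool) with widths `base·(1,2,4,8)` and a `base·16` bottleneck; the default
base width is 64. Decoder stages upsample with 2×2 stride-2 transposed
convolutions and concatenate the MSAG-gated skip. A 1×1 head yields two
logits per pixel (background / tongue); the mask is the per-pixel argmax.
Inputs must be divisible by 16. The four stage outputs plus the bottleneck
are returned as `encoder_features` for fusion.

### RCA-Net

Five conv blocks (3×3 conv → BN → ReLU → RCBAM) with dilation factors
(3, 2, 1, 1, 1): the dilated stem widens the receptive field without pooling
so shallow detail survives. No pool follows block 1; 2×2 max pools follow
blocks 2–5 (224 → 14). A side branch (RCBAM + max pool) taps block 1's output
and is merged into the main path after block 2's pooling; because the branch
carries `widths[0]` channels and the main path `widths[1]`, a 1×1 projection
is inserted before the elementwise add — a necessary design addition for
channel compatibility. Global average pooling and a three-layer FC head (512 → 512 → 3 by
default, ReLU + dropout 0.5 between layers) produce the class logits.

### IF-RCNet couplings

*Mixed input*: the default `mask_channel` mode appends the soft foreground
probability `sigmoid(z₁ − z₀)` as a fourth channel; `masked_rgb_concat`
stacks the masked RGB image with the original (six channels). *Feature
fusion*: the deepest encoder map is projected by a 1×1 convolution, globally
average-pooled, and concatenated to the pooled backbone vector ahead of the
first FC layer. The ablation lattice is `base` / `mixed` / `fusion` / `both`;
`base` is parameter-identical to a standalone RCA-Net (tested bitwise).
Training is two-phase: the segmentation net is trained first and frozen
(kept in eval mode, excluded from the classifier's optimizer) while the
classifier trains.

## Metrics

Classification: accuracy, one-vs-rest precision/recall per class, macro F1,
3×3 confusion matrix; zero-division cases report 0 with a warning.

Segmentation, averaged over images: mean IoU over the two classes
(background and tongue), foreground Dice `2TP/(FN+2TP+FP)`, and the
symmetric boundary Hausdorff distance. Boundaries are foreground pixels
minus their 4-connected erosion. The Hausdorff distance has a brute-force
pairwise-distance reference and an exact-Euclidean-distance-transform fast
path that agree exactly on pixel grids. Degenerate policy: both masks empty
→ (MIoU 1, Dice 1, HD 0); exactly one empty → Dice 0 and HD equal to the
image diagonal.

## Cross-validation

The 3.5 : 0.5 : 1 train/test/eval ratio with five repeats is realized as a
ten-shard plan: ids are shuffled (stratified by class when labels exist,
since a 10% shard of a small dataset can otherwise miss a class) and dealt
round-robin; round *r* takes shard 2*r* as test and the next two shards
(cyclically) as eval, leaving seven shards (70%) for training. Test shards
are pairwise disjoint across rounds. Model selection uses the eval subset
(Dice for segmentation, accuracy for classification); the test subset is
scored once per round.

## Synthetic data

Real tongue photographs cannot ship with the package, so a generator renders
structurally analogous scenes: a rotated ellipse whose lower half is
stretched by a `droop` factor (the hanging-tongue outline), class-separating
width ratios 0.35 / 0.55 / 0.80 of the image width (±5% jitter), a lip
crescent of blendable hue hugging the upper tongue boundary but never inside
the mask, and multiplicative smooth texture plus additive Gaussian noise
applied to the image only. Per-sample seeds derive as
`master_seed·10⁶ + index`, so a dataset is fully reproducible from one seed.

Limits of the emulation: classes are separable by silhouette area/aspect
alone (no texture cues), the lip is the only distractor, and illumination,
pose and occlusion variation are absent. Results on this benchmark
demonstrate that the pipeline trains and that the couplings help when lips
touch the tongue; they do not predict clinical accuracy.

## Numerical backend and design decisions

No deep-learning framework is available in the target environment, so the
package ships a small NumPy reverse-mode autodiff core (`ifrcnet.nn`):
stride-1 convolutions as im2col + matmul (backward recomputes the im2col
view instead of caching it, saving k² times the activation memory), 2×2
stride-2 transposed convolution, floor-mode 2×2 max pooling, batch
normalization (batch statistics while training, running statistics in eval),
dropout with inverted scaling, fused softmax cross-entropy, and Adam / SGD
with momentum. Gradients are verified against central finite differences and
nested-loop convolution oracles. Everything runs in float32 on one CPU;
`device='gpu'` raises a configuration error.

Training defaults follow the recipe the networks were designed around (batch
size 2, Adam, learning rate 1e-4); SGD with momentum remains available as an
option.
`desk_scale_config` (batch 8, learning rate 1e-3, few epochs) is the preset
used by the benchmarks and tests so they converge in minutes on one CPU.

### Problem sizes in tests and the acceptance script

Clinical-scale results would need hundreds of real tongue photographs and
far longer training, so the shipped benchmarks are deliberately small — the
package's own choices, recorded here:

| benchmark | data | model | budget |
| --- | --- | --- | --- |
| segmentation trainability | 60 scenes, 64×64 | base width 16 | ≤ 200 steps |
| classification trainability | 150 samples, 64×64 | widths (8,16,32,64,64), fc 128, fusion 32 | ≤ 10 epochs |
| ablation direction | 60 lip-contact samples, 48×48, lip similarity 0.85 | widths (8,16,32,32,32), fc 96, fusion 32 | 10 epochs × 5 rounds |

At these scales the segmentation benchmark reaches test Dice ≈ 0.99 and the
classification benchmark reaches test accuracy 1.0; the ablation reproduces
the expected direction (both couplings ≥ baseline) without claiming
magnitudes.

## Limitations

- The autodiff core implements only what these networks need (stride-1
  convolutions, 2× upsampling); it is not a general framework.
- Checkpoints (`.npz`) are content-deterministic but not byte-identical
  across runs because zip archives embed timestamps; reports are
  byte-identical.
- Synthetic benchmarks bound what can be claimed: trainability and coupling
  direction, not clinical performance.
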