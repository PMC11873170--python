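# ifrcnet

Two-level nested tongue-image analysis: an attention U-Net (**RCA-UNet**)
segments the tongue, and its predictions feed a dilated-stem CNN classifier
(**RCA-Net**) through two couplings — *mixed input* (the predicted mask joins
the image at the classifier input) and *feature fusion* (a pooled encoder
feature vector joins the classifier head). The combined model is **IF-RCNet**.

Tongue-shape classification (thin / normal / bulgy) is hard for a standalone
classifier because lips of near-tongue hue often touch the tongue boundary;
telling the classifier which pixels are tongue removes that ambiguity. The
package ships the full pipeline: attention blocks (RCBAM, MSAG), both
networks and their nesting, segmentation/classification metrics, a
five-round 70/10/20 cross-validation harness, a synthetic tongue-scene
generator (real clinical images cannot be distributed), and a CLI.

Everything runs on a pure-NumPy autodiff backend on one CPU — no
deep-learning framework is required. See `docs/methods.md` for the model,
metric definitions, and design decisions.

## Worked example

Generate a synthetic dataset, train the segmentation network, and inspect
the report (numbers below are from an actual run at these settings):

```bash
ifrcnet synth --n-per-class 20 --image-size 64 --seed 1 --out data/demo
ifrcnet train-seg --data data/demo --out runs/seg --image-size 64 --seed 1 \
    --config config.yaml
```

with `config.yaml`:

```yaml
seg_net: {base_width: 16}
training: {batch_size: 8, lr: 0.001, epochs: 40, max_steps: 200, patience: 5}
```

Training 200 optimizer steps on the 70% training split reaches, on the
held-out 10% test split:

```
dice 0.995   miou 0.993   mean Hausdorff 1.0 px
```

The same pipeline in Python, including the nested classifier (this is the
classification trainability benchmark; it reached test accuracy 1.000):

```python
from ifrcnet.data_pipeline import make_fold_plan, standardize
from ifrcnet.if_rcnet import FusionConfig, build_ifrcnet
from ifrcnet.rca_net import ClsNetConfig
from ifrcnet.rca_unet import RCAUNet, SegNetConfig
from ifrcnet.synthetic_data import SceneParams, make_dataset
from ifrcnet.training_eval import desk_scale_config, evaluate, train

samples = [standardize(s, 64) for s in make_dataset(50, SceneParams(image_size=64, seed=2))]
plan = make_fold_plan([s.id for s in samples], 2, labels=[s.label for s in samples])
train_ids, test_ids, eval_ids = plan.rounds[0]

seg = RCAUNet(SegNetConfig(base_width=8), seed=2)
train(seg, samples, (train_ids, eval_ids),
      desk_scale_config(seed=2, epochs=20, max_steps=150), "seg")
seg.eval()

model = build_ifrcnet(
    seg, "both",
    cls_cfg=ClsNetConfig(widths=(8, 16, 32, 64, 64), fc_nodes=(128, 128, 3)),
    fusion_cfg=FusionConfig(fusion_width=32), seed=2)
train(model, samples, (train_ids, eval_ids), desk_scale_config(seed=2, epochs=10), "cls")

by_id = {s.id: s for s in samples}
print(evaluate(model, [by_id[i] for i in test_ids], "cls").to_json())
# {"accuracy": 1.0, "f1": 1.0, ...}
```

### Ablation

On a deliberately hard benchmark (lips touching the tongue, lip hue 85%
blended toward tongue hue), five-round cross-validation reproduces the
expected coupling direction (actual run, seed 3, settings as in
`tests/test_acceptance.py`):

```
configuration  accuracy        f1
base            0.9000    0.8756
mixed           0.9333    0.9111
fusion          1.0000    1.0000
both            0.9667    0.9644
```

Run it via `ifrcnet ablation --data ... --out ... --config ...`.

## CLI

| command | purpose |
| --- | --- |
| `ifrcnet synth` | generate a synthetic labelled dataset (images, masks, labels.csv) |
| `ifrcnet train-seg` | train RCA-UNet on one split; test report + checkpoint |
| `ifrcnet train-cls` | train standalone RCA-Net (the ablation baseline) |
| `ifrcnet train-joint` | two-phase IF-RCNet training (`--ablation base|mixed|fusion|both`) |
| `ifrcnet cv` | five-round cross-validation of RCA-Net |
| `ifrcnet ablation` | the four-configuration ablation table |
| `ifrcnet predict-seg` | predict masks for a directory of images |
| `ifrcnet eval` | score a saved checkpoint on a dataset |

All commands are seeded and CPU-deterministic: the same command run twice
produces byte-identical reports. Model/training settings come from a YAML
config with sections `seg_net`, `cls_net`, `fusion`, `training`.

## Reproduction

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

trains the three desk-scale benchmarks (segmentation trainability,
classification trainability, ablation direction) and writes their headline
quantities as JSON — roughly 10–15 minutes on one CPU. The library defaults
(batch 2, Adam, learning rate 1e-4) target full-scale training; the
benchmarks use `desk_scale_config` (batch 8, learning rate 1e-3) so they
converge in minutes. Full-scale clinical results require data that cannot be
distributed; see the "Problem sizes" section of `docs/methods.md`.
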