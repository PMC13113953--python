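# edgeunet

Edge-aware U-Net with boundary-sensitive optimization for
histopathology-style binary segmentation.

## What this is for

Segmentation quality in renal pathology is judged at the boundary:
glomerular areas, interstitial fractions and similar morphometric
readouts are computed from mask contours, so a model with excellent bulk
overlap but blurry borders is clinically much less useful than its Dice
score suggests. This package implements, as a tested and reusable
toolkit, a segmentation approach that attacks the boundary problem from
both the architecture and the objective:

* an **edge-gated U-Net** — a standard encoder–decoder with skip
  connections, augmented at two scales with Sobel-driven attention
  gates `E = σ(conv1×1(‖Sobel(x)‖))` that multiply and concatenate with
  the feature maps, plus auxiliary low-resolution boundary/edge heads
  under deep supervision;
* a **boundary-sensitive loss** — `L = λ₁·L_wBCE + λ₂·L_bDice` with
  λ₁ = 0.6, λ₂ = 0.4, where the weighted BCE (β = 2.5 on the foreground
  class) handles class imbalance and the boundary Dice term restricts
  its sums to a band of pixels within Chebyshev radius 3 of the mask
  border, penalizing contour misalignment specifically.

Because clinical kidney datasets are rarely shareable, the package ships
a synthetic histology-like data generator (elliptical glomerulus-like
blobs and ring-shaped tubule-like objects, per-patient stain shifts,
noise, patient-level grouping) so the entire pipeline — patient-level
splitting, training, evaluation, ablation, statistical reporting — runs
end to end with known ground truth and no downloads.

The network and trainer run on a small NumPy reverse-mode autodiff
engine included in the package (no deep-learning framework dependency);
every gradient is finite-difference-checked in the test suite.

## Worked example

```python
from edgeunet import (SyntheticConfig, generate_dataset, split_by_patient,
                      build_model, TrainConfig)

cfg = SyntheticConfig(n_patients=30, images_per_patient=6, image_size=64,
                      foreground_contrast=0.6, noise_sd=0.02, seed=42)
samples = generate_dataset(cfg)                       # 180 image/mask pairs
train_set, val_set, test_set = split_by_patient(samples, (2/3, 1/6, 1/6),
                                                seed=42)

model = build_model(input_size=64, base_channels=16, variant="full", seed=42)
results = model.fit(train_set, val_set,
                    train_config=TrainConfig(seed=42, epochs=15))
print(results.summary())
report = results.evaluate(test_set)
print(report.summary())
```

which prints (abridged):

```
Edge-aware U-Net training results (variant=full)
  epochs run      : 15
  best epoch      : 15
  best val loss   : 0.662105
  final val Dice  : 0.8672
  final val IoU   : 0.7701
  final lr        : 1.00e-04
metric           mean       sd               95% CI
dice           0.9087   0.0343 [0.8968, 0.9207]
iou            0.8345   0.0576 [0.8146, 0.8553]
hd95           2.6194   4.2999 [1.3666, 4.3327]
boundary_f1    0.9683   0.0281 [0.9579, 0.9774]
precision      0.8349   0.0574 [0.8151, 0.8554]
recall         0.9994   0.0018 [0.9987, 0.9999]
...
```

Held-out Dice ~0.91 with boundary F1 ~0.97 says the model recovers both
the bulk of the synthetic structures and their contours (nearly all
predicted border pixels fall within 2 px of a true border). Recall near
1 with precision ~0.83 is the signature of the foreground weighting
β = 2.5: the objective deliberately prefers slight over-segmentation to
missed tissue. Numbers are deterministic for the seeds shown; aggregate
rows carry bootstrap 95% CIs.

The same stages are available from the shell via a YAML config:

```sh
edgeunet generate --config run.yaml     # dataset + manifest on disk
edgeunet train --config run.yaml        # history.csv, checkpoint.npz
edgeunet evaluate --config run.yaml     # per-image + aggregate metrics
edgeunet ablate --config run.yaml       # 4 variants, table + paired stats
edgeunet sweep-lambda --config run.yaml # λ₁ grid search
edgeunet report runs/a runs/b -o report.md
```

## Layout

| path | contents |
|------|----------|
| `src/edgeunet/synthetic.py` | synthetic dataset generator, patient-level split, disk writer |
| `src/edgeunet/data.py` | paired image/mask loading, normalization, augmentation |
| `src/edgeunet/edges.py` | Sobel magnitude, boundary band, edge targets, gated conv |
| `src/edgeunet/losses.py` | weighted BCE, boundary Dice, composite multi-task loss |
| `src/edgeunet/autodiff.py`, `nn.py` | NumPy autodiff engine, layers, Adam |
| `src/edgeunet/network.py` | the edge-aware U-Net and its ablation variants |
| `src/edgeunet/trainer.py` | training loop, early stopping, LR plateau, prediction |
| `src/edgeunet/metrics.py` | Dice/IoU/HD95/boundary-F1, image quality, bootstrap CIs, paired tests, morphometry |
| `src/edgeunet/experiments.py` | canned desk-scale study protocols |
| `src/edgeunet/pipeline.py`, `cli.py` | YAML-driven stages and the `edgeunet` CLI |
| `docs/methods.md` | model, conventions, design choices, limitations |

See `docs/methods.md` for the scientific details and the exact
conventions behind every metric.
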