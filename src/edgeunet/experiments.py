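"""Canned desk-scale study protocols.

Two reference experiments used by the test suite, the acceptance script
and the worked README example:

* :func:`smoke_study` — train the full edge-aware variant on a small
  high-contrast synthetic cohort (120 train / 30 val / 30 test images at
  64x64, 15 epochs, batch 8, Adam 1e-4) and evaluate on the held-out
  patients. A recovery check: the model must essentially solve this
  easy dataset.
* :func:`ring_ablation_study` — the boundary-metric ablation: train the
  full and baseline variants on thin-ring-only datasets over several
  seeds and compare median HD95 on held-out images. Rings are the
  synthetic analogue of tubule cross-sections, where boundary accuracy
  dominates the metric. Each run trains for 30 epochs so both variants
  are compared after convergence (desk-scale datasets provide an order
  of magnitude fewer optimizer steps per epoch than the full-scale
  schedule).

Problem sizes are fixed here on purpose: they are the package's
reference conditions, not tunables.
"""

from __future__ import annotations

import numpy as np

from .metrics import hd95
from .network import build_model
from .synthetic import SyntheticConfig, generate_dataset, split_by_patient
from .trainer import TrainConfig, train

__all__ = ["smoke_study", "ring_ablation_study"]

SMOKE_BASE_CHANNELS = 16
SMOKE_IMAGE_SIZE = 64


def smoke_study(seed: int = 42, epochs: int = 15) -> dict:
    """Train + evaluate the full variant on the easy synthetic cohort.

    Returns the training results, the held-out MetricsReport, and the
    headline scalars (mean test Dice / IoU / HD95).
    """
    cfg = SyntheticConfig(
        n_patients=30, images_per_patient=6, image_size=SMOKE_IMAGE_SIZE,
        foreground_contrast=0.6, noise_sd=0.02, seed=seed,
    )
    samples = generate_dataset(cfg)
    # 30 patients x 6 images; whole-patient apportionment gives 120/30/30
    tr, va, te = split_by_patient(samples, (2 / 3, 1 / 6, 1 / 6), seed=seed)
    model = build_model(input_size=SMOKE_IMAGE_SIZE,
                        base_channels=SMOKE_BASE_CHANNELS,
                        variant="full", seed=seed)
    results = train(model, tr, va, config=TrainConfig(seed=seed, epochs=epochs))
    report = results.evaluate(te, ci_seed=seed)
    agg = report.aggregates
    return {
        "results": results,
        "report": report,
        "n_train": len(tr), "n_val": len(va), "n_test": len(te),
        "dice": float(agg.loc["dice", "mean"]),
        "iou": float(agg.loc["iou", "mean"]),
        "hd95": float(agg.loc["hd95", "mean"]),
        "boundary_f1": float(agg.loc["boundary_f1", "mean"]),
    }


def _one_ring_run(variant: str, seed: int, epochs: int) -> dict:
    cfg = SyntheticConfig(
        n_patients=20, images_per_patient=6, image_size=SMOKE_IMAGE_SIZE,
        object_kinds=("ring",), foreground_contrast=0.6, noise_sd=0.02,
        seed=seed,
    )
    samples = generate_dataset(cfg)
    tr, va, te = split_by_patient(samples, (0.6, 0.2, 0.2), seed=seed)
    model = build_model(input_size=SMOKE_IMAGE_SIZE,
                        base_channels=SMOKE_BASE_CHANNELS,
                        variant=variant, seed=seed)
    results = train(model, tr, va, config=TrainConfig(seed=seed, epochs=epochs))
    preds = results.predict(te)
    dists = [hd95(s.mask, p) for s, p in zip(te, preds)]
    return {"median_hd95": float(np.median(dists)), "results": results}


def ring_ablation_study(seeds=(0, 1, 2), epochs: int = 30,
                        variants=("full", "baseline")) -> dict:
    """Median held-out HD95 per variant over seeds on thin-ring data.

    Returns per-variant per-seed medians, the across-seed median, and
    the last run's history (for loss-decomposition checks).
    """
    out: dict = {"per_seed": {}, "median": {}}
    history = None
    for variant in variants:
        per_seed = []
        for seed in seeds:
            run = _one_ring_run(variant, seed, epochs)
            per_seed.append(run["median_hd95"])
            if variant == "full":
                history = run["results"].history
        out["per_seed"][variant] = per_seed
        out["median"][variant] = float(np.median(per_seed))
    out["full_history"] = history
    return out
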