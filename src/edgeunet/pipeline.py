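"""End-to-end pipeline stages driven by one configuration.

A single global seed fans out to per-stage seeds through a stable
derivation (seed mixed with a stage-name hash), so each stage is
independently reproducible without ever reusing a raw seed across
stages. Stage outputs are plain files: PNG datasets, CSV histories and
metric tables, Markdown reports.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import AugmentConfig, PreprocessConfig, load_pairs
from .losses import LossWeights, lambda_sensitivity_sweep
from .metrics import (MetricsReport, evaluate_run, paired_compare,
                      tabulate_ablation, to_markdown_table)
from .network import EdgeAwareUNet, ModelConfig, build_model
from .synthetic import (SamplePair, SyntheticConfig, generate_dataset,
                        split_by_patient, write_dataset)
from .trainer import TrainConfig, TrainingResults, train

__all__ = ["RunConfig", "derive_seed", "cmd_generate", "cmd_train",
           "cmd_evaluate", "cmd_sweep_lambda", "cmd_ablate", "cmd_report"]

ABLATION_VARIANTS = {
    "A": ("baseline", "Baseline U-Net"),
    "B": ("edge_only", "Edge-Gated Only"),
    "C": ("boundary_only", "Boundary Loss Only"),
    "D": ("full", "Full Model (Edge + Boundary)"),
}


def derive_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: global seed mixed with a CRC32 of the stage name."""
    return int((global_seed * 1_000_003 + zlib.crc32(stage.encode())) % 2**31)


@dataclass
class RunConfig:
    """All stage configurations under one roof, loadable from YAML."""

    seed: int = 0
    data_dir: str | None = None          # paired images/ masks/ layout
    out_dir: str = "runs/run"
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossWeights = field(default_factory=LossWeights)
    threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("seed", "data_dir", "out_dir", "threshold"):
            if key in raw:
                kwargs[key] = raw[key]
        if "split_fractions" in raw:
            kwargs["split_fractions"] = tuple(raw["split_fractions"])
        sub = {"synthetic": SyntheticConfig, "preprocess": PreprocessConfig,
               "augment": AugmentConfig, "model": ModelConfig,
               "train": TrainConfig, "loss": LossWeights}
        for key, cls_ in sub.items():
            if key in raw:
                val = raw[key]
                if val is None:
                    kwargs[key] = None
                else:
                    if "objects_per_image" in val:
                        val["objects_per_image"] = tuple(val["objects_per_image"])
                    if "object_kinds" in val:
                        val["object_kinds"] = tuple(val["object_kinds"])
                    if "scale_range" in val:
                        val["scale_range"] = tuple(val["scale_range"])
                    if "ring_thickness" in val:
                        val["ring_thickness"] = tuple(val["ring_thickness"])
                    kwargs[key] = cls_(**val)
        return cls(**kwargs)


def _load_or_generate(config: RunConfig) -> list[SamplePair]:
    if config.data_dir:
        root = Path(config.data_dir)
        manifest = root / "manifest.csv"
        return load_pairs(root / "images", root / "masks", config.preprocess,
                          manifest=manifest if manifest.exists() else None)
    gen_cfg = SyntheticConfig(**{
        **{f.name: getattr(config.synthetic, f.name)
           for f in config.synthetic.__dataclass_fields__.values()},
        "seed": derive_seed(config.seed, "generate"),
    })
    return generate_dataset(gen_cfg)


def _splits(config: RunConfig, samples: list[SamplePair]):
    if all(s.split for s in samples):
        by = {"train": [], "val": [], "test": []}
        for s in samples:
            by[s.split].append(s)
        return by["train"], by["val"], by["test"]
    return split_by_patient(samples, config.split_fractions,
                            seed=derive_seed(config.seed, "split"))


def cmd_generate(config: RunConfig) -> Path:
    """Generate the synthetic dataset and write it to disk."""
    samples = _load_or_generate(config)
    split_by_patient(samples, config.split_fractions,
                     seed=derive_seed(config.seed, "split"))
    out = Path(config.out_dir) / "dataset"
    return write_dataset(samples, out)


def cmd_train(config: RunConfig) -> TrainingResults:
    """Train one model end to end; history and checkpoint land in out_dir."""
    samples = _load_or_generate(config)
    tr, va, _ = _splits(config, samples)
    model = build_model(ModelConfig(**{
        **{f.name: getattr(config.model, f.name)
           for f in config.model.__dataclass_fields__.values()},
        "seed": derive_seed(config.seed, "model"),
    }))
    tcfg = TrainConfig(**{
        **{f.name: getattr(config.train, f.name)
           for f in config.train.__dataclass_fields__.values()},
        "seed": derive_seed(config.seed, "train"),
    })
    results = train(model, tr, va, loss_weights=config.loss, config=tcfg,
                    augment_config=config.augment)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.history.to_csv(out / "history.csv", index=False)
    model.save(out / "checkpoint.npz")
    (out / "summary.txt").write_text(results.summary() + "\n")
    return results


def cmd_evaluate(config: RunConfig,
                 model: EdgeAwareUNet | None = None) -> MetricsReport:
    """Evaluate a trained model on the held-out test split."""
    if model is None:
        model = EdgeAwareUNet.load(Path(config.out_dir) / "checkpoint.npz")
    samples = _load_or_generate(config)
    _, _, te = _splits(config, samples)
    from .trainer import _predict_probs
    report = evaluate_run([s.mask for s in te],
                          list(_predict_probs(model, te)),
                          threshold=config.threshold,
                          ci_seed=derive_seed(config.seed, "bootstrap"))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.per_image.to_csv(out / "metrics_per_image.csv", index=False)
    report.aggregates.to_csv(out / "metrics_aggregate.csv")
    return report


def cmd_sweep_lambda(config: RunConfig, grid=None) -> pd.DataFrame:
    """Grid search over the wBCE/boundary-Dice mixing weight lambda1."""
    grid = list(grid) if grid is not None else [round(x, 1) for x in
                                                np.arange(0.1, 0.95, 0.2)]
    samples = _load_or_generate(config)
    tr, va, _ = _splits(config, samples)

    def train_fn(weights: LossWeights) -> dict:
        model = build_model(ModelConfig(**{
            **{f.name: getattr(config.model, f.name)
               for f in config.model.__dataclass_fields__.values()},
            "seed": derive_seed(config.seed, "model"),
        }))
        tcfg = TrainConfig(**{
            **{f.name: getattr(config.train, f.name)
               for f in config.train.__dataclass_fields__.values()},
            "seed": derive_seed(config.seed, "train"),
        })
        res = train(model, tr, va, loss_weights=weights, config=tcfg,
                    augment_config=config.augment)
        rep = res.evaluate(va)
        agg = rep.aggregates
        return {"dice": agg.loc["dice", "mean"], "iou": agg.loc["iou", "mean"],
                "hd95": agg.loc["hd95", "mean"]}

    table = lambda_sensitivity_sweep(train_fn, grid)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "lambda_sweep.csv", index=False)
    return table


def cmd_ablate(config: RunConfig) -> pd.DataFrame:
    """Train all four ablation variants on identical data and seed.

    Returns the configuration table (one row per variant A-D) and
    writes per-variant metrics plus paired Dice comparisons against
    the baseline.
    """
    samples = _load_or_generate(config)
    tr, va, te = _splits(config, samples)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_variant: dict[str, pd.DataFrame] = {}
    for code, (variant, label) in ABLATION_VARIANTS.items():
        model = build_model(ModelConfig(**{
            **{f.name: getattr(config.model, f.name)
               for f in config.model.__dataclass_fields__.values()},
            "variant": variant,
            "seed": derive_seed(config.seed, "model"),
        }))
        tcfg = TrainConfig(**{
            **{f.name: getattr(config.train, f.name)
               for f in config.train.__dataclass_fields__.values()},
            "seed": derive_seed(config.seed, "train"),
        })
        res = train(model, tr, va, loss_weights=config.loss, config=tcfg,
                    augment_config=config.augment)
        rep = res.evaluate(te, ci_seed=derive_seed(config.seed, "bootstrap"))
        per_variant[f"{code}: {label}"] = rep.per_image
        rep.per_image.to_csv(out / f"ablation_{code}_per_image.csv", index=False)
    table = tabulate_ablation(per_variant)
    table.to_csv(out / "ablation_table.csv")
    comparisons = []
    base_key = next(k for k in per_variant if k.startswith("A"))
    for key, df in per_variant.items():
        if key == base_key:
            continue
        for metric in ("dice", "iou", "hd95"):
            c = paired_compare(df[metric], per_variant[base_key][metric],
                               metric=metric)
            comparisons.append({"configuration": key, "metric": metric,
                                "p_value": c.p_value, "cohens_d": c.cohens_d,
                                "n": c.n})
    pd.DataFrame(comparisons).to_csv(out / "ablation_comparisons.csv",
                                     index=False)
    return table


def cmd_report(run_dirs: list[str | Path], out_path: str | Path) -> str:
    """Collate per-run metrics into a Markdown report.

    One section of mean +/- SD with bootstrap CIs per run; when exactly
    two runs are given, a paired-comparison section (t-test p-value and
    Cohen's d per metric) is appended.
    """
    frames = {}
    for d in run_dirs:
        d = Path(d)
        f = d / "metrics_per_image.csv"
        if not f.exists():
            raise FileNotFoundError(f"run {d} has no metrics_per_image.csv")
        frames[d.name] = pd.read_csv(f)
    lines = ["# Segmentation report", ""]
    for name, df in frames.items():
        rep = MetricsReport(df, ci_seed=0)
        lines += [f"## {name}", "", to_markdown_table(rep.aggregates), ""]
    if len(frames) == 2:
        (name_a, df_a), (name_b, df_b) = frames.items()
        lines += [f"## Paired comparison: {name_a} vs {name_b}", ""]
        rows = []
        for metric in df_a.columns:
            c = paired_compare(df_a[metric], df_b[metric], metric=metric)
            rows.append({"metric": metric, "p_value": c.p_value,
                         "cohens_d": c.cohens_d, "n": c.n})
        lines += [to_markdown_table(pd.DataFrame(rows).set_index("metric")), ""]
    text = "\n".join(lines)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(text)
    return text


def run_manifest(config: RunConfig) -> dict:
    """Structured provenance record for logging."""
    import edgeunet
    cfg_json = json.dumps(config, default=lambda o: getattr(o, "__dict__",
                                                            str(o)),
                          sort_keys=True)
    return {
        "version": edgeunet.__version__,
        "config_hash": f"{zlib.crc32(cfg_json.encode()):08x}",
        "seed": config.seed,
    }
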