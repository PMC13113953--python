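"""Segmentation evaluation: overlap, boundary and image-quality metrics,
bootstrap confidence intervals, paired model comparison, and mask-derived
morphometry.

Conventions for degenerate inputs (relevant for sparse synthetic masks):
Dice / IoU / volumetric similarity of two empty masks are 1.0, their HD95
is 0.0; HD95 with exactly one empty mask is the image diagonal, a sentinel
for "no boundary to match".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from skimage.metrics import structural_similarity

from .edges import _border_pixels, _require_binary

__all__ = [
    "dice",
    "iou",
    "hd95",
    "boundary_f1",
    "confusion_metrics",
    "image_quality",
    "bootstrap_ci",
    "paired_compare",
    "PairedComparison",
    "morphometry",
    "correlate",
    "evaluate_run",
    "MetricsReport",
    "tabulate_ablation",
]

PSNR_CAP = 100.0  # dB, reported for identical inputs (MSE = 0)


# ---------------------------------------------------------------- overlap

def dice(y: np.ndarray, p: np.ndarray) -> float:
    """Dice coefficient 2|Y∩P| / (|Y|+|P|); both-empty -> 1.0."""
    y = _require_binary(y, "y")
    p = _require_binary(p, "p")
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    denom = y.sum() + p.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(y, p).sum() / denom)


def iou(y: np.ndarray, p: np.ndarray) -> float:
    """Jaccard index |Y∩P| / |Y∪P|; both-empty -> 1.0."""
    y = _require_binary(y, "y")
    p = _require_binary(p, "p")
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    union = np.logical_or(y, p).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(y, p).sum() / union)


# --------------------------------------------------------------- boundary

def _border_coords(mask: np.ndarray) -> np.ndarray:
    return np.argwhere(_border_pixels(mask))


def hd95(y: np.ndarray, p: np.ndarray, spacing: float = 1.0) -> float:
    """95th-percentile symmetric boundary distance.

    Nearest-neighbour Euclidean distances from each border pixel of one
    mask to the border set of the other, pooled over both directions;
    the 95th percentile of that multiset is returned. Pooling (rather
    than a max of directed percentiles) keeps the statistic symmetric
    by construction.
    """
    y = _require_binary(y, "y")
    p = _require_binary(p, "p")
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    by, bp = _border_coords(y), _border_coords(p)
    if len(by) == 0 and len(bp) == 0:
        return 0.0
    if len(by) == 0 or len(bp) == 0:
        return float(np.hypot(*y.shape) * spacing)
    d_yp = cKDTree(bp).query(by)[0]
    d_py = cKDTree(by).query(bp)[0]
    pooled = np.concatenate([d_yp, d_py])
    return float(np.percentile(pooled, 95) * spacing)


def boundary_f1(y: np.ndarray, p: np.ndarray, tolerance: float = 2.0) -> float:
    """F1 over border pixels matched within a Euclidean ``tolerance``."""
    y = _require_binary(y, "y")
    p = _require_binary(p, "p")
    by, bp = _border_coords(y), _border_coords(p)
    if len(by) == 0 and len(bp) == 0:
        return 1.0
    if len(by) == 0 or len(bp) == 0:
        return 0.0
    prec = float((cKDTree(by).query(bp)[0] <= tolerance).mean())
    rec = float((cKDTree(bp).query(by)[0] <= tolerance).mean())
    if prec + rec == 0:
        return 0.0
    return 2.0 * prec * rec / (prec + rec)


# -------------------------------------------------------------- confusion

def confusion_metrics(y: np.ndarray, p: np.ndarray) -> dict[str, float]:
    """Precision, recall, specificity and volumetric similarity.

    Volumetric similarity is 1 - ||Y|-|P|| / (|Y|+|P|), i.e. agreement
    of foreground volumes irrespective of overlap; both-empty -> 1.
    """
    y = _require_binary(y, "y")
    p = _require_binary(p, "p")
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    tp = float(np.logical_and(y, p).sum())
    fp = float(np.logical_and(~y, p).sum())
    fn = float(np.logical_and(y, ~p).sum())
    tn = float(np.logical_and(~y, ~p).sum())
    vol = y.sum() + p.sum()
    return {
        "precision": tp / (tp + fp) if tp + fp > 0 else 1.0,
        "recall": tp / (tp + fn) if tp + fn > 0 else 1.0,
        "specificity": tn / (tn + fp) if tn + fp > 0 else 1.0,
        "vol_sim": 1.0 - abs(float(y.sum()) - float(p.sum())) / vol if vol > 0 else 1.0,
    }


# ---------------------------------------------------------- image quality

def image_quality(y: np.ndarray, p: np.ndarray) -> dict[str, float]:
    """PSNR, SSIM, MAE and RMSE between truth and probability map.

    Both inputs live in [0, 1] (data range 1). PSNR is -10 log10(MSE),
    capped at 100 dB for identical inputs; SSIM uses a 7x7 window with
    the standard constants.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    err = y - p
    mse = float(np.mean(err * err))
    psnr = PSNR_CAP if mse == 0 else min(PSNR_CAP, -10.0 * np.log10(mse))
    ssim = float(structural_similarity(y, p, data_range=1.0, win_size=7))
    return {
        "psnr": float(psnr),
        "ssim": ssim,
        "mae": float(np.mean(np.abs(err))),
        "rmse": float(np.sqrt(mse)),
    }


# ------------------------------------------------------------- statistics

def bootstrap_ci(
    values,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean.

    For tiny samples where the number of distinct resamples n**n does
    not exceed ``n_boot``, all resamples are enumerated and the CI is
    exact and deterministic; otherwise seeded Monte Carlo resampling
    is used.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values for a bootstrap CI")
    if n**n <= n_boot:
        means = np.array(
            [np.mean(c) for c in itertools.product(values, repeat=n)]
        )
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


@dataclass
class PairedComparison:
    """Paired two-sided t-test with effect size for one metric."""

    metric: str
    p_value: float
    cohens_d: float
    n: int


def paired_compare(a, b, metric: str = "") -> PairedComparison:
    """Two-sided paired t-test and Cohen's d on paired samples.

    Cohen's d for paired data: mean(a-b) / sd(a-b) with sample sd
    (ddof=1). All-zero differences are reported as d=0, p=1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedComparison(metric, 1.0, 0.0, n)
    res = stats.ttest_rel(a, b)
    return PairedComparison(metric, float(res.pvalue), float(d.mean() / sd), n)


# ------------------------------------------------------------ morphometry

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


def morphometry(mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Connected-component areas (8-connectivity, px^2) and foreground
    fraction of a binary mask — the basis for glomerular-area and
    interstitial-fraction readouts from predicted masks."""
    m = _require_binary(mask)
    labels, n = ndimage.label(m, structure=_STRUCT8)
    areas = np.bincount(labels.ravel())[1 : n + 1].astype(float)
    return areas, float(m.mean())


def correlate(a, b) -> float:
    """Pearson correlation coefficient."""
    r, _ = stats.pearsonr(np.asarray(a, float), np.asarray(b, float))
    return float(r)


# ------------------------------------------------------------- reporting

_METRIC_COLS = [
    "dice", "iou", "hd95", "boundary_f1", "precision", "recall",
    "specificity", "vol_sim", "psnr", "ssim", "mae", "rmse",
]


@dataclass
class MetricsReport:
    """Per-image metric rows plus aggregate mean, SD and bootstrap CI."""

    per_image: pd.DataFrame
    aggregates: pd.DataFrame = field(init=False)
    ci_seed: int | None = None

    def __post_init__(self) -> None:
        rows = []
        for col in self.per_image.columns:
            vals = self.per_image[col].to_numpy(dtype=float)
            lo, hi = bootstrap_ci(vals, seed=self.ci_seed) if len(vals) >= 2 else (
                float(vals[0]), float(vals[0]))
            rows.append({
                "metric": col,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "ci_low": lo,
                "ci_high": hi,
            })
        self.aggregates = pd.DataFrame(rows).set_index("metric")

    def summary(self) -> str:
        lines = [f"{'metric':<12} {'mean':>8} {'sd':>8} {'95% CI':>20}"]
        for m, row in self.aggregates.iterrows():
            lines.append(
                f"{m:<12} {row['mean']:>8.4f} {row['sd']:>8.4f} "
                f"[{row['ci_low']:.4f}, {row['ci_high']:.4f}]"
            )
        return "\n".join(lines)


def evaluate_run(
    truths,
    prob_maps,
    threshold: float = 0.5,
    ci_seed: int | None = 0,
) -> MetricsReport:
    """Full per-image evaluation of probability maps against truths.

    Overlap/boundary metrics are computed on the thresholded masks,
    image-quality metrics on the raw probability maps.
    """
    truths = list(truths)
    prob_maps = list(prob_maps)
    if len(truths) != len(prob_maps):
        raise ValueError(
            f"got {len(truths)} truths but {len(prob_maps)} predictions"
        )
    if not truths:
        raise ValueError("nothing to evaluate")
    rows = []
    for y, prob in zip(truths, prob_maps):
        y = np.asarray(y)
        prob = np.asarray(prob, dtype=float)
        p = (prob > threshold).astype(np.uint8)
        row = {
            "dice": dice(y, p),
            "iou": iou(y, p),
            "hd95": hd95(y, p),
            "boundary_f1": boundary_f1(y, p),
        }
        row.update(confusion_metrics(y, p))
        row.update(image_quality(y.astype(float), prob))
        rows.append(row)
    return MetricsReport(pd.DataFrame(rows, columns=_METRIC_COLS), ci_seed=ci_seed)


def tabulate_ablation(runs: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Aggregate ablation runs into one row per configuration.

    ``runs`` maps a configuration label (e.g. "A: baseline") to the
    per-image metrics DataFrame of that run; the output carries the
    mean Dice/IoU/HD95 per configuration.
    """
    rows = []
    for label, df in runs.items():
        rows.append({
            "configuration": label,
            "dice": float(df["dice"].mean()),
            "iou": float(df["iou"].mean()),
            "hd95": float(df["hd95"].mean()),
        })
    return pd.DataFrame(rows).set_index("configuration")


def to_markdown_table(df: pd.DataFrame, floatfmt: str = "{:.4f}") -> str:
    """Render a small DataFrame as a GitHub-style markdown table."""
    df = df.reset_index()
    headers = [str(c) for c in df.columns]

    def fmt(v):
        return floatfmt.format(v) if isinstance(v, float) else str(v)

    body = [[fmt(v) for v in row] for row in df.itertuples(index=False)]
    widths = [max(len(h), *(len(r[i]) for r in body)) for i, h in enumerate(headers)]
    def line(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    sep = "|" + "|".join("-" * (w + 2) for w in widths) + "|"
    return "\n".join([line(headers), sep] + [line(r) for r in body])
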