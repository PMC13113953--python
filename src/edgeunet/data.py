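"""Paired image/mask loading, normalization, resizing and augmentation.

The on-disk contract: an image directory and a mask directory whose
files pair by identical basename. 8-bit intensities are normalized as
``I / 255`` and masks binarized as ``round(M / 255)``; both are resized
to a square target (bilinear for images, nearest for masks so binarity
survives). RGB inputs are reduced to single-channel luminance by
default, matching the network's one-channel input.

Augmentation follows common histopathology practice: random 90-degree
rotation, horizontal flip, and a mild uniform zoom, each fired
independently with its configured probability; image and mask always
receive the identical geometric transform.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.transform import resize

from .synthetic import SamplePair

__all__ = ["PreprocessConfig", "AugmentConfig", "load_pairs", "augment"]

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


@dataclass(frozen=True)
class PreprocessConfig:
    target_size: int = 256
    grayscale: bool = True

    def __post_init__(self) -> None:
        if self.target_size % 8:
            raise ValueError("target_size must be divisible by 8")


@dataclass(frozen=True)
class AugmentConfig:
    p_rot90: float = 0.5
    p_hflip: float = 0.5
    p_scale: float = 0.5
    scale_range: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self) -> None:
        for name in ("p_rot90", "p_hflip", "p_scale"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")


def _read_image(path: Path) -> np.ndarray:
    try:
        return np.asarray(iio.imread(path))
    except Exception as exc:  # decode failure
        raise ValueError(f"cannot decode image file {path}") from exc


def _index_dir(d: Path) -> dict[str, Path]:
    return {p.stem: p for p in sorted(d.iterdir())
            if p.suffix.lower() in _IMAGE_SUFFIXES}


def load_pairs(
    image_dir: str | Path,
    mask_dir: str | Path,
    config: PreprocessConfig | None = None,
    manifest: str | Path | None = None,
) -> list[SamplePair]:
    """Load every image/mask pair under the two directories.

    Raises if any image lacks a same-name mask (or vice versa), naming
    the orphan. An optional manifest CSV supplies patient ids, class
    labels and split tags; without one, each image is its own patient.
    """
    cfg = config or PreprocessConfig()
    images = _index_dir(Path(image_dir))
    masks = _index_dir(Path(mask_dir))
    orphans = sorted(set(images) ^ set(masks))
    if orphans:
        raise ValueError(f"unpaired files (no image/mask partner): {orphans}")
    if not images:
        raise ValueError(f"no images found under {image_dir}")

    meta: dict[str, dict[str, str]] = {}
    if manifest is not None:
        with open(manifest, newline="") as fh:
            for row in csv.DictReader(fh):
                meta[row["name"]] = row

    size = cfg.target_size
    pairs = []
    for name in sorted(images):
        img = _read_image(images[name]).astype(np.float64) / 255.0
        if img.ndim == 3:
            img = rgb2gray(img[..., :3]) if cfg.grayscale else img[..., :3]
        msk = _read_image(masks[name]).astype(np.float64)
        if msk.ndim == 3:
            msk = msk[..., 0]
        msk = np.round(msk / 255.0)
        if img.shape[:2] != (size, size):
            img = resize(img, (size, size), order=1, mode="edge",
                         anti_aliasing=False)
        if msk.shape != (size, size):
            msk = resize(msk, (size, size), order=0, mode="edge",
                         anti_aliasing=False)
        info = meta.get(name, {})
        pairs.append(SamplePair(
            image=np.clip(img, 0.0, 1.0).astype(np.float32),
            mask=msk.astype(np.uint8),
            patient_id=info.get("patient_id", name),
            class_label=info.get("class_label", ""),
            name=name,
            split=info.get("split", ""),
        ))
    return pairs


def _zoom(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Uniform zoom returned at the original shape.

    Zoom-out is reflection-padded back to size; zoom-in is center-
    cropped. Nearest (order 0) keeps masks binary.
    """
    h, w = arr.shape[:2]
    zoomed = ndimage.zoom(arr, factor, order=order, mode="reflect",
                          grid_mode=True)
    zh, zw = zoomed.shape[:2]
    if zh >= h:
        top, left = (zh - h) // 2, (zw - w) // 2
        return zoomed[top:top + h, left:left + w]
    pad_h, pad_w = h - zh, w - zw
    return np.pad(zoomed,
                  ((pad_h // 2, pad_h - pad_h // 2),
                   (pad_w // 2, pad_w - pad_w // 2)),
                  mode="reflect")


def augment(sample: SamplePair, config: AugmentConfig,
            rng: np.random.Generator) -> SamplePair:
    """Apply one random geometric augmentation draw to a sample.

    The three transforms fire independently; image and mask get the
    same geometry and the mask stays binary throughout.
    """
    img, msk = sample.image, sample.mask
    if img.shape[:2] != msk.shape:
        raise ValueError(f"image/mask shape mismatch: {img.shape} vs {msk.shape}")
    if rng.random() < config.p_rot90:
        k = int(rng.integers(1, 4))
        img = np.rot90(img, k)
        msk = np.rot90(msk, k)
    if rng.random() < config.p_hflip:
        img = np.fliplr(img)
        msk = np.fliplr(msk)
    if rng.random() < config.p_scale:
        factor = float(rng.uniform(*config.scale_range))
        img = _zoom(img, factor, order=1)
        msk = _zoom(msk.astype(np.uint8), factor, order=0)
    return SamplePair(
        image=np.ascontiguousarray(img, dtype=np.float32),
        mask=np.ascontiguousarray(msk, dtype=np.uint8),
        patient_id=sample.patient_id,
        class_label=sample.class_label,
        name=sample.name,
        split=sample.split,
    )
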