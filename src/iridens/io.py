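"""Reading and writing frames, masks and iris photographs.

Grayscale frames are 8-bit PNG/TIFF; masks are 8-bit label PNGs with
codes 0=background, 1=cornea, 2=iris, 3=lateral; iris ROI masks are
binary PNGs (0/255); iris photographs are RGB PNG/TIFF/JPEG.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import MaskMismatch, NotColorImage
from .segmentation import (
    RegionMasks,
    ScheimpflugFrame,
    label_image_to_masks,
    masks_to_label_image,
)

__all__ = [
    "load_frame",
    "load_masks",
    "save_masks",
    "load_rgb_image",
    "load_binary_mask",
    "save_gray_image",
]


def load_frame(
    path: str | Path, eye_id: str | None = None, meridian_index: int = 1
) -> ScheimpflugFrame:
    """Load an 8-bit grayscale frame; RGB files are reduced by channel mean."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    if eye_id is None:
        eye_id = Path(path).stem
    return ScheimpflugFrame(
        pixels=np.clip(np.round(img), 0, 255).astype(np.uint8),
        eye_id=eye_id,
        meridian_index=meridian_index,
    )


def load_masks(path: str | Path) -> RegionMasks:
    """Load a label PNG (0/1/2/3) as external-provenance region masks."""
    label = iio.imread(path)
    if label.ndim != 2:
        raise MaskMismatch("label image must be single-channel")
    return label_image_to_masks(label, provenance="external")


def save_masks(path: str | Path, masks: RegionMasks) -> None:
    iio.imwrite(path, masks_to_label_image(masks))


def load_rgb_image(path: str | Path) -> np.ndarray:
    """Load an RGB photograph as a uint8 (H, W, 3) array."""
    img = iio.imread(path)
    if img.ndim != 3 or img.shape[-1] < 3:
        raise NotColorImage(f"{path} is not a color image")
    return np.asarray(img[..., :3], dtype=np.uint8)


def load_binary_mask(path: str | Path) -> np.ndarray:
    """Load a 0/255 (or 0/1) mask PNG as a boolean array."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return np.asarray(img) > 0


def save_gray_image(path: str | Path, pixels: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(pixels, dtype=np.uint8))
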