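"""Foreground mask generation and image-quality metrics.

Plants are imaged against a white background, so the foreground mask is
an intensity threshold (pixels darker than the background), cleaned by
3x3 erosion/dilation, keeping only the largest 8-connected component —
which in practice is the plant. Render fidelity is reported as PSNR and
as masked PSNR, which averages the squared error only over foreground
pixels so the trivially-rendered white background cannot inflate the
score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyResultError

logger = logging.getLogger(__name__)

#: PSNR reported for identical images (avoids infinity in reports).
PSNR_CAP_DB = 100.0
#: ITU-R BT.601 luma weights.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class MaskedImage:
    rgb: np.ndarray    # (H, W, 3) uint8
    mask: np.ndarray   # (H, W) bool, True = foreground

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.rgb.shape[:2] != self.mask.shape:
            raise ValueError("rgb and mask shapes differ")


def make_mask(rgb: np.ndarray, threshold: float = 240.0,
              erode_iter: int = 1, dilate_iter: int = 1) -> np.ndarray:
    """Foreground mask of a white-background 8-bit RGB image.

    Pixels with BT.601 luma below ``threshold`` are foreground; 3x3
    erosion then dilation removes speckle noise, and only the largest
    8-connected component is kept.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    luma = rgb.astype(float) @ _LUMA
    mask = luma < threshold
    footprint = np.ones((3, 3), dtype=bool)
    for _ in range(erode_iter):
        mask = ndimage.binary_erosion(mask, structure=footprint)
    for _ in range(dilate_iter):
        mask = ndimage.binary_dilation(mask, structure=footprint)
    if not mask.any():
        raise EmptyResultError("no foreground found")
    labels, n = ndimage.label(mask, structure=footprint)  # 8-connectivity
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _check_pair(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def psnr(a: np.ndarray, b: np.ndarray) -> float:
    """10 log10(255^2 / MSE) over all pixels and channels, in dB.

    Identical images return the 100-dB cap.
    """
    a, b = _check_pair(a, b)
    mse = float(((a - b) ** 2).mean())
    if mse == 0:
        return PSNR_CAP_DB
    return float(10.0 * np.log10(255.0**2 / mse))


def masked_psnr(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """PSNR with the MSE averaged only over mask-true pixels (3 channels)."""
    a, b = _check_pair(a, b)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != a.shape[:2]:
        raise ValueError("mask shape must match the image height/width")
    if not mask.any():
        raise EmptyResultError("empty mask")
    mse = float(((a[mask] - b[mask]) ** 2).mean())
    if mse == 0:
        return PSNR_CAP_DB
    return float(10.0 * np.log10(255.0**2 / mse))
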