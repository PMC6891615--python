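"""Data augmentation with exact factor arithmetic.

Three augmentation methods expand small leaf datasets:

* **Sliding-crop translation** with a perfect-square factor ``F``: the image
  is resized to ``S x S`` with ``S = crop + sqrt(F) - 1`` and all ``F``
  one-pixel-shifted ``crop x crop`` windows are enumerated row-major.  The
  factor/resize pairs used throughout the dataset recipes are (256, 900),
  (236, 100), (231, 25), (228, 4) and (237, 121), each satisfying
  ``(S - crop + 1)**2 = F``.
* **Horizontal mirror** (left-right reflection).
* **Small-angle rotation**: the ten angles -5..-1 and +1..+5 degrees,
  bilinear interpolation, black fill, output dimensions preserved.

Enumeration (not sampling) of the crop windows is what makes the advertised
factor counts exact and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as sk_resize
from skimage.transform import rotate as sk_rotate

__all__ = ["AugmentationSpec", "translate_crops", "mirror", "rotations",
           "ROTATION_ANGLES", "resize_side"]

ROTATION_ANGLES: tuple[int, ...] = (-5, -4, -3, -2, -1, 1, 2, 3, 4, 5)


@dataclass(frozen=True)
class AugmentationSpec:
    """Declarative description of an augmentation stage.

    ``translation_factor`` must be a perfect square (or None to skip);
    ``rotation_angles`` excludes 0 by construction.
    """

    translation_factor: int | None = None
    mirror: bool = False
    rotation_angles: tuple[int, ...] = ()
    crop_size: int = 227

    def __post_init__(self) -> None:
        if self.translation_factor is not None:
            _sqrt_factor(self.translation_factor)
        if 0 in self.rotation_angles:
            raise ValueError("rotation angles must exclude 0")
        if self.crop_size < 1:
            raise ValueError("crop_size must be >= 1")


def _sqrt_factor(F: int) -> int:
    s = math.isqrt(int(F))
    if s * s != F or F < 1:
        raise ValueError(f"translation factor must be a perfect square >= 1, got {F}")
    return s


def resize_side(F: int, crop: int = 227) -> int:
    """Side S of the pre-crop resize: S = crop + sqrt(F) - 1."""
    return crop + _sqrt_factor(F) - 1


def _resize_uint8(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = sk_resize(
        image.astype(float), shape + image.shape[2:], order=1,
        mode="reflect", anti_aliasing=False, preserve_range=True,
    )
    return np.clip(out, 0, 255).round().astype(np.uint8)


def translate_crops(image: np.ndarray, F: int, crop: int = 227) -> list[np.ndarray]:
    """All F one-pixel-shifted crop x crop windows of the resized image.

    The image is first resized (bilinear) to ``S x S`` with
    ``S = crop + sqrt(F) - 1``; the ``(sqrt(F))**2`` axis-aligned windows are
    returned in row-major scan order, so crop ``(i, j)`` starts at pixel
    ``(i, j)``.
    """
    image = np.asarray(image)
    s = _sqrt_factor(F)
    S = crop + s - 1
    resized = _resize_uint8(image, (S, S))
    return [
        resized[i : i + crop, j : j + crop].copy()
        for i in range(s)
        for j in range(s)
    ]


def mirror(image: np.ndarray) -> np.ndarray:
    """Horizontal (left-right) reflection; an involution."""
    return np.asarray(image)[:, ::-1].copy()


def rotations(image: np.ndarray,
              angles: tuple[int, ...] = ROTATION_ANGLES) -> list[np.ndarray]:
    """Rotate by each angle in -5..+5 degrees (0 excluded), black fill.

    Output dimensions equal input dimensions; pixels rotated out of frame are
    lost and exposed frame is filled black.  Bilinear interpolation.
    """
    image = np.asarray(image)
    outs = []
    for ang in angles:
        rot = sk_rotate(
            image.astype(float), ang, resize=False, order=1,
            mode="constant", cval=0, preserve_range=True,
        )
        outs.append(np.clip(rot, 0, 255).round().astype(np.uint8))
    return outs
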