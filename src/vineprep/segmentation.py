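"""Leaf segmentation onto an exact-black background, and leaf-patch harvest.

The downstream warping and patch operations rely on one contract only: in a
segmented image, background pixels are exactly (0,0,0) and every non-black
pixel is leaf.  ``segment_leaf`` is a documented stand-in for a full leaf
segmentation algorithm: green-dominance thresholding in HSV space, followed by
morphological closing and retention of the largest connected component.  Users
with a better mask (or ground truth) inject it through ``apply_mask``.

A true-black foreground pixel would be indistinguishable from background, so
masking nudges (0,0,0) foreground to (1,1,1) before zeroing the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hsv
from skimage.morphology import disk

__all__ = ["SegmentedLeafImage", "segment_leaf", "apply_mask",
           "leaf_patch_extract"]


@dataclass(frozen=True)
class SegmentedLeafImage:
    """RGB image whose background pixels are exactly (0,0,0)."""

    pixels: np.ndarray  # H x W x 3, uint8
    empty: bool = field(default=False)

    @property
    def foreground(self) -> np.ndarray:
        """Boolean H x W map of non-black pixels."""
        return (self.pixels != 0).any(axis=-1)


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected H x W x 3 RGB array, got shape {image.shape}")
    if image.dtype != np.uint8:
        raise ValueError(f"expected 8-bit image, got dtype {image.dtype}")
    return image


def apply_mask(image: np.ndarray, mask: np.ndarray) -> SegmentedLeafImage:
    """Zero the background of ``image`` according to a binary ``mask``.

    Foreground pixel values are preserved verbatim, except exact-black
    foreground pixels which are nudged to (1,1,1) so "non-black" remains an
    unambiguous foreground test.
    """
    image = _check_rgb(image)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != image.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {image.shape[:2]}"
        )
    out = image.copy()
    fg_black = mask & (out == 0).all(axis=-1)
    out[fg_black] = (1, 1, 1)
    out[~mask] = 0
    return SegmentedLeafImage(pixels=out, empty=not mask.any())


def segment_leaf(image: np.ndarray) -> SegmentedLeafImage:
    """Segment the dominant leaf from a color field photograph.

    Stand-in pipeline: green-dominance threshold in HSV (green hue band with
    non-trivial saturation/value, plus G exceeding both R and B in RGB),
    morphological closing with a small disk, hole filling, then the largest
    connected component.  Inputs whose background is already exactly black are
    passed through with their foreground untouched.

    Returns an empty-flagged all-black result (never raises) when no candidate
    foreground is found.
    """
    image = _check_rgb(image)
    nonblack = (image != 0).any(axis=-1)
    if not nonblack.any():
        return SegmentedLeafImage(pixels=np.zeros_like(image), empty=True)
    if not nonblack.all():
        # already segmented: honor idempotence on clean input
        return SegmentedLeafImage(pixels=image.copy(), empty=False)

    hsv = rgb2hsv(image)
    hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    r = image[..., 0].astype(int)
    g = image[..., 1].astype(int)
    b = image[..., 2].astype(int)
    green_hue = (hue > 0.16) & (hue < 0.50)
    cand = green_hue & (sat > 0.15) & (val > 0.08) & (g > r) & (g > b)
    if not cand.any():
        return SegmentedLeafImage(pixels=np.zeros_like(image), empty=True)

    cand = ndi.binary_opening(cand, structure=disk(2))  # drop speckle
    cand = ndi.binary_closing(cand, structure=disk(5))
    cand = ndi.binary_fill_holes(cand)
    labels, n = ndi.label(cand)
    if n == 0:
        return SegmentedLeafImage(pixels=np.zeros_like(image), empty=True)
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    return apply_mask(image, mask)


def leaf_patch_extract(
    seg: SegmentedLeafImage, patch: int = 64
) -> list[np.ndarray]:
    """Harvest non-overlapping ``patch`` x ``patch`` tiles with no black pixel.

    Tiles lie on a regular grid anchored at the top-left pixel; a tile is kept
    only if every pixel in it is non-black (pure leaf).  May return an empty
    list.
    """
    if patch < 1:
        raise ValueError("patch size must be >= 1")
    px = seg.pixels
    fg = seg.foreground
    h, w = fg.shape
    out: list[np.ndarray] = []
    for i in range(h // patch):
        for j in range(w // patch):
            r, c = i * patch, j * patch
            if fg[r : r + patch, c : c + patch].all():
                out.append(px[r : r + patch, c : c + patch].copy())
    return out
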