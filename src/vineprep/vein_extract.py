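"""Leaf-vein extraction pre-processings.

Two complementary pipelines expose vein structure before classification:

* **Gray-scale morphology processing (GMP)** — the bot-hat minus top-hat
  composition ``g = (closing(f) - f) - (f - opening(f))``, equivalently
  ``closing + opening - 2f``, with a flat square structuring element (default
  width 7).  Thin dark structures narrower than the element — veins on a leaf
  surface — produce a strong positive bot-hat response and map to high output
  values; thin bright structures drive the result negative and are clipped.

* **Canny edge pipeline** — grayscale conversion, Canny detection at
  ``sigma = 1.75``, removal of all 8-connected components of size exactly one
  (isolated speckle), and replication of the binary map onto three channels so
  the result drops into RGB-consuming models.

Computation runs in signed arithmetic and clips to [0, 255] on output.
Erosion/dilation use reflect padding at the borders, which avoids artificial
responses at leaf-patch edges.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, measure

__all__ = ["gmp_vein", "canny_vein"]


def gmp_vein(f: np.ndarray, se_width: int = 7) -> np.ndarray:
    """Highlight thin dark veins via bot-hat minus top-hat morphology.

    Parameters
    ----------
    f
        Single-channel gray image (any real dtype).
    se_width
        Width of the flat square structuring element; must be odd so the
        element is centered.  Default 7.

    Returns
    -------
    uint8 array, same shape: ``clip(closing + opening - 2 f, 0, 255)``.
    """
    f = np.asarray(f)
    if f.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape {f.shape}")
    if se_width < 1 or se_width % 2 == 0:
        raise ValueError(f"structuring element width must be odd, got {se_width}")
    work = f.astype(np.int32)
    size = (se_width, se_width)
    closing = ndi.grey_closing(work, size=size, mode="reflect")
    opening = ndi.grey_opening(work, size=size, mode="reflect")
    g = (closing - work) - (work - opening)
    return np.clip(g, 0, 255).astype(np.uint8)


def canny_vein(patch: np.ndarray, sigma: float = 1.75) -> np.ndarray:
    """Canny edge map with single-pixel speckle removed, as a 3-channel image.

    Parameters
    ----------
    patch
        RGB array (H x W x 3).
    sigma
        Gaussian smoothing scale of the Canny detector; must be positive.

    Returns
    -------
    uint8 H x W x 3 array with values in {0, 255}; guaranteed to contain no
    8-connected foreground component of size one.
    """
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[-1] != 3:
        raise ValueError(f"expected H x W x 3 input, got shape {patch.shape}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    # ITU-R 601 luminance weighting
    gray = patch.astype(float) @ np.array([0.299, 0.587, 0.114])
    edges = feature.canny(gray, sigma=sigma)
    edges = remove_single_pixels(edges)
    out = np.where(edges, 255, 0).astype(np.uint8)
    return np.repeat(out[..., None], 3, axis=-1)


def remove_single_pixels(binary: np.ndarray) -> np.ndarray:
    """Zero all 8-connected foreground components of size exactly one."""
    binary = np.asarray(binary).astype(bool)
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        return binary.copy()
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0  # background label is never a component
    singles = np.flatnonzero(sizes == 1)
    keep = binary.copy()
    keep[np.isin(labels, singles)] = False
    return keep
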