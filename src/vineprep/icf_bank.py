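"""Independent-component filter (ICF) banks learned from image patches.

A gray image is cut into non-overlapping ``p x p`` patches, vectorized into a
matrix ``X`` (``p**2`` rows, one column per patch; e.g. a 636 x 960 image at
``p = 12`` gives 144 x 4240).  Fixed-point FastICA with a kurtosis-style
contrast fits an unmixing matrix whose rows, reshaped to ``p x p``, act as
convolution filters tuned to the independent structure of the patch
population.  A deterministic subset (first three, last three, and the
remaining interior rows evenly spaced) is then convolved channel-wise with
color images as a pre-processing step, and large convolution outputs are cut
into a fixed grid of square blocks for downstream cropping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from vineprep.errors import IcaConvergenceError

__all__ = [
    "PatchMatrix",
    "FilterBank",
    "patchify",
    "unpatchify",
    "fit_ica",
    "select_filters",
    "convolve_bank",
    "select_blocks",
]


@dataclass(frozen=True)
class PatchMatrix:
    """Vectorized non-overlapping patches of one or more gray images.

    ``X`` has ``p**2`` rows and one column per patch, patches scanned
    row-major over the source image and vectorized row-major.
    """

    X: np.ndarray
    p: int
    source_dims: tuple[int, int]

    @property
    def n_patches(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class FilterBank:
    """Ordered set of square convolution filters from FastICA.

    ``W`` holds one unit-norm filter per row (each reshapable to ``p x p``);
    ``rotation`` is the whitened-space unmixing rotation retained for
    orthogonality diagnostics.
    """

    W: np.ndarray
    p: int
    seed: int
    rotation: np.ndarray | None = None

    @property
    def n_filters(self) -> int:
        return self.W.shape[0]

    def filter_image(self, i: int) -> np.ndarray:
        """Filter ``i`` reshaped to its square p x p form."""
        return self.W[i].reshape(self.p, self.p)


def patchify(gray: np.ndarray, p: int) -> PatchMatrix:
    """Cut a gray image into non-overlapping p x p patches, vectorized.

    Trailing rows/columns that do not fill a complete patch are dropped.  An
    image smaller than ``p x p`` yields an empty (0-column) matrix.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError(f"expected a single-channel image, got {gray.shape}")
    if p < 2:
        raise ValueError("patch side must be >= 2")
    h, w = gray.shape
    nh, nw = h // p, w // p
    crop = gray[: nh * p, : nw * p]
    # (nh, p, nw, p) -> (nh, nw, p, p) -> columns in row-major patch order
    tiles = crop.reshape(nh, p, nw, p).transpose(0, 2, 1, 3)
    X = tiles.reshape(nh * nw, p * p).T.astype(float)
    return PatchMatrix(X=X, p=p, source_dims=(h, w))


def unpatchify(pm: PatchMatrix) -> np.ndarray:
    """Reassemble the cropped source image from a patch matrix (round-trip)."""
    p = pm.p
    h, w = pm.source_dims
    nh, nw = h // p, w // p
    tiles = pm.X.T.reshape(nh, nw, p, p).transpose(0, 2, 1, 3)
    return tiles.reshape(nh * p, nw * p)


def fit_ica(X: PatchMatrix, seed: int, max_iter: int = 500) -> FilterBank:
    """Fit fixed-point FastICA on a patch matrix, returning p**2 filters.

    The contrast is the cube nonlinearity (kurtosis maximization).  Columns of
    ``X`` are the samples; the matrix is centered internally and must have at
    least as many columns as rows.  Raises :class:`IcaConvergenceError` when
    FastICA does not converge (rank-deficient or Gaussian-only data).
    """
    n_comp = X.p * X.p
    if X.n_patches < n_comp:
        raise ValueError(
            f"need at least {n_comp} patches to fit {n_comp} filters, "
            f"got {X.n_patches}"
        )
    data = X.X.T  # sklearn wants (n_samples, n_features)
    ica = FastICA(
        n_components=n_comp,
        algorithm="parallel",
        fun="cube",
        whiten="unit-variance",
        max_iter=max_iter,
        random_state=int(seed) & 0x7FFFFFFF,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ica.fit(data)
        except (ConvergenceWarning, np.linalg.LinAlgError, ValueError) as exc:
            raise IcaConvergenceError(
                f"FastICA failed to converge on a {n_comp} x {X.n_patches} "
                f"patch matrix: {exc}"
            ) from exc
    W = ica.components_.copy()
    rotation = W @ np.linalg.pinv(ica.whitening_)
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    if not np.all(norms > 0):
        raise IcaConvergenceError("FastICA produced a zero filter row")
    return FilterBank(W=W / norms, p=X.p, seed=int(seed), rotation=rotation)


def selection_indices(n: int, k: int = 25, mode: str = "spaced") -> np.ndarray:
    """0-based indices of the deterministic k-filter subset of n filters.

    ``spaced`` (default): the first three, the last three, and the remaining
    ``k - 6`` interior filters evenly spaced over the interior by rounded
    linear spacing.  ``gap3``: a literal arithmetic interior sequence with a
    gap of three filters (rows 4, 7, 10, ...).
    """
    if k > n:
        raise ValueError(f"cannot select {k} filters from {n}")
    if n == k:
        return np.arange(n)
    if k < 7:
        raise ValueError("selection needs k >= 7 (first three + last three)")
    first = np.arange(3)
    last = np.arange(n - 3, n)
    if mode == "spaced":
        interior = np.round(np.linspace(3, n - 4, k - 6)).astype(int)
    elif mode == "gap3":
        interior = 3 + 3 * np.arange(k - 6)
        if interior[-1] > n - 4:
            raise ValueError(f"gap-of-3 interior sequence exceeds n={n}")
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    idx = np.unique(np.concatenate([first, interior, last]))
    if len(idx) != k:
        raise ValueError(
            f"selection degenerate for n={n}, k={k}: got {len(idx)} indices"
        )
    return idx


def select_filters(bank: FilterBank, k: int = 25, mode: str = "spaced") -> FilterBank:
    """Deterministic k-filter subset of a fitted bank (ascending row order)."""
    idx = selection_indices(bank.n_filters, k, mode)
    rot = bank.rotation[idx] if bank.rotation is not None else None
    return FilterBank(W=bank.W[idx].copy(), p=bank.p, seed=bank.seed,
                      rotation=rot)


def convolve_bank(image: np.ndarray, bank: FilterBank) -> list[np.ndarray]:
    """Convolve each filter with each channel of a color image.

    Returns one image per filter: channel ``c`` of output ``i`` is the 2-D
    convolution (reflect boundary, same-size output) of channel ``c`` with
    filter ``i``, then the whole output image is min-max rescaled to 8-bit.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected H x W x 3 input, got shape {image.shape}")
    outs: list[np.ndarray] = []
    src = image.astype(float)
    for i in range(bank.n_filters):
        kern = bank.filter_image(i)
        resp = np.stack(
            [
                ndi.convolve(src[..., c], kern, mode="reflect")
                for c in range(3)
            ],
            axis=-1,
        )
        lo, hi = resp.min(), resp.max()
        if hi > lo:
            resp = (resp - lo) / (hi - lo) * 255.0
        else:
            resp = np.zeros_like(resp)
        outs.append(resp.round().astype(np.uint8))
    return outs


def select_blocks(
    image: np.ndarray, block: int = 228, count: int = 8
) -> list[np.ndarray]:
    """Cut a fixed grid of ``count`` square blocks evenly spaced over an image.

    The grid is ``r x c`` with ``r * c == count``; the larger grid dimension
    follows the image's longer axis.  Block top-left positions are rounded
    linear spacings from 0 to ``dim - block``.  Raises if the image is smaller
    than the block in either dimension.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < block or w < block:
        raise ValueError(
            f"image {h}x{w} smaller than block size {block}"
        )
    if count < 1:
        raise ValueError("count must be >= 1")
    r = int(np.floor(np.sqrt(count)))
    while count % r:
        r -= 1
    c = count // r
    rows_n, cols_n = (r, c) if w >= h else (c, r)
    row_starts = np.round(np.linspace(0, h - block, rows_n)).astype(int)
    col_starts = np.round(np.linspace(0, w - block, cols_n)).astype(int)
    return [
        image[rs : rs + block, cs : cs + block].copy()
        for rs in row_starts
        for cs in col_starts
    ]
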