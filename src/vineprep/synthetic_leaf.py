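"""Reproducible synthetic vineyard-leaf images.

Field datasets of grapevine canopies (six red varieties, a few tens of images
per variety) are not publicly deposited, so every test and example in this
package runs on synthetic stand-ins generated here: per-class leaf-shaped
foreground regions with distinct vein geometry, drawn over cluttered non-leaf
backgrounds, together with ground-truth masks and class labels.

Each synthetic variety is defined by a lobe count (silhouette = union of
rotated ellipses), a dominant vein orientation, a vein stroke width and a leaf
color.  Backgrounds combine low-frequency color noise with random bright/dark
blobs so that segmentation has real work to do.  Generation is a pure function
of ``(params, dims, seed)``: the same call is bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage.transform import resize

__all__ = [
    "LeafClassParams",
    "SyntheticSample",
    "default_classes",
    "generate_sample",
    "generate_dataset",
    "mean_vein_orientation",
]

MIN_DIM = 64


@dataclass(frozen=True)
class LeafClassParams:
    """Parameters defining one synthetic leaf variety.

    Distinct classes must differ in at least one of ``lobe_count`` /
    ``vein_angle_deg`` so a vein-geometry signal exists for classifiers.
    """

    class_id: int
    lobe_count: int
    vein_angle_deg: float
    vein_width_px: int
    leaf_color: tuple[int, int, int]
    background_texture_scale: int = 24

    def __post_init__(self) -> None:
        if not 0 <= self.class_id <= 5:
            raise ValueError(f"class_id must be in 0..5, got {self.class_id}")
        if self.lobe_count < 1:
            raise ValueError("lobe_count must be >= 1")
        if self.vein_width_px < 1:
            raise ValueError("vein_width_px must be >= 1")


@dataclass(frozen=True)
class SyntheticSample:
    """One generated image with its ground-truth mask and label."""

    image: np.ndarray  # H x W x 3, uint8
    mask: np.ndarray  # H x W, bool; True = leaf
    label: int
    seed: int


def default_classes() -> list[LeafClassParams]:
    """Six synthetic varieties with pairwise-distinct vein geometry.

    Orientations are spread evenly over 0..150 degrees and leaf hues vary
    slightly, emulating six visually similar red-grape varieties.
    """
    specs = [
        (0, 3, 0.0, 2, (60, 130, 45)),
        (1, 5, 30.0, 1, (75, 145, 60)),
        (2, 3, 60.0, 2, (50, 120, 70)),
        (3, 5, 90.0, 2, (85, 135, 40)),
        (4, 7, 120.0, 1, (65, 150, 80)),
        (5, 4, 150.0, 3, (55, 115, 35)),
    ]
    return [
        LeafClassParams(cid, lobes, ang, vw, color)
        for cid, lobes, ang, vw, color in specs
    ]


def _leaf_mask(rng: np.random.Generator, h: int, w: int, lobes: int) -> np.ndarray:
    """Union of ``lobes`` rotated ellipses; radius adjusted so coverage lands
    in the 10-70% band."""
    cy = h / 2 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2 + rng.uniform(-0.05, 0.05) * w
    base = 0.30 * min(h, w) * rng.uniform(0.9, 1.1)
    phase = rng.uniform(0, 2 * np.pi)
    jitter = rng.uniform(-0.2, 0.2, size=lobes)

    def build(r0: float) -> np.ndarray:
        m = np.zeros((h, w), dtype=bool)
        for k in range(lobes):
            ang = phase + 2 * np.pi * k / lobes + jitter[k]
            ecy = cy + 0.45 * r0 * np.sin(ang)
            ecx = cx + 0.45 * r0 * np.cos(ang)
            rr, cc = skdraw.ellipse(
                ecy, ecx, 0.75 * r0, 0.5 * r0, shape=(h, w), rotation=ang
            )
            m[rr, cc] = True
        return m

    r0 = base
    for _ in range(12):
        m = build(r0)
        frac = m.mean()
        if frac < 0.10:
            r0 *= 1.25
        elif frac > 0.70:
            r0 *= 0.85
        else:
            return m
    return m


def _background(
    rng: np.random.Generator, h: int, w: int, texture_scale: int
) -> np.ndarray:
    """Cluttered non-leaf background: low-frequency color field plus random
    bright/dark blobs.  Greens are suppressed so segmentation stays solvable."""
    ts = max(2, texture_scale)
    coarse = rng.uniform(40, 140, size=(max(2, h // ts), max(2, w // ts), 3))
    bg = resize(coarse, (h, w, 3), order=1, mode="reflect", anti_aliasing=False)
    n_blobs = rng.integers(6, 12)
    for _ in range(n_blobs):
        by, bx = rng.uniform(0, h), rng.uniform(0, w)
        br = rng.uniform(0.03, 0.10) * min(h, w)
        rr, cc = skdraw.disk((by, bx), br, shape=(h, w))
        col = rng.uniform(0, 255, size=3)
        bg[rr, cc] = 0.5 * bg[rr, cc] + 0.5 * col
    bg += rng.normal(0, 6.0, size=bg.shape)
    # soil/trellis/sky palette: the green channel never dominates, so the
    # foreground keeps a usable chromatic signature
    bg[..., 1] = np.minimum(bg[..., 1], 0.85 * np.maximum(bg[..., 0],
                                                          bg[..., 2]))
    return bg


def _draw_veins(
    rng: np.random.Generator,
    leaf: np.ndarray,
    mask: np.ndarray,
    angle_deg: float,
    width_px: int,
    color: np.ndarray,
) -> None:
    """Dark parallel strokes at the class orientation, clipped to the leaf."""
    h, w = mask.shape
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    theta = np.deg2rad(angle_deg)
    d = np.array([np.cos(theta), np.sin(theta)])  # (dx, dy)
    nrm = np.array([-np.sin(theta), np.cos(theta)])
    half = 0.75 * min(h, w)
    spacing = max(6, min(h, w) // 10)
    stroke = np.zeros((h, w), dtype=bool)
    for k in range(-4, 5):
        off = k * spacing + rng.uniform(-1.5, 1.5)
        p0 = np.array([cx, cy]) + off * nrm - half * d
        p1 = np.array([cx, cy]) + off * nrm + half * d
        r0, c0 = int(round(p0[1])), int(round(p0[0]))
        r1, c1 = int(round(p1[1])), int(round(p1[0]))
        rr, cc, val = skdraw.line_aa(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        stroke[rr[keep], cc[keep]] |= val[keep] > 0.4
    if width_px > 1:
        stroke = ndi.binary_dilation(stroke, iterations=width_px - 1)
    stroke &= mask
    leaf[stroke] = 0.35 * leaf[stroke] + 0.65 * color[None, :]


def generate_sample(
    params: LeafClassParams, height: int, width: int, seed: int
) -> SyntheticSample:
    """Generate one synthetic leaf image with ground-truth mask.

    Parameters
    ----------
    params
        Class definition (lobes, vein orientation/width, color).
    height, width
        Output dimensions in pixels; both must be >= 64.
    seed
        Integer seed; output is a pure function of all four arguments.
    """
    if height < MIN_DIM or width < MIN_DIM:
        raise ValueError(
            f"image dimensions must be >= {MIN_DIM}, got {height}x{width}"
        )
    rng = np.random.default_rng(
        [int(seed) & 0x7FFFFFFF, params.class_id, height, width]
    )
    mask = _leaf_mask(rng, height, width, params.lobe_count)
    img = _background(rng, height, width, params.background_texture_scale)

    base = np.asarray(params.leaf_color, dtype=float)
    leaf = np.tile(base, (height, width, 1))
    leaf += rng.normal(0, 8.0, size=leaf.shape)
    # gentle radial shading so the leaf is not flat
    yy, xx = np.mgrid[0:height, 0:width]
    ys, xs = np.nonzero(mask)
    rad = np.hypot(yy - ys.mean(), xx - xs.mean())
    leaf -= (18.0 * rad / max(rad.max(), 1.0))[..., None]

    vein_color = 0.3 * base
    _draw_veins(rng, leaf, mask, params.vein_angle_deg, params.vein_width_px,
                vein_color)

    img[mask] = leaf[mask]
    img = np.clip(img, 0, 255).round().astype(np.uint8)
    # foreground must never be exact black: (0,0,0) is the background sentinel
    fg_black = mask & (img == 0).all(axis=-1)
    img[fg_black] = (1, 1, 1)
    return SyntheticSample(image=img, mask=mask, label=params.class_id,
                           seed=int(seed))


def generate_dataset(
    classes: list[LeafClassParams],
    n_per_class: int,
    height: int,
    width: int,
    seed: int,
) -> list[SyntheticSample]:
    """Generate ``len(classes) * n_per_class`` samples, class-major order.

    Per-sample seeds are derived deterministically from ``seed`` so the label
    sequence and every image are reproducible.
    """
    if not classes:
        raise ValueError("classes must be non-empty")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    samples = []
    for params in classes:
        for j in range(n_per_class):
            s = (int(seed) * 9973 + j * 7919 + params.class_id) % (2**31)
            samples.append(generate_sample(params, height, width, s))
    return samples


def mean_vein_orientation(image: np.ndarray, mask: np.ndarray) -> float:
    """Dominant stripe orientation (degrees in [0, 180)) inside the leaf.

    Uses the gradient structure tensor: gradient angles doubled, averaged with
    magnitude weights, halved back.  On synthetic leaves this recovers the
    class vein angle and serves as a trivial one-feature classifier.
    """
    gray = image.astype(float).mean(axis=-1)
    gy = ndi.sobel(gray, axis=0)
    gx = ndi.sobel(gray, axis=1)
    core = ndi.binary_erosion(mask, iterations=3)
    wgt = np.hypot(gx, gy) * core
    ang = np.arctan2(gy, gx)  # gradient direction; stripe is perpendicular
    c = (wgt * np.cos(2 * ang)).sum()
    s = (wgt * np.sin(2 * ang)).sum()
    grad_dir = 0.5 * np.arctan2(s, c)
    stripe = np.rad2deg(grad_dir) + 90.0
    return float(stripe % 180.0)
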