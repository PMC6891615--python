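"""Four-corners-in-one image warping.

A segmented leaf (exact-black background) is compacted toward each of the four
image corners: one pass shifts every row's non-black pixels, order preserved,
to the corner's horizontal side; a second pass does the same per column toward
the corner's vertical side.  The four compacted images are each rotated 180
degrees and tiled into the quadrants of a (2H+1) x (2W+1) canvas around a
one-pixel white cross, so all leaf content abuts the center.  The output is
the largest square centered on the cross whose pixels are all non-black, with
the cross row and column removed (side length is therefore even).

The method is purely pixel-rearranging: no interpolation, no invented values.
Coordinates are 0-based, row-major, origin at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from vineprep.errors import NoForegroundError
from vineprep.segmentation import SegmentedLeafImage

__all__ = [
    "Corner",
    "CornerComposite",
    "compact_to_corner",
    "assemble_composite",
    "extract_center_square",
    "four_corners_in_one",
]

WHITE = np.array([255, 255, 255], dtype=np.uint8)


class Corner(Enum):
    """The four image corners, named by cardinal direction."""

    NW = "NW"
    NE = "NE"
    SE = "SE"
    SW = "SW"


@dataclass(frozen=True)
class CornerComposite:
    """2x2 mosaic of corner-compacted images around a one-pixel white cross."""

    pixels: np.ndarray  # (2H+1) x (2W+1) x 3, uint8
    cross_row: int
    cross_col: int


def _as_pixels(seg: SegmentedLeafImage | np.ndarray) -> np.ndarray:
    px = seg.pixels if isinstance(seg, SegmentedLeafImage) else np.asarray(seg)
    if px.ndim != 3 or px.shape[-1] != 3:
        raise ValueError(f"expected H x W x 3 array, got shape {px.shape}")
    return px


def _compact_rows_left(px: np.ndarray) -> np.ndarray:
    """Shift each row's non-black pixels to column 0, order preserved."""
    out = np.zeros_like(px)
    fg = (px != 0).any(axis=-1)
    for r in range(px.shape[0]):
        vals = px[r, fg[r]]
        out[r, : len(vals)] = vals
    return out


def compact_to_corner(
    seg: SegmentedLeafImage | np.ndarray, corner: Corner
) -> SegmentedLeafImage:
    """Compact all non-black pixels toward ``corner``.

    Pass 1 shifts each row's non-black pixels (order preserved) toward the
    corner's horizontal side; pass 2 shifts each column's non-black pixels
    toward the corner's vertical side.  The multiset of non-black pixel values
    is conserved exactly.
    """
    px = _as_pixels(seg)
    corner = Corner(corner)
    flip_h = corner in (Corner.NE, Corner.SE)  # shift right instead of left
    flip_v = corner in (Corner.SE, Corner.SW)  # shift down instead of up

    work = px[:, ::-1] if flip_h else px
    work = _compact_rows_left(work)
    if flip_h:
        work = work[:, ::-1]
    # vertical pass = horizontal pass on the transpose
    work = work.transpose(1, 0, 2)
    work = work[:, ::-1] if flip_v else work
    work = _compact_rows_left(work)
    if flip_v:
        work = work[:, ::-1]
    work = work.transpose(1, 0, 2)
    return SegmentedLeafImage(pixels=np.ascontiguousarray(work),
                              empty=not (work != 0).any())


def assemble_composite(
    nw: SegmentedLeafImage | np.ndarray,
    ne: SegmentedLeafImage | np.ndarray,
    se: SegmentedLeafImage | np.ndarray,
    sw: SegmentedLeafImage | np.ndarray,
) -> CornerComposite:
    """Tile the four corner-compacted images around a white cross.

    Each input is rotated 180 degrees and placed in the quadrant matching its
    corner (NW-compacted content, rotated, occupies the NW quadrant and abuts
    the cross from the upper left, and so on).  The cross row/column index is
    (H, W), 0-based.
    """
    arrs = [_as_pixels(a) for a in (nw, ne, se, sw)]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"all four inputs must share dimensions, got {shapes}")
    h, w, _ = arrs[0].shape
    canvas = np.zeros((2 * h + 1, 2 * w + 1, 3), dtype=np.uint8)
    canvas[h, :] = WHITE
    canvas[:, w] = WHITE
    rot = [a[::-1, ::-1] for a in arrs]  # 180-degree rotation
    canvas[:h, :w] = rot[0]          # NW
    canvas[:h, w + 1 :] = rot[1]     # NE
    canvas[h + 1 :, w + 1 :] = rot[2]  # SE
    canvas[h + 1 :, :w] = rot[3]     # SW
    return CornerComposite(pixels=canvas, cross_row=h, cross_col=w)


def extract_center_square(comp: CornerComposite) -> np.ndarray:
    """Largest all-non-black square centered on the cross, cross removed.

    Grows the half-side s while the 2s x 2s square centered at the cross point
    (ignoring the cross row/column itself) stays entirely non-black; returns
    that square with the cross row and column deleted, so the output side 2s
    is even.  Raises :class:`NoForegroundError` if any quadrant contributes no
    non-black pixel adjacent to the center.
    """
    px = comp.pixels
    cr, cc = comp.cross_row, comp.cross_col
    h = cr
    w = cc
    fg = (px != 0).any(axis=-1)
    # quadrant views flipped so index [0,0] is the pixel touching the cross
    quads = [
        fg[:cr, :cc][::-1, ::-1],          # NW
        fg[:cr, cc + 1 :][::-1, :],        # NE
        fg[cr + 1 :, cc + 1 :],            # SE
        fg[cr + 1 :, :cc][:, ::-1],        # SW
    ]
    if any(not q.any() for q in quads):
        raise NoForegroundError("a quadrant contains no non-black pixels")
    smax = min(h, w)
    s = 0
    while s < smax and all(q[: s + 1, : s + 1].all() for q in quads):
        s += 1
    if s == 0:
        raise NoForegroundError(
            "no non-black square exists around the cross point"
        )
    block = px[cr - s : cr + s + 1, cc - s : cc + s + 1]
    block = np.delete(block, s, axis=0)
    block = np.delete(block, s, axis=1)
    return np.ascontiguousarray(block)


def four_corners_in_one(seg: SegmentedLeafImage | np.ndarray) -> np.ndarray:
    """Full warping chain: compact to all four corners, assemble, extract.

    Returns a square RGB array, all pixels non-black, containing only colors
    present in the input.  Raises :class:`NoForegroundError` on an all-black
    input.  The output is returned at natural size; any resizing belongs to
    the dataset recipe.
    """
    px = _as_pixels(seg)
    if not (px != 0).any():
        raise NoForegroundError("input contains no non-black pixels")
    compacted = {c: compact_to_corner(px, c) for c in Corner}
    comp = assemble_composite(
        compacted[Corner.NW], compacted[Corner.NE],
        compacted[Corner.SE], compacted[Corner.SW],
    )
    return extract_center_square(comp)
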