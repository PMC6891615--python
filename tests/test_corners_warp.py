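"""Four-corners-in-one warp: hand oracles, brute force, conservation laws."""

import numpy as np
import pytest

import vineprep as vp
from vineprep import Corner
from vineprep.errors import NoForegroundError

from conftest import random_segmented


# ---------------------------------------------------------------- oracles
def compact_oracle(img: np.ndarray, corner: Corner) -> np.ndarray:
    """Literal two-pass compaction: per-row shift then per-column shift."""
    out = img.copy()
    h, w, _ = out.shape
    rev_h = corner in (Corner.NE, Corner.SE)
    rev_v = corner in (Corner.SE, Corner.SW)
    res = np.zeros_like(out)
    for r in range(h):
        vals = [out[r, c] for c in (range(w - 1, -1, -1) if rev_h else range(w))
                if out[r, c].any()]
        for k, v in enumerate(vals):
            res[r, w - 1 - k if rev_h else k] = v
    out, res = res, np.zeros_like(res)
    for c in range(w):
        vals = [out[r, c] for r in (range(h - 1, -1, -1) if rev_v else range(h))
                if out[r, c].any()]
        for k, v in enumerate(vals):
            res[h - 1 - k if rev_v else k, c] = v
    return res


def center_square_oracle(comp: vp.CornerComposite):
    """Exhaustive search over all centered squares."""
    px = comp.pixels
    cr, cc = comp.cross_row, comp.cross_col
    fg = (px != 0).any(axis=-1)
    best = None
    for s in range(1, min(cr, cc) + 1):
        region = np.ones((2 * s, 2 * s), dtype=bool)
        rows = list(range(cr - s, cr)) + list(range(cr + 1, cr + s + 1))
        cols = list(range(cc - s, cc)) + list(range(cc + 1, cc + s + 1))
        if fg[np.ix_(rows, cols)].all() & region.all():
            best = s
    return best


# ------------------------------------------------------------ compaction
def test_hand_executable_two_pass_example():
    img = np.zeros((3, 3, 3), np.uint8)
    img[0, 2] = (10, 10, 10)
    img[2, 1] = (20, 20, 20)
    out = vp.compact_to_corner(img, Corner.NW).pixels
    coords = sorted(map(tuple, np.argwhere((out != 0).any(-1))))
    assert coords == [(0, 0), (1, 0)]


def test_all_black_and_fully_dense_inputs_are_fixed_points():
    black = np.zeros((5, 7, 3), np.uint8)
    assert vp.compact_to_corner(black, Corner.SE).pixels.sum() == 0
    dense = np.arange(5 * 7 * 3, dtype=np.uint8).reshape(5, 7, 3) + 1
    for corner in Corner:
        assert np.array_equal(vp.compact_to_corner(dense, corner).pixels, dense)


@pytest.mark.parametrize("corner", list(Corner))
def test_compaction_matches_brute_force_on_random_images(corner):
    rng = np.random.default_rng(11)
    for _ in range(50):
        h, w = rng.integers(1, 17, size=2)
        img = random_segmented(rng, h, w, density=rng.uniform(0.1, 0.9))
        got = vp.compact_to_corner(img, corner).pixels
        assert np.array_equal(got, compact_oracle(img, corner))


@pytest.mark.parametrize("corner", list(Corner))
def test_compaction_conserves_pixel_color_multiset(corner):
    rng = np.random.default_rng(3)
    for _ in range(20):
        img = random_segmented(rng, 12, 9, density=0.5)
        out = vp.compact_to_corner(img, corner).pixels
        def multiset(a):
            flat = a.reshape(-1, 3)
            flat = flat[(flat != 0).any(axis=1)]
            return sorted(map(tuple, flat))
        assert multiset(img) == multiset(out)


def test_mirror_symmetry_between_corners():
    rng = np.random.default_rng(7)
    for _ in range(20):
        img = random_segmented(rng, 10, 8, density=0.4)
        ne = vp.compact_to_corner(img[:, ::-1], Corner.NE).pixels
        nw = vp.compact_to_corner(img, Corner.NW).pixels
        assert np.array_equal(ne, nw[:, ::-1])
        sw = vp.compact_to_corner(img[::-1, :], Corner.SW).pixels
        assert np.array_equal(sw, nw[::-1, :])


# -------------------------------------------------------------- assembly
def test_composite_structure_and_cross():
    h, w = 4, 6
    black = np.zeros((h, w, 3), np.uint8)
    comp = vp.assemble_composite(black, black, black, black)
    assert comp.pixels.shape == (2 * h + 1, 2 * w + 1, 3)
    assert (comp.pixels[comp.cross_row] == 255).all()
    assert (comp.pixels[:, comp.cross_col] == 255).all()
    off_cross = np.delete(np.delete(comp.pixels, comp.cross_row, 0),
                          comp.cross_col, 1)
    assert off_cross.sum() == 0


def test_rotation_maps_origin_pixel_next_to_cross():
    h, w = 4, 6
    nw = np.zeros((h, w, 3), np.uint8)
    nw[0, 0] = (9, 9, 9)
    black = np.zeros_like(nw)
    comp = vp.assemble_composite(nw, black, black, black)
    assert tuple(comp.pixels[h - 1, w - 1]) == (9, 9, 9)


def test_dimension_mismatch_rejected():
    a = np.zeros((4, 4, 3), np.uint8)
    b = np.zeros((5, 4, 3), np.uint8)
    with pytest.raises(ValueError):
        vp.assemble_composite(a, a, a, b)


# ----------------------------------------------------- square extraction
def test_full_quadrants_give_twice_min_dim():
    h, w = 5, 9
    dense = np.full((h, w, 3), 7, np.uint8)
    comp = vp.assemble_composite(dense, dense, dense, dense)
    sq = vp.extract_center_square(comp)
    assert sq.shape == (2 * min(h, w), 2 * min(h, w), 3)
    assert (sq != 0).any(axis=-1).all()


def test_k_block_quadrants_give_side_2k():
    h, w, k = 6, 8, 3
    img = np.zeros((h, w, 3), np.uint8)
    img[2 : 2 + k, 3 : 3 + k] = 5  # compacts to a k x k block in every corner
    comp = vp.assemble_composite(
        *(vp.compact_to_corner(img, c) for c in
          (Corner.NW, Corner.NE, Corner.SE, Corner.SW))
    )
    sq = vp.extract_center_square(comp)
    assert sq.shape == (2 * k, 2 * k, 3)


def test_extraction_matches_exhaustive_search_on_random_composites():
    rng = np.random.default_rng(19)
    for _ in range(200):
        h, w = rng.integers(2, 17, size=2)
        quads = [random_segmented(rng, h, w, density=rng.uniform(0.3, 1.0))
                 for _ in range(4)]
        comp = vp.assemble_composite(*[vp.compact_to_corner(q, c).pixels
                                       for q, c in zip(quads, Corner)])
        expected = center_square_oracle(comp)
        if expected is None:
            with pytest.raises(NoForegroundError):
                vp.extract_center_square(comp)
        else:
            sq = vp.extract_center_square(comp)
            assert sq.shape[0] == 2 * expected


def test_empty_quadrant_raises():
    dense = np.full((4, 4, 3), 8, np.uint8)
    black = np.zeros_like(dense)
    comp = vp.assemble_composite(dense, dense, dense, black)
    with pytest.raises(NoForegroundError):
        vp.extract_center_square(comp)


# ------------------------------------------------------------ full chain
def test_chain_on_dense_input_and_color_closure():
    rng = np.random.default_rng(23)
    img = random_segmented(rng, 7, 11, density=0.6)
    out = vp.four_corners_in_one(img)
    assert out.shape[0] == out.shape[1]
    assert (out != 0).any(axis=-1).all()
    in_colors = set(map(tuple, img.reshape(-1, 3)))
    out_colors = set(map(tuple, out.reshape(-1, 3)))
    assert out_colors <= in_colors

    dense = np.full((5, 9, 3), 7, np.uint8)
    assert vp.four_corners_in_one(dense).shape == (10, 10, 3)


def test_chain_rejects_all_black():
    with pytest.raises(NoForegroundError):
        vp.four_corners_in_one(np.zeros((8, 8, 3), np.uint8))


def test_adding_foreground_never_shrinks_output():
    rng = np.random.default_rng(29)
    for _ in range(20):
        img = random_segmented(rng, 10, 10, density=0.5)
        if not (img != 0).any():
            continue
        side = vp.four_corners_in_one(img).shape[0]
        more = img.copy()
        bg = np.argwhere((more == 0).all(-1))
        if len(bg):
            take = bg[rng.integers(len(bg), size=max(1, len(bg) // 3))]
            more[take[:, 0], take[:, 1]] = 99
        assert vp.four_corners_in_one(more).shape[0] >= side
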