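"""Declarative assembly of pre-processed, augmented leaf datasets.

Ten numbered recipes bind a pre-processing method to an augmentation spec:

====  =============  =========================  ==================
id    preprocessing  augmentation               originals retained
====  =============  =========================  ==================
#1    none           F900                       no
#2    icf            F4                         no
#3    corners        F900                       no
#4    lpe            F25                        no
#5    lpe+icf        F25                        no
#6    lpe+canny      F25                        no
#7    lpe+gmp        F25                        no
#8    corners        F900                       yes
#9    corners        F900 + mirror              yes
#10   corners        F100 + mirror + rotate     yes
====  =============  =========================  ==================

Counts compose as: translation contributes ``n * F`` crops, the mirror branch
duplicates the translated set, rotation multiplies the translated + mirrored
sets by ten (the originals are never rotated), and recipes #8-#10 retain the
raw originals alongside.  With the full-scale raw counts this arithmetic yields
126,000 / 28,000 -> 112,000 / 91,100 and 147,764 / 295,364 / 360,964 /
54,060 / 108,060 / 132,060 per split.

Splits are taken at the raw-image level *before* augmentation, so no
augmented image can leak across splits: either N test images per class with
the remainder shuffled 80/20 into train/validation, or N test images per
class followed by a fixed per-class validation hold-out (10 + 6 per class,
which maps 224 raw images to a 128/36/60 train/val/test split).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from vineprep.augment import (
    ROTATION_ANGLES,
    AugmentationSpec,
    mirror as mirror_op,
    rotations as rotations_op,
    translate_crops,
)
from vineprep.corners_warp import four_corners_in_one
from vineprep.icf_bank import fit_ica, patchify, select_blocks, select_filters
from vineprep.segmentation import apply_mask, leaf_patch_extract, segment_leaf
from vineprep.vein_extract import canny_vein, gmp_vein

__all__ = [
    "RawImage",
    "DatasetRecipe",
    "SplitSpec",
    "ManifestRecord",
    "Manifest",
    "RECIPES",
    "drgv_split",
    "drgv2018_split",
    "expected_counts",
    "split_collection",
    "build_dataset",
]

N_CLASSES = 6
PREPROCESSINGS = ("none", "icf", "corners", "lpe", "lpe+icf", "lpe+canny",
                  "lpe+gmp")


@dataclass(frozen=True)
class RawImage:
    """A labeled raw image, optionally with a known foreground mask."""

    image: np.ndarray
    label: int
    name: str = ""
    mask: np.ndarray | None = None


@dataclass(frozen=True)
class DatasetRecipe:
    """One pre-processing + augmentation binding.

    ``icf_filters * icf_blocks`` is the per-raw-image multiplicity of the
    whole-image ICF pre-processing; ``icf_patch`` is the ICA patch side.
    """

    id: int
    preprocessing: str
    augmentation: AugmentationSpec
    keep_originals: bool = False
    icf_filters: int = 25
    icf_blocks: int = 8
    icf_patch: int = 12
    icf_block_size: int = 228
    lpe_patch: int = 64

    def __post_init__(self) -> None:
        if self.preprocessing not in PREPROCESSINGS:
            raise ValueError(f"unknown preprocessing {self.preprocessing!r}")

    def scaled(self, **kwargs: Any) -> "DatasetRecipe":
        """Desk-scale variant with some parameters replaced."""
        return dataclasses.replace(self, **kwargs)


def _spec(F: int | None, mirror: bool = False, rotate: bool = False,
          crop: int = 227) -> AugmentationSpec:
    return AugmentationSpec(
        translation_factor=F,
        mirror=mirror,
        rotation_angles=ROTATION_ANGLES if rotate else (),
        crop_size=crop,
    )


RECIPES: dict[int, DatasetRecipe] = {
    1: DatasetRecipe(1, "none", _spec(900)),
    2: DatasetRecipe(2, "icf", _spec(4)),
    3: DatasetRecipe(3, "corners", _spec(900)),
    4: DatasetRecipe(4, "lpe", _spec(25)),
    5: DatasetRecipe(5, "lpe+icf", _spec(25), icf_patch=8),
    6: DatasetRecipe(6, "lpe+canny", _spec(25)),
    7: DatasetRecipe(7, "lpe+gmp", _spec(25)),
    8: DatasetRecipe(8, "corners", _spec(900), keep_originals=True),
    9: DatasetRecipe(9, "corners", _spec(900, mirror=True),
                     keep_originals=True),
    10: DatasetRecipe(10, "corners", _spec(100, mirror=True, rotate=True),
                      keep_originals=True),
}


@dataclass(frozen=True)
class SplitSpec:
    """Raw-level split rule applied per class before augmentation."""

    test_per_class: int
    val_rule: str  # "fraction" or "per_class"
    val_amount: float | int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.val_rule not in ("fraction", "per_class"):
            raise ValueError(f"unknown val_rule {self.val_rule!r}")


def drgv_split(seed: int = 0) -> SplitSpec:
    """Six test images per class; remainder shuffled 80/20 train/validation."""
    return SplitSpec(test_per_class=6, val_rule="fraction", val_amount=0.20,
                     seed=seed)


def drgv2018_split(seed: int = 0) -> SplitSpec:
    """Ten test images per class, then six validation images per class."""
    return SplitSpec(test_per_class=10, val_rule="per_class", val_amount=6,
                     seed=seed)


@dataclass(frozen=True)
class ManifestRecord:
    output_path: str
    source_image: str
    class_label: int
    split: str
    transform_chain: tuple[str, ...]


@dataclass
class Manifest:
    """Full provenance of a built dataset; counts are derived, never stored."""

    recipe_id: int
    records: list[ManifestRecord] = field(default_factory=list)

    def summary(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.records:
            out[rec.split] = out.get(rec.split, 0) + 1
        out["total"] = len(self.records)
        return out

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            {
                "output_path": [r.output_path for r in self.records],
                "source_image": [r.source_image for r in self.records],
                "class_label": [r.class_label for r in self.records],
                "split": [r.split for r in self.records],
                "transform_chain": [json.dumps(list(r.transform_chain))
                                    for r in self.records],
            }
        )
        df.to_csv(path, index=False)


def expected_counts(n: int, recipe: DatasetRecipe) -> dict[str, int]:
    """Closed-form audit of the builder, without materializing any image.

    ``n`` is the number of raw images for whole-image recipes, or the number
    of leaf patches for the patch-based (lpe*) recipes, whose pre-processed
    count is data-dependent.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    aug = recipe.augmentation
    if recipe.preprocessing == "icf":
        pre = n * recipe.icf_filters * recipe.icf_blocks
    else:
        pre = n
    translated = pre * (aug.translation_factor or 1)
    mirrored = translated if aug.mirror else 0
    rotated = (translated + mirrored) * len(aug.rotation_angles)
    originals = n if recipe.keep_originals else 0
    total = originals + translated + mirrored + rotated
    return {
        "preprocessed": pre,
        "originals": originals,
        "translated": translated,
        "mirrored": mirrored,
        "rotated": rotated,
        "total": total,
    }


def _by_class(images: Sequence[RawImage]) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for i, im in enumerate(images):
        if not 0 <= im.label < N_CLASSES:
            raise ValueError(f"unknown class label {im.label}")
        groups.setdefault(im.label, []).append(i)
    return groups


def split_collection(
    images: Sequence[RawImage], split: SplitSpec
) -> tuple[list[RawImage], list[RawImage], list[RawImage]]:
    """Partition raw images into (train, val, test) sets, per class.

    Deterministic under ``split.seed``; the three sets are pairwise disjoint
    and their union is the input collection.
    """
    groups = _by_class(images)
    rng = np.random.default_rng(split.seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(groups):
        idx = np.array(groups[label])
        need = split.test_per_class + (
            split.val_amount if split.val_rule == "per_class" else 1
        )
        if len(idx) <= split.test_per_class or len(idx) < need:
            raise ValueError(
                f"class {label} has only {len(idx)} images; too few for the "
                f"split rule"
            )
        perm = rng.permutation(len(idx))
        idx = idx[perm]
        t = split.test_per_class
        test_idx.extend(idx[:t])
        rest = idx[t:]
        if split.val_rule == "per_class":
            v = int(split.val_amount)
        else:
            v = int(round(float(split.val_amount) * len(rest)))
        val_idx.extend(rest[:v])
        train_idx.extend(rest[v:])
    return (
        [images[i] for i in sorted(train_idx)],
        [images[i] for i in sorted(val_idx)],
        [images[i] for i in sorted(test_idx)],
    )


def _segmented(im: RawImage):
    if im.mask is not None:
        return apply_mask(im.image, im.mask)
    return segment_leaf(im.image)


def _fit_recipe_bank(images: Sequence[RawImage], recipe: DatasetRecipe,
                     patch_source: str):
    """Fit the recipe's ICF bank over the collection's patch matrices."""
    cols = []
    p = recipe.icf_patch
    for im in images:
        if patch_source == "raw":
            gray = im.image.astype(float).mean(axis=-1)
            cols.append(patchify(gray, p).X)
        else:  # leaf patches
            seg = _segmented(im)
            for lp in leaf_patch_extract(seg, recipe.lpe_patch):
                # intensity surrogate: the V channel of HSV is max(R,G,B)
                gray = lp.max(axis=-1).astype(float)
                cols.append(patchify(gray, p).X)
    if not cols:
        raise ValueError("no patches available to fit the ICF bank")
    X = np.concatenate(cols, axis=1)
    from vineprep.icf_bank import PatchMatrix

    pm = PatchMatrix(X=X, p=p, source_dims=(p, p))
    bank = fit_ica(pm, seed=0)
    return select_filters(bank, min(recipe.icf_filters, bank.n_filters))


def _preprocess(im: RawImage, recipe: DatasetRecipe, bank) -> list[tuple[np.ndarray | None, str]]:
    """Apply the recipe's pre-processing; returns (image-or-None, tag) pairs.

    Images are None when the caller only needs counts and the multiplicity is
    data-independent (handled by the caller); here every returned entry is a
    real image.
    """
    kind = recipe.preprocessing
    if kind == "none":
        return [(im.image, "raw")]
    if kind == "corners":
        return [(four_corners_in_one(_segmented(im)), "corners")]
    if kind == "icf":
        outs = []
        for fi, conv in enumerate(_convolved(im.image, bank)):
            for bi, block in enumerate(
                select_blocks(conv, recipe.icf_block_size, recipe.icf_blocks)
            ):
                outs.append((block, f"icf[{fi}]block[{bi}]"))
        return outs
    # patch-based recipes
    seg = _segmented(im)
    patches = leaf_patch_extract(seg, recipe.lpe_patch)
    outs = []
    for pi, lp in enumerate(patches):
        if kind == "lpe":
            outs.append((lp, f"lpe[{pi}]"))
        elif kind == "lpe+icf":
            from vineprep.icf_bank import convolve_bank, FilterBank

            first = FilterBank(W=bank.W[:1], p=bank.p, seed=bank.seed)
            outs.append((convolve_bank(lp, first)[0], f"lpe[{pi}]+icf"))
        elif kind == "lpe+canny":
            outs.append((canny_vein(lp), f"lpe[{pi}]+canny"))
        elif kind == "lpe+gmp":
            gray = lp.astype(float).mean(axis=-1)
            g = gmp_vein(gray.astype(np.uint8))
            outs.append((np.repeat(g[..., None], 3, axis=-1),
                         f"lpe[{pi}]+gmp"))
    return outs


def _convolved(image: np.ndarray, bank) -> list[np.ndarray]:
    from vineprep.icf_bank import convolve_bank

    return convolve_bank(image, bank)


def _augment_records(
    rec_base: dict[str, Any],
    pre_tag: str,
    aug: AugmentationSpec,
    image: np.ndarray | None,
    writer,
) -> list[ManifestRecord]:
    """Enumerate (and optionally materialize) the augmentation fan-out of one
    pre-processed image."""
    s = int(np.sqrt(aug.translation_factor or 1))
    records = []

    def emit(chain: tuple[str, ...], img: np.ndarray | None):
        path = writer(img, chain) if writer else ""
        records.append(ManifestRecord(output_path=path,
                                      transform_chain=chain, **rec_base))

    crops = None
    if image is not None:
        crops = translate_crops(image, aug.translation_factor or 1,
                                aug.crop_size)
    base_chain = (pre_tag,)
    translated_chains = []
    for i in range(s):
        for j in range(s):
            chain = base_chain + (f"crop({i},{j})",)
            img = crops[i * s + j] if crops is not None else None
            translated_chains.append((chain, img))
            emit(chain, img)
    mirrored_chains = []
    if aug.mirror:
        for chain, img in translated_chains:
            mchain = chain + ("mirror",)
            mimg = mirror_op(img) if img is not None else None
            mirrored_chains.append((mchain, mimg))
            emit(mchain, mimg)
    if aug.rotation_angles:
        for chain, img in translated_chains + mirrored_chains:
            if img is not None:
                rots = rotations_op(img, aug.rotation_angles)
            for k, ang in enumerate(aug.rotation_angles):
                rimg = rots[k] if img is not None else None
                emit(chain + (f"rotate({ang})",), rimg)
    return records


def build_dataset(
    images: Sequence[RawImage],
    recipe: DatasetRecipe,
    split: SplitSpec | None = None,
    out_dir: str | Path | None = None,
) -> Manifest:
    """Apply a recipe's pre-processing and augmentation split by split.

    Test and validation raw images are removed before augmentation, so no
    augmented image in one split derives from a raw image of another.  With
    ``out_dir`` set, every output image is written as PNG and the manifest
    records its path; otherwise only the manifest is produced (pre-processing
    still runs where the output count is data-dependent).

    ``expected_counts`` audits the record count in closed form.
    """
    images = list(images)
    if not images:
        raise ValueError("empty image collection")
    _by_class(images)  # label validation
    if split is not None:
        train, val, test = split_collection(images, split)
        parts = [("train", train), ("val", val), ("test", test)]
    else:
        parts = [("train", images)]

    materialize = out_dir is not None
    lpe_based = recipe.preprocessing.startswith("lpe")
    bank = None
    if materialize and "icf" in recipe.preprocessing:
        bank = _fit_recipe_bank(
            images, recipe,
            "raw" if recipe.preprocessing == "icf" else "patches",
        )

    out_path = Path(out_dir) if out_dir is not None else None
    counter = [0]

    def writer(img: np.ndarray | None, chain: tuple[str, ...]) -> str:
        if not materialize or img is None:
            return ""
        from PIL import Image

        fname = f"img_{counter[0]:07d}.png"
        counter[0] += 1
        Image.fromarray(img).save(out_path / fname)
        return fname

    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    manifest = Manifest(recipe_id=recipe.id)
    for split_name, members in parts:
        for idx, im in enumerate(members):
            name = im.name or f"raw_{split_name}_{idx}"
            rec_base = dict(source_image=name, class_label=im.label,
                            split=split_name)
            if materialize:
                pre = _preprocess(im, recipe, bank)
            elif lpe_based:
                # multiplicity is data-dependent: count real leaf patches
                n_patches = len(
                    leaf_patch_extract(_segmented(im), recipe.lpe_patch)
                )
                suffix = recipe.preprocessing.removeprefix("lpe")
                pre = [(None, f"lpe[{pi}]{suffix}") for pi in range(n_patches)]
            elif recipe.preprocessing == "icf":
                pre = [
                    (None, f"icf[{fi}]block[{bi}]")
                    for fi in range(recipe.icf_filters)
                    for bi in range(recipe.icf_blocks)
                ]
            else:
                tag = ("corners" if recipe.preprocessing == "corners"
                       else "raw")
                pre = [(None, tag)]
            if recipe.keep_originals:
                path = writer(im.image if materialize else None,
                              ("original",))
                manifest.records.append(
                    ManifestRecord(output_path=path, transform_chain=("original",),
                                   **rec_base)
                )
            for img, tag in pre:
                manifest.records.extend(
                    _augment_records(rec_base, tag, recipe.augmentation,
                                     img if materialize else None, writer)
                )
    return manifest
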