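"""Recipe counts, split integrity, and builder/audit oracle equivalence."""

import numpy as np
import pytest

import vineprep as vp
from vineprep import (RECIPES, RawImage, build_dataset, drgv2018_split,
                      drgv_split, expected_counts, split_collection)
from vineprep.augment import AugmentationSpec


# ------------------------------------------------------- printed totals
def test_expected_counts_reproduce_full_scale_totals():
    assert expected_counts(140, RECIPES[1])["total"] == 126_000
    r2 = expected_counts(140, RECIPES[2])
    assert r2["preprocessed"] == 28_000 and r2["total"] == 112_000
    assert expected_counts(140, RECIPES[3])["total"] == 126_000
    for rid in (4, 5, 6, 7):
        assert expected_counts(3644, RECIPES[rid])["total"] == 91_100
    assert expected_counts(164, RECIPES[8])["total"] == 147_764
    assert expected_counts(164, RECIPES[9])["total"] == 295_364
    r10 = expected_counts(164, RECIPES[10])
    assert r10["rotated"] == 328_000 and r10["total"] == 360_964
    assert expected_counts(60, RECIPES[8])["total"] == 54_060
    assert expected_counts(60, RECIPES[9])["total"] == 108_060
    assert expected_counts(60, RECIPES[10])["total"] == 132_060
    # dataset-level grand totals: train/val on 164 raws + test on 60
    for rid, total in ((8, 201_824), (9, 403_424), (10, 493_024)):
        assert (expected_counts(164, RECIPES[rid])["total"]
                + expected_counts(60, RECIPES[rid])["total"]) == total


def test_expected_counts_degenerate_cases():
    assert expected_counts(0, RECIPES[9])["total"] == 0
    with pytest.raises(ValueError):
        expected_counts(-1, RECIPES[1])


# ---------------------------------------------------------------- splits
def _flat_collection(counts):
    classes = vp.default_classes()
    return [
        RawImage(image=np.full((64, 64, 3), 10, np.uint8),
                 label=c.class_id, name=f"{c.class_id}_{k}")
        for c, n in zip(classes, counts) for k in range(n)
    ]


def test_drgv2018_rule_yields_128_36_60():
    images = _flat_collection([38, 38, 38, 38, 36, 36])
    assert len(images) == 224
    tr, va, te = split_collection(images, drgv2018_split(seed=3))
    assert (len(tr), len(va), len(te)) == (128, 36, 60)


def test_split_is_seeded_partition():
    images = _flat_collection([20, 20, 20, 20, 20, 20])
    split = drgv_split(seed=9)
    a = split_collection(images, split)
    b = split_collection(images, split)
    for x, y in zip(a, b):
        assert [im.name for im in x] == [im.name for im in y]
    names = [im.name for part in a for im in part]
    assert sorted(names) == sorted(im.name for im in images)
    assert len(set(names)) == len(names)  # pairwise disjoint


def test_split_rejects_too_small_class():
    images = _flat_collection([8, 20, 20, 20, 20, 20])
    with pytest.raises(ValueError):
        split_collection(images, drgv2018_split(seed=0))


def test_unknown_label_rejected():
    bad = [RawImage(image=np.zeros((64, 64, 3), np.uint8), label=7)]
    with pytest.raises(ValueError):
        split_collection(bad, drgv_split())
    with pytest.raises(ValueError):
        build_dataset(bad, RECIPES[1])


# ------------------------------------------- builder vs closed-form audit
@pytest.mark.parametrize("rid", [1, 3, 8, 9, 10])
def test_builder_matches_audit_whole_image_recipes(rid, small_collection):
    for n in (6, 12):
        manifest = build_dataset(small_collection[:n], RECIPES[rid])
        assert len(manifest.records) == expected_counts(n, RECIPES[rid])["total"]


def test_builder_matches_audit_icf_recipe(small_collection):
    manifest = build_dataset(small_collection[:6], RECIPES[2])
    assert len(manifest.records) == expected_counts(6, RECIPES[2])["total"]


def test_builder_matches_audit_patch_recipes(small_collection, small_samples):
    recipe = RECIPES[4].scaled(lpe_patch=16)
    manifest = build_dataset(small_collection, recipe)
    n_patches = sum(
        len(vp.leaf_patch_extract(vp.apply_mask(s.image, s.mask), 16))
        for s in small_samples
    )
    assert n_patches > 0
    assert len(manifest.records) == expected_counts(n_patches, recipe)["total"]


# ------------------------------------------------- no-leakage + manifest
def test_no_augmented_image_crosses_splits(small_collection):
    classes = vp.default_classes()
    samples = vp.generate_dataset(classes, 4, 96, 96, seed=11)
    images = [RawImage(image=s.image, label=s.label, name=f"r{i}", mask=s.mask)
              for i, s in enumerate(samples)]
    split = vp.SplitSpec(test_per_class=1, val_rule="per_class", val_amount=1,
                         seed=2)
    manifest = build_dataset(images, RECIPES[9].scaled(
        augmentation=AugmentationSpec(translation_factor=4, mirror=True,
                                      crop_size=32)), split=split)
    source_split: dict[str, str] = {}
    for rec in manifest.records:
        prev = source_split.setdefault(rec.source_image, rec.split)
        assert prev == rec.split  # a raw image feeds exactly one split
    assert set(r.split for r in manifest.records) == {"train", "val", "test"}


def test_materialized_run_writes_every_record(tmp_path, small_collection):
    recipe = RECIPES[9].scaled(
        augmentation=AugmentationSpec(translation_factor=25, mirror=True,
                                      crop_size=32))
    manifest = build_dataset(small_collection, recipe, out_dir=tmp_path)
    expected = expected_counts(len(small_collection), recipe)["total"]
    assert len(manifest.records) == expected
    pngs = {p.name for p in tmp_path.glob("*.png")}
    assert pngs == {r.output_path for r in manifest.records}
    manifest.to_csv(tmp_path / "manifest.csv")
    import pandas as pd

    df = pd.read_csv(tmp_path / "manifest.csv")
    assert len(df) == expected
    assert set(df.columns) >= {"output_path", "source_image", "class_label",
                               "split", "transform_chain"}
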