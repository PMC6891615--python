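"""Dataset recipes: closed-form audits and a materialized small build.

Prints the expected counts of the numbered recipes at the full-scale raw-image
counts (the translation factor multiplies, the mirror branch duplicates, the
rotation branch multiplies the augmented sets by ten), then materializes one
scaled-down recipe and verifies the builder agrees with the audit.
"""

import tempfile
from pathlib import Path

import vineprep as vp
from vineprep import RECIPES, RawImage, build_dataset, expected_counts
from vineprep.augment import AugmentationSpec

print("recipe  n_raw  preprocessed  total")
for rid, n in [(1, 140), (2, 140), (3, 140), (8, 164), (9, 164), (10, 164)]:
    c = expected_counts(n, RECIPES[rid])
    print(f"  #{rid:<4} {n:>6} {c['preprocessed']:>12,} {c['total']:>10,}")
print("patch-based recipes at 3,644 patches:",
      f"{expected_counts(3644, RECIPES[4])['total']:,}")

# materialize a desk-scale variant of recipe #9 (corners warp + F25 + mirror)
classes = vp.default_classes()
samples = vp.generate_dataset(classes, 2, 96, 96, seed=5)
raw = [RawImage(image=s.image, label=s.label, name=f"s{i}", mask=s.mask)
       for i, s in enumerate(samples)]
recipe = RECIPES[9].scaled(
    augmentation=AugmentationSpec(translation_factor=25, mirror=True,
                                  crop_size=32))
with tempfile.TemporaryDirectory() as td:
    manifest = build_dataset(raw, recipe, out_dir=td)
    n_png = len(list(Path(td).glob("*.png")))
    print(f"\nmaterialized recipe #9 (scaled): {len(manifest.records)} "
          f"records, {n_png} PNGs written")
    print("audit agrees:",
          len(manifest.records) == expected_counts(12, recipe)["total"])
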