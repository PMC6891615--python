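"""Learn an independent-component filter bank from image patches.

Cuts a synthetic leaf image into non-overlapping patches, fits fixed-point
FastICA, selects the deterministic 25-filter subset (first three, last three,
evenly spaced interior), and convolves the bank with the image.
"""

import numpy as np

import vineprep as vp

s = vp.generate_sample(vp.default_classes()[1], 128, 128, seed=9)
gray = s.image.astype(float).mean(axis=-1)

pm = vp.patchify(gray, p=4)
print(f"patch matrix: {pm.X.shape[0]} rows x {pm.X.shape[1]} patches "
      "(rows = vectorized 4x4 patches)")

bank = vp.fit_ica(pm, seed=0)
print(f"fitted {bank.n_filters} unit-norm filters "
      f"(norms: {np.linalg.norm(bank.W, axis=1).round(3)[:4]} ...)")

sub = vp.select_filters(bank, k=bank.n_filters)  # identity when n == k
outs = vp.convolve_bank(s.image, vp.select_filters(bank, 7))
print(f"selected 7 filters -> {len(outs)} convolved images, "
      f"each {outs[0].shape}, 8-bit rescaled")

blocks = vp.select_blocks(np.zeros((636, 960, 3), np.uint8),
                          block=228, count=8)
print(f"block grid on a full-size convolution output: {len(blocks)} blocks "
      f"of {blocks[0].shape[0]} x {blocks[0].shape[1]}")
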