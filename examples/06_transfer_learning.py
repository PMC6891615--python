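"""Desk-scale transfer learning on warped synthetic leaves.

Verifies the reference backbone's printed dimensions, then trains a reduced
backbone with the freeze-first-two-convs scheme on four-corners-warped
synthetic data, and runs the frozen-features + linear-SVM branch.  Printed
accuracies are on a held-out test set (chance = 16.7% for six classes).
"""

import numpy as np
from skimage.transform import resize

import vineprep as vp
from vineprep.tl_harness import (SVMConfig, TLScheme, TrainConfig,
                                 alexnet_layers, apply_scheme, build_backbone,
                                 evaluate, propagate_dims,
                                 small_backbone_layers, svm_classify, train)

dims = propagate_dims(alexnet_layers(), (227, 227, 3))
print(f"reference backbone verified: {len(dims)} rows, conv1 -> {dims[1]}, "
      f"pool5 -> {dims[15]} (fc6 input {np.prod(dims[15])})")

X, y = [], []
for params in vp.default_classes():
    for k in range(20):
        s = vp.generate_sample(params, 96, 96, seed=1000 + k)
        warp = vp.four_corners_in_one(vp.apply_mask(s.image, s.mask))
        X.append(resize(warp.astype(float), (32, 32, 3), order=1,
                        anti_aliasing=True, preserve_range=True) / 255.0)
        y.append(s.label)
X = np.asarray(X, np.float32)
X -= X.mean()
y = np.asarray(y)
tr = np.concatenate([np.where(y == c)[0][:15] for c in range(6)])
te = np.concatenate([np.where(y == c)[0][15:] for c in range(6)])
Xtr = np.concatenate([X[tr], X[tr][:, :, ::-1]])  # mirror augmentation
ytr = np.concatenate([y[tr], y[tr]])

net = build_backbone(small_backbone_layers(32, 6, width=8), 6, seed=0)
net = apply_scheme(net, TLScheme.LAST3_CONV)
cfg = TrainConfig(learning_rate=0.02, weight_decay=1e-4, max_epochs=30,
                  batch_size=32, patience=10, seed=0)
res = train(net, (Xtr, ytr), (X[te], y[te]), cfg)
ev = evaluate(net, X[te], y[te])
print(f"LAST3_CONV: {len(res.history['epoch'])} epochs, "
      f"test accuracy {ev.accuracy:.1%} (chance 16.7%)")

feats = net.activations(X, "fc6")
svm = svm_classify(feats, y, SVMConfig(folds=5, C_grid=(0.01, 0.1, 1.0)))
print(f"FE_SVM on fc6 features: CV accuracy {svm.mean_accuracy:.1%} "
      f"at C = {svm.best_C}")
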