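"""Backbone geometry, freezing semantics, training loop, SVM branch."""

import numpy as np
import pytest

import vineprep as vp
from vineprep.errors import NetworkStructureError
from vineprep.tl_harness import (EarlyStopper, FeatureExtractor, SVMConfig,
                                 TLScheme, TrainConfig, alexnet_layers,
                                 apply_scheme, build_backbone, evaluate,
                                 propagate_dims, small_backbone_layers,
                                 svm_classify, train)


# ----------------------------------------------------- dimension algebra
def test_reference_table_dims_reproduced_row_by_row():
    layers = alexnet_layers()
    dims = propagate_dims(layers, (227, 227, 3))
    assert len(dims) == 25
    for spec, got in zip(layers, dims):
        assert spec.out_dims == got, spec.name
    # spot checks on the canonical rows
    by_name = dict(zip([l.name for l in layers], dims))
    assert by_name["conv1"] == (55, 55, 96)
    assert by_name["pool1"] == (27, 27, 96)
    assert by_name["pool5"] == (6, 6, 256)
    assert layers[16].fc_in == 9216 == 6 * 6 * 256


def test_dimension_mismatch_names_the_layer():
    import dataclasses

    layers = alexnet_layers()
    layers[4] = dataclasses.replace(layers[4], out_dims=(28, 28, 96))
    with pytest.raises(NetworkStructureError, match="pool1"):
        propagate_dims(layers, (227, 227, 3))


# ------------------------------------------------------------- backbone
def test_head_resized_and_seed_deterministic():
    specs = small_backbone_layers(16, 6, width=4)
    net = build_backbone(specs, n_classes=6, seed=0)
    fc8 = [l for l in net.layers if l.name == "fc8"][0]
    assert fc8.W.shape[1] == 6
    other = build_backbone(specs, n_classes=6, seed=0)
    for k, w in net.get_weights().items():
        assert np.array_equal(w, other.get_weights()[k])
    different = build_backbone(specs, n_classes=6, seed=1)
    assert not np.array_equal(fc8.W, [l for l in different.layers
                                      if l.name == "fc8"][0].W)


def test_backward_gradients_match_finite_differences():
    rng = np.random.default_rng(0)
    net = build_backbone(small_backbone_layers(16, 3, width=4), 3, seed=0)
    X = rng.standard_normal((4, 16, 16, 3)).astype(np.float32)
    y = np.array([0, 1, 2, 0])
    net.loss_and_grads(X, y, train=True)
    eps = 1e-3
    for layer in net.trainable_layers():
        W = layer.W
        idx = tuple(rng.integers(s) for s in W.shape)
        analytic = layer.dW[idx]
        saved = W[idx]
        W[idx] = saved + eps
        l1, _ = net.loss_and_grads(X, y, train=False)
        W[idx] = saved - eps
        l2, _ = net.loss_and_grads(X, y, train=False)
        W[idx] = saved
        assert abs(analytic - (l1 - l2) / (2 * eps)) < 1e-3, layer.name


# -------------------------------------------------------------- schemes
@pytest.fixture()
def tiny_batch():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((12, 16, 16, 3)).astype(np.float32)
    y = np.tile(np.arange(3), 4)
    return X, y


def _one_step(net, batch, lr=0.05):
    X, y = batch
    cfg = TrainConfig(learning_rate=lr, weight_decay=1e-4, max_epochs=1,
                      batch_size=len(X), seed=0)
    train(net, (X, y), (X, y), cfg)


def test_last3_scheme_freezes_first_two_convs(tiny_batch):
    net = build_backbone(small_backbone_layers(16, 3, width=4), 3, seed=0)
    net = apply_scheme(net, TLScheme.LAST3_CONV)
    before = net.get_weights()
    _one_step(net, tiny_batch)
    after = net.get_weights()
    for name in ("conv1", "conv2"):
        assert np.array_equal(before[f"{name}.W"], after[f"{name}.W"])
        assert np.array_equal(before[f"{name}.b"], after[f"{name}.b"])
    assert not np.array_equal(before["conv3.W"], after["conv3.W"])
    assert not np.array_equal(before["fc8.W"], after["fc8.W"])


def test_fe_classifier_updates_every_tensor(tiny_batch):
    net = build_backbone(small_backbone_layers(16, 3, width=4), 3, seed=0)
    net = apply_scheme(net, TLScheme.FE_CLASSIFIER)
    before = net.get_weights()
    _one_step(net, tiny_batch)
    after = net.get_weights()
    for key in before:
        if key.endswith(".W"):
            assert not np.array_equal(before[key], after[key]), key


def test_fe_svm_freezes_and_extracts_4096_features():
    net = build_backbone(alexnet_layers(), n_classes=6, seed=0)
    fx = apply_scheme(net, TLScheme.FE_SVM)
    assert isinstance(fx, FeatureExtractor)
    x = np.zeros((1, 227, 227, 3), np.float32)
    assert fx(x).shape == (1, 4096)
    assert all(l.lr_mult == 0.0 for l in net.layers)


def test_unknown_scheme_rejected(tiny_batch):
    net = build_backbone(small_backbone_layers(16, 3, width=4), 3, seed=0)
    with pytest.raises(ValueError):
        apply_scheme(net, "warmstart")


# ------------------------------------------------------------- training
def test_early_stopper_counts_validations_beyond_best():
    stopper = EarlyStopper(patience=10)
    losses = [1.0 + 0.1 * k for k in range(30)]  # strictly increasing
    stops = [stopper.update(l) for l in losses]
    assert stops.index(True) == 10  # 10 validations beyond the best (first)


def test_training_checkpoints_match_epochs_and_early_stop(tiny_batch):
    X, y = tiny_batch
    net = build_backbone(small_backbone_layers(16, 3, width=4), 3, seed=0)
    # huge lr diverges -> validation loss keeps growing -> early stop
    cfg = TrainConfig(learning_rate=50.0, weight_decay=0.0, max_epochs=40,
                      batch_size=6, patience=3, seed=0)
    res = train(net, (X, y), (X, y), cfg)
    assert len(res.checkpoints) == len(res.history["epoch"])
    assert len(res.checkpoints) < 40 and res.stopped_early


def test_overfit_capacity_on_synthetic_crops(leaf_classes):
    """A small backbone memorizes a 6-class synthetic crop set quickly."""
    from skimage.transform import resize

    rng = np.random.default_rng(0)
    X, y = [], []
    for params in leaf_classes:
        for k in range(6):
            s = vp.generate_sample(params, 96, 96, seed=300 + k)
            seg = vp.apply_mask(s.image, s.mask)
            warp = vp.four_corners_in_one(seg)
            small = resize(warp.astype(float), (32, 32, 3), order=1,
                           preserve_range=True, anti_aliasing=True) / 255.0
            X.append(small)
            X.append(small[:, ::-1])
            y += [s.label, s.label]
    X = np.asarray(X, np.float32) - 0.5
    y = np.asarray(y)
    net = build_backbone(small_backbone_layers(32, 6, width=8), 6, seed=0)
    cfg = TrainConfig(learning_rate=0.02, weight_decay=1e-4, max_epochs=30,
                      batch_size=24, patience=30, seed=0)
    res = train(net, (X, y), (X, y), cfg)
    assert max(res.history["train_acc"]) >= 0.95


def test_empty_dataset_rejected(tiny_batch):
    X, y = tiny_batch
    net = build_backbone(small_backbone_layers(16, 3, width=4), 3, seed=0)
    cfg = TrainConfig(max_epochs=1)
    with pytest.raises(ValueError):
        train(net, (X[:0], y[:0]), (X, y), cfg)


# ------------------------------------------------------------ SVM branch
def test_separable_vectors_reach_full_cv_accuracy():
    rng = np.random.default_rng(0)
    F = np.vstack([rng.normal(0, 0.1, (30, 4)),
                   rng.normal(5, 0.1, (30, 4))])
    y = np.repeat([0, 1], 30)
    res = vp.tl_harness.svm_classify(F, y, SVMConfig(folds=10))
    assert res.mean_accuracy == 1.0
    assert len(res.fold_accuracies) == 10


def test_shuffled_labels_score_near_chance():
    rng = np.random.default_rng(1)
    F = rng.normal(size=(240, 8))
    y = np.tile(np.arange(6), 40)
    res = svm_classify(F, rng.permutation(y), SVMConfig(folds=10))
    assert abs(res.mean_accuracy - 1 / 6) < 0.05


def test_single_c_grid_is_selected_and_small_class_rejected():
    rng = np.random.default_rng(2)
    F = rng.normal(size=(40, 3))
    y = np.tile([0, 1], 20)
    res = svm_classify(F, y, SVMConfig(folds=5, C_grid=(0.3,)))
    assert res.best_C == 0.3
    with pytest.raises(ValueError):
        svm_classify(F[:6], y[:6], SVMConfig(folds=5))


# ------------------------------------------------------------ evaluation
class _Const:
    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.full(len(X), self.label)


class _Perfect:
    def __init__(self, y):
        self.y = y

    def predict(self, X):
        return self.y


def test_confusion_matrix_shapes_and_normalization():
    y = np.tile(np.arange(6), 10)
    X = np.zeros((60, 1))
    perfect = evaluate(_Perfect(y), X, y)
    assert perfect.accuracy == 1.0
    assert np.allclose(perfect.confusion_percent, np.eye(6) * 100)
    const = evaluate(_Const(3), X, y)
    assert np.allclose(const.confusion_percent[:, 3], 100)
    assert np.allclose(const.confusion_percent.sum(axis=1), 100, atol=0.5)


def test_majority_vote_groups():
    y = np.array([0, 0, 0, 1, 1, 1])
    groups = np.array([0, 0, 0, 1, 1, 1])

    class Flaky:
        def predict(self, X):
            return np.array([0, 0, 1, 1, 1, 0])  # 2/3 right per group

    res = evaluate(Flaky(), np.zeros((6, 1)), y, groups=groups)
    assert res.group_accuracy == 1.0
    assert res.accuracy == pytest.approx(4 / 6)


def test_empty_test_set_rejected():
    with pytest.raises(ValueError):
        evaluate(_Const(0), np.zeros((0, 1)), np.zeros(0, int))
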