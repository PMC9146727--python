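"""Desk-scale training and deep-feature extraction."""

import numpy as np
import pytest

from histofuse import (
    SixBranchNet,
    build_6bnet,
    extract_6bnet_features,
    extract_reference_features,
    make_synthetic_histology,
)
from histofuse.layers import cross_entropy
from histofuse.network import (
    backward,
    forward,
    init_network,
    load_network,
    resize_batch,
    save_network,
    train_backbone,
)


@pytest.fixture(scope="module")
def tiny_net():
    g = build_6bnet(2, input_side=48, width_scale=0.125)
    return g, init_network(g, seed=0)


class TestTraining:
    def test_zero_epochs_keeps_initial_weights(self, small_images):
        g = build_6bnet(2, input_side=48, width_scale=0.125)
        x = resize_batch(small_images.images, 48)
        params, trace = train_backbone(g, x, small_images.labels, epochs=0, seed=3)
        ref = init_network(g, seed=3)
        assert trace == []
        assert np.array_equal(params["conv1"]["w"], ref["conv1"]["w"])

    def test_loss_decreases_on_two_class_set(self):
        imgs = make_synthetic_histology(n_per_class=40, K=2, side=48, seed=6)
        g = build_6bnet(2, input_side=48, width_scale=0.25)
        x = resize_batch(imgs.images, 48)
        _, trace = train_backbone(g, x, imgs.labels, epochs=5, lr=0.02,
                                  batch_size=16, seed=0)
        assert len(trace) == 5
        assert trace[-1] < trace[0]

    def test_same_seed_gives_identical_traces(self, small_images):
        g = build_6bnet(2, input_side=48, width_scale=0.125)
        x = resize_batch(small_images.images, 48)
        _, t1 = train_backbone(g, x, small_images.labels, epochs=2, seed=4)
        _, t2 = train_backbone(g, x, small_images.labels, epochs=2, seed=4)
        assert t1 == t2

    def test_empty_data_rejected(self, tiny_net):
        g, _ = tiny_net
        with pytest.raises(ValueError):
            train_backbone(g, np.empty((0, 48, 48, 3)), np.empty(0, int), epochs=1)

    def test_gradients_match_finite_differences(self, tiny_net):
        # numeric check of the whole backward pass through conv/pool/bn/fc
        g, params = tiny_net
        rng = np.random.default_rng(0)
        x = rng.random((4, 48, 48, 3)).astype(np.float32) - 0.5
        y = np.array([0, 1, 0, 1])

        def loss_at(params):
            logits, _, _ = forward(g, params, x, mode="infer", upto="fc2")
            return cross_entropy(logits, y)[0]

        logits, acts, caches = forward(g, params, x, mode="infer", upto="fc2")
        _, dlog = cross_entropy(logits, y)
        grads = backward(g, params, acts, caches, dlog, "fc2")
        w = params["fc2"]["w"]
        for idx in [(0, 0), (5, 1), (100, 0)]:
            eps = 1e-3
            orig = w[idx]
            w[idx] = orig + eps
            up = loss_at(params)
            w[idx] = orig - eps
            dn = loss_at(params)
            w[idx] = orig
            assert grads["fc2"]["w"][idx] == pytest.approx((up - dn) / (2 * eps),
                                                           rel=1e-2, abs=1e-4)


class TestExtraction:
    def test_6bnet_feature_width_is_4096_at_full_width(self, small_images):
        # feature tap is the 4096-unit fc layer; full channel width, small
        # spatial input (the fc fan-out is independent of input side)
        g = build_6bnet(2, input_side=48, width_scale=1.0)
        params = init_network(g, seed=0)
        fm = extract_6bnet_features(g, params, small_images)
        assert fm.values.shape == (len(small_images), 4096)
        assert fm.source == "FV2_6bnet"
        assert np.array_equal(fm.labels, small_images.labels)

    def test_softmax_tap_rows_sum_to_one(self, small_images):
        g = build_6bnet(2, input_side=48, width_scale=0.125)
        params = init_network(g, seed=0)
        fm = extract_6bnet_features(g, params, small_images, layer_name="softmax")
        assert fm.values.shape == (len(small_images), 2)
        assert np.allclose(fm.values.sum(axis=1), 1.0, atol=1e-6)

    def test_unknown_layer_rejected(self, small_images, tiny_net):
        g, params = tiny_net
        with pytest.raises(KeyError):
            extract_6bnet_features(g, params, small_images, layer_name="nope")

    def test_identical_images_give_identical_rows(self, tiny_net):
        g, params = tiny_net
        img = make_synthetic_histology(1, 2, 48, seed=0).images[0]
        fm = extract_6bnet_features(g, params, [img, img],
                                    labels=np.array([0, 1]))
        assert np.array_equal(fm.values[0], fm.values[1])

    def test_extraction_does_not_mutate_weights(self, small_images, tiny_net):
        g, params = tiny_net
        before = params["conv1"]["w"].copy()
        extract_6bnet_features(g, params, small_images)
        assert np.array_equal(before, params["conv1"]["w"])

    def test_reference_features_are_1000_wide_and_deterministic(self, small_images):
        a = extract_reference_features(small_images, input_side=48, seed=2)
        b = extract_reference_features(small_images, input_side=48, seed=2)
        assert a.values.shape == (len(small_images), 1000)
        assert a.source == "FV1_reference"
        assert np.array_equal(a.values, b.values)

    def test_constant_image_duplicated_rows_identical(self):
        img = np.full((48, 48, 3), 120, dtype=np.uint8)
        fm = extract_reference_features([img, img], labels=np.array([0, 1]),
                                        input_side=48, seed=0)
        assert np.array_equal(fm.values[0], fm.values[1])


class TestEstimatorAndIO:
    def test_estimator_fit_predict_and_roundtrip(self, small_images, tmp_path):
        net = SixBranchNet(input_side=48, width_scale=0.125, epochs=1,
                           lr=0.02, batch_size=8, random_state=0)
        net.fit(small_images)
        pred = net.predict(small_images.images)
        assert set(pred) <= {0, 1}
        save_network(tmp_path / "net", net.graph_, net.params_)
        g2, p2 = load_network(tmp_path / "net")
        fm1 = extract_6bnet_features(net.graph_, net.params_, small_images)
        fm2 = extract_6bnet_features(g2, p2, small_images)
        assert np.allclose(fm1.values, fm2.values)
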