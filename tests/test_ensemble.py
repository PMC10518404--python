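"""Network construction, preprocessing, training contracts."""

import numpy as np
import pytest

from qcdseg import NetworkSpec, TrainingConfig, build_network, predict_scs, \
    preprocess, train_ensemble
from qcdseg.ensemble import default_dropout_schedule
from qcdseg.nn import EarlyStopping, UNet, softmax, train_network


class TestPreprocess:
    def test_min_max_scaling(self):
        img = np.array([[100.0, 200.0], [300.0, 150.0]])
        out, _ = preprocess(img, target_size=4)
        inner = out[1:3, 1:3]
        assert np.allclose(inner, (img - 100) / 200)

    def test_constant_image_maps_to_zeros(self):
        out, _ = preprocess(np.full((4, 4), 7.0), target_size=8)
        assert np.all(out == 0)

    def test_symmetric_padding_offsets(self):
        img = np.ones((50, 60))
        img[0, 0] = 0.0
        out, off = preprocess(img, target_size=64)
        assert out.shape == (64, 64)
        assert off == (7, 2)
        assert out[7, 3] == 1.0 and out[6, 3] == 0.0 and out[7, 1] == 0.0

    def test_oversized_input_rejected(self):
        with pytest.raises(ValueError, match="cropping"):
            preprocess(np.ones((70, 70)), target_size=64)


class TestNetworkSpec:
    def test_input_size_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkSpec(depth=5, input_size=48)

    def test_dropout_schedule_constraints(self):
        with pytest.raises(ValueError, match="entries"):
            NetworkSpec(depth=3, dropout_schedule=(0.1, 0.2))
        with pytest.raises(ValueError, match="non-decreasing"):
            NetworkSpec(depth=3, dropout_schedule=(0.3, 0.2, 0.1))

    def test_default_schedule_is_monotone_ramp(self):
        sched = default_dropout_schedule(6)
        assert len(sched) == 6
        assert sched[0] == pytest.approx(0.05)
        assert sched[-1] == pytest.approx(0.5)
        assert all(b >= a for a, b in zip(sched, sched[1:]))


class TestNetwork:
    @pytest.mark.parametrize("depth", [1, 2, 4, 6])
    def test_shape_roundtrip(self, depth):
        spec = NetworkSpec(depth=depth, base_filters=2, input_size=64)
        net = build_network(spec)
        out = net.forward(np.zeros((1, 64, 64), np.float32))
        assert out.shape == (1, 64, 64, 2)

    def test_softmax_normalisation(self, rng):
        spec = NetworkSpec(depth=2, base_filters=4, input_size=16)
        net = build_network(spec, seed=1)
        p = net.predict_proba(rng.random((2, 16, 16)).astype(np.float32))
        assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_depth_one_single_pool_pair(self):
        net = build_network(NetworkSpec(depth=1, base_filters=2, input_size=8))
        assert len(net.enc_pools) == 1
        assert len(net.dec_ups) == 1
        out = net.forward(np.zeros((1, 8, 8), np.float32))
        assert out.shape == (1, 8, 8, 2)


class TestEarlyStopping:
    def test_worsening_validation_stops_and_restores_first_epoch(self):
        net = UNet(depth=1, base_filters=2, dropout_schedule=[0.0],
                   input_size=8, seed=0)
        stopper = EarlyStopping(patience=5)
        stopped_at = None
        state0 = net.get_state()
        for epoch, loss in enumerate([1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6]):
            # mutate parameters each epoch, as training would
            for l, n in net.parameters():
                l.params[n] += 0.1
            if stopper.update(epoch, loss, net):
                stopped_at = epoch
                break
        assert stopped_at == 5  # epochs 1..5 are the 5 bad epochs
        stopper.restore(net)
        restored = net.get_state()
        for k in state0:
            assert np.allclose(restored[k], state0[k] + 0.1)  # epoch-0 params

    def test_restored_loss_never_worse_than_best(self):
        net = UNet(depth=1, base_filters=2, dropout_schedule=[0.0],
                   input_size=8, seed=0)
        stopper = EarlyStopping(patience=2)
        losses = [0.9, 0.7, 0.8, 0.75]
        for epoch, loss in enumerate(losses):
            stopper.update(epoch, loss, net)
        assert stopper.best_loss == min(losses)
        assert stopper.best_epoch == 1


class TestTraining:
    def test_epoch_one_loss_reproducible(self, rng):
        x = rng.random((6, 16, 16)).astype(np.float32)
        y = (rng.random((6, 16, 16)) < 0.3).astype(np.int64)
        losses = []
        for _ in range(2):
            net = UNet(depth=1, base_filters=2, dropout_schedule=[0.1],
                       input_size=16, seed=3)
            log = train_network(net, x, y, x, y, lr=1e-3, max_epochs=1,
                                patience=1, seed=3)
            losses.append(log.train_loss[0])
        assert losses[0] == losses[1]

    def test_leak_guard_refuses_patient_overlap(self, tiny_split):
        train, val, _ = tiny_split
        specs = [NetworkSpec(depth=1, base_filters=2, input_size=64)]
        cfg = TrainingConfig(max_epochs=1)
        with pytest.raises(ValueError, match="leak"):
            train_ensemble(train, train[:4], specs, cfg)


class TestEnsembleInference:
    def test_one_mask_per_member_in_order(self, tiny_bundle, tiny_split):
        _, _, test = tiny_split
        img, _ = preprocess(test[0].image, 64)
        masks = predict_scs(tiny_bundle, img)
        assert len(masks) == len(tiny_bundle)
        for m in masks:
            assert m.shape == (64, 64)
            assert set(np.unique(m)) <= {0, 1}

    def test_inference_is_deterministic(self, tiny_bundle, tiny_split):
        _, _, test = tiny_split
        img, _ = preprocess(test[0].image, 64)
        m1 = predict_scs(tiny_bundle, img)
        m2 = predict_scs(tiny_bundle, img)
        for a, b in zip(m1, m2):
            assert np.array_equal(a, b)

    def test_shape_mismatch_names_expected_size(self, tiny_bundle):
        with pytest.raises(ValueError, match="64"):
            predict_scs(tiny_bundle, np.zeros((32, 32)))

    def test_bundle_depth_ascending(self, tiny_bundle):
        depths = [m.depth for m in tiny_bundle.members]
        assert depths == sorted(depths)

    def test_bundle_save_load_identical_predictions(self, tiny_bundle,
                                                    tiny_split, tmp_path):
        from qcdseg import EnsembleBundle
        _, _, test = tiny_split
        img, _ = preprocess(test[0].image, 64)
        tiny_bundle.save(tmp_path / "b")
        loaded = EnsembleBundle.load(tmp_path / "b")
        for a, b in zip(predict_scs(tiny_bundle, img),
                        predict_scs(loaded, img)):
            assert np.array_equal(a, b)
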