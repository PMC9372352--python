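import numpy as np
import pytest

from wmhkit.core import LabelVolume
from wmhkit.fusion import WeightMap, build_weight_map, fuse_pair
from wmhkit.nn import build_network, tiny_config
from wmhkit.nn.autodiff import Tensor
from wmhkit.phantom import PhantomSpec, generate_phantom, simulate_raters
from wmhkit.training import (TrainConfig, dice_loss, load_checkpoint, one_hot,
                             predict, sample_patches, save_checkpoint, train,
                             weighted_dice_loss, _dice_terms)


def _random_probs(rng, shape=(2, 3, 8, 8)):
    logits = rng.normal(size=shape)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def _random_onehot(rng, shape=(2, 3, 8, 8)):
    labels = rng.integers(0, shape[1], size=(shape[0],) + shape[2:])
    return np.stack([one_hot(l, shape[1]) for l in labels])


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self):
        rng = np.random.default_rng(0)
        g = _random_onehot(rng)
        assert float(dice_loss(Tensor(g), g).data) < 1e-3

    def test_total_miss_is_one(self):
        g = np.zeros((1, 2, 2, 2))
        p = np.zeros_like(g)
        g[0, 0] = 1.0  # truth all class 0
        p[0, 1] = 1.0  # prediction all class 1
        assert float(dice_loss(Tensor(p), g).data) == pytest.approx(1.0,
                                                                    abs=1e-4)

    def test_toy_patch_matches_hand_formula(self):
        """4-voxel 2-class patch evaluated against the soft-Dice formula."""
        p0 = np.array([0.9, 0.6, 0.2, 0.1])
        p = np.stack([p0, 1 - p0]).reshape(1, 2, 1, 4)
        g0 = np.array([1.0, 1.0, 0.0, 0.0])
        g = np.stack([g0, 1 - g0]).reshape(1, 2, 1, 4)
        eps = 1e-5
        expected = 1 - 0.5 * (
            2 * (p0 * g0).sum() / ((p0 ** 2).sum() + (g0 ** 2).sum() + eps) +
            2 * ((1 - p0) * (1 - g0)).sum() /
            (((1 - p0) ** 2).sum() + ((1 - g0) ** 2).sum() + eps))
        assert float(dice_loss(Tensor(p), g).data) == pytest.approx(
            expected, abs=1e-6)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            v = float(dice_loss(Tensor(_random_probs(rng)),
                                _random_onehot(rng)).data)
            assert 0.0 <= v <= 1.0


class TestWeightedDiceLoss:
    def test_unit_weights_reduce_to_plain_dice(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            p = _random_probs(rng)
            g = _random_onehot(rng)
            w = np.ones(p.shape[:1] + p.shape[2:])
            assert abs(float(weighted_dice_loss(Tensor(p), g, w).data) -
                       float(dice_loss(Tensor(p), g).data)) <= 1e-6

    def test_weights_affect_only_wmh_class_term(self):
        rng = np.random.default_rng(3)
        p = Tensor(_random_probs(rng))
        g = _random_onehot(rng)
        w1 = np.ones(p.shape[:1] + p.shape[2:])
        w2 = np.where(g[:, 1] > 0.5, 2.0, 1.0)
        t1 = [float(t.data) for t in _dice_terms(p, g, w1, (1,))]
        t2 = [float(t.data) for t in _dice_terms(p, g, w2, (1,))]
        assert t1[0] == pytest.approx(t2[0], abs=1e-12)   # background
        assert t1[2] == pytest.approx(t2[2], abs=1e-12)   # other lesion
        assert t1[1] != pytest.approx(t2[1], abs=1e-9)    # WMH changed

    def test_out_of_range_weights_rejected(self):
        rng = np.random.default_rng(4)
        p = Tensor(_random_probs(rng))
        g = _random_onehot(rng)
        w = np.full(p.shape[:1] + p.shape[2:], 2.5)
        with pytest.raises(ValueError):
            weighted_dice_loss(p, g, w)

    @pytest.mark.usefixtures("float64_autodiff")
    def test_definite_voxel_gets_larger_gradient(self):
        """Weight 2 at a WMH voxel scales its loss gradient above weight 1."""
        rng = np.random.default_rng(5)
        p_data = _random_probs(rng, (1, 3, 4, 4))
        g = np.zeros((1, 3, 4, 4))
        g[0, 1, 1, 1] = g[0, 1, 2, 2] = 1.0      # two WMH voxels
        g[0, 0] = 1.0 - g[0, 1]
        w = np.ones((1, 4, 4))
        w[0, 1, 1] = 2.0                          # definite; (2,2) suspected w=1
        p = Tensor(p_data, requires_grad=True)
        weighted_dice_loss(p, g, w).backward()
        assert abs(p.grad[0, 1, 1, 1]) > abs(p.grad[0, 1, 2, 2])


class TestSamplePatches:
    def _study(self, seed=0, shape=(10, 16, 16)):
        spec = PhantomSpec(shape=shape, spacing=(5.0, 2.0, 2.0),
                           n_wmh_lesions=1, n_other_lesions=0, seed=seed)
        return generate_phantom(spec)

    def test_seeded_batches_identical(self, tiny_phantom):
        args = (tiny_phantom, tiny_phantom.truth, None, 32, 4)
        a = sample_patches(*args, seed=9)
        b = sample_patches(*args, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_lesion_free_study_uniform_slices(self):
        spec = PhantomSpec(shape=(10, 16, 16), spacing=(5.0, 2.0, 2.0),
                           n_wmh_lesions=0, n_other_lesions=0, seed=1)
        st = generate_phantom(spec)
        xs, gs, ws = sample_patches(st, st.truth, None, 16, 64, seed=0,
                                    oversample=5.0)
        assert xs.shape == (64, 3, 16, 16) and not gs.any()

    def test_oversampling_frequency_matches_expectation(self):
        st = self._study(seed=3)
        lesion_slices = (st.truth.data > 0).any(axis=(1, 2))
        k = int(lesion_slices.sum())
        nz = st.truth.data.shape[0]
        # full-slice patches: a patch contains lesion iff its slice does
        _, gs, _ = sample_patches(st, st.truth, None, 16, 4000, seed=0,
                                  oversample=5.0)
        frac = (gs > 0).any(axis=(1, 2)).mean()
        p_expected = 5.0 * k / (5.0 * k + (nz - k))
        sd = np.sqrt(p_expected * (1 - p_expected) / 4000)
        assert abs(frac - p_expected) < 5 * sd

    def test_small_slice_zero_padded(self):
        spec = PhantomSpec(shape=(6, 12, 12), spacing=(5.0, 2.0, 2.0),
                           n_wmh_lesions=0, n_other_lesions=0, seed=4)
        st = generate_phantom(spec)
        xs, gs, ws = sample_patches(st, st.truth, None, 16, 3, seed=1)
        assert xs.shape == (3, 3, 16, 16)
        assert np.all(xs[:, :, 0, :] == 0) and np.all(xs[:, :, -1, :] == 0)
        assert np.all(ws[:, 0, :] == 1.0)  # padding carries neutral weight


def _prepare(n, base_seed=0, shape=(12, 64, 64)):
    studies, lw = [], []
    for s in range(n):
        spec = PhantomSpec(shape=shape, spacing=(5.0, 2.0, 2.0), seed=base_seed + s,
                           n_wmh_lesions=5, n_other_lesions=2)
        st = generate_phantom(spec)
        ra, rb = simulate_raters(st.truth, spec)
        fus = fuse_pair(ra, rb)
        studies.append(st)
        lw.append((fus.union_label, build_weight_map(fus)))
    return studies, lw


class TestTrainLoop:
    def test_loss_decreases_on_single_phantom(self):
        studies, lw = _prepare(1, base_seed=10)
        net = build_network(tiny_config(), seed=0)
        cfg = TrainConfig(batch_size=4, patch_size=64, epochs=3,
                          steps_per_epoch=8, seed=0)
        res = train(net, studies, lw, cfg)
        assert res.history.train_loss.iloc[-1] < res.history.train_loss.iloc[0]

    def test_zero_learning_rate_freezes_weights(self):
        studies, lw = _prepare(1, base_seed=11)
        net = build_network(tiny_config(), seed=0)
        before = [a.copy() for a in net.state_arrays()]
        cfg = TrainConfig(learning_rate=0.0, batch_size=2, patch_size=64,
                          epochs=1, steps_per_epoch=3, seed=0)
        train(net, studies, lw, cfg)
        trainable = {id(p.data) for p in net.parameters()}
        for a, b in zip(net.state_arrays(), before):
            if id(a) in trainable:
                assert np.array_equal(a, b)

    def test_training_reproducible_for_fixed_seed(self):
        studies, lw = _prepare(1, base_seed=12)
        cfg = TrainConfig(batch_size=2, patch_size=64, epochs=1,
                          steps_per_epoch=4, seed=7)
        r1 = train(build_network(tiny_config(), seed=1), studies, lw, cfg)
        r2 = train(build_network(tiny_config(), seed=1), studies, lw, cfg)
        assert r1.history.train_loss.iloc[-1] == \
            pytest.approx(r2.history.train_loss.iloc[-1], abs=1e-7)


class TestPredict:
    def test_argmax_and_mask_contract(self, tiny_phantom):
        net = build_network(tiny_config(), seed=0)
        label, probs = predict(net, tiny_phantom)
        assert label.shape == tiny_phantom.shape
        assert probs.shape == (3,) + tiny_phantom.shape
        inside = tiny_phantom.brain_mask
        assert np.array_equal(label.data[inside],
                              probs.argmax(axis=0)[inside])
        assert not label.data[~inside].any()

    def test_checkpoint_round_trip(self, tmp_path, tiny_phantom):
        net = build_network(tiny_config(), seed=2)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, net)
        restored = load_checkpoint(path)
        l1, p1 = predict(net, tiny_phantom)
        l2, p2 = predict(restored, tiny_phantom)
        assert np.array_equal(l1.data, l2.data)
        assert np.allclose(p1, p2)
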