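"""2.5D CNN stage: activations, switchable norm, architecture, training."""

import numpy as np
import pytest

from petctrad.deep import (
    CNN25D,
    TrainConfig,
    Var,
    build_cnn,
    conv2d,
    extract_deep_features,
    maxpool2d,
    mish,
    train_cnn,
)
from petctrad.deep.layers import SwitchableNorm2d, softmax_weights
from petctrad.types import PatchSet


class TestMish:
    def test_zero(self):
        assert mish(0.0) == pytest.approx(0.0)

    def test_positive_asymptote(self):
        assert mish(20.0) == pytest.approx(20.0, rel=1e-6)

    def test_negative_asymptote(self):
        assert mish(-20.0) == pytest.approx(0.0, abs=1e-6)

    def test_matches_definition_on_grid(self):
        x = np.linspace(-5, 5, 101)
        ref = x * np.tanh(np.log1p(np.exp(x)))
        np.testing.assert_allclose(mish(x), ref, atol=1e-9)


class TestSwitchableNorm:
    def test_one_hot_batch_weights_reduce_to_batchnorm(self, rng):
        sn = SwitchableNorm2d(3, "t")
        sn.mean_logits.data = np.array([-60.0, -60.0, 60.0], np.float32)
        sn.var_logits.data = np.array([-60.0, -60.0, 60.0], np.float32)
        x = rng.normal(2.0, 3.0, size=(8, 3, 4, 4)).astype(np.float32)
        out = sn(Var(x)).data
        mu = x.mean(axis=(0, 2, 3), keepdims=True)
        var = x.var(axis=(0, 2, 3), keepdims=True)
        np.testing.assert_allclose(out, (x - mu) / np.sqrt(var + 1e-5), atol=1e-4)

    def test_constant_input_returns_beta(self):
        sn = SwitchableNorm2d(2, "t")
        sn.beta.data = np.full((1, 2, 1, 1), 0.7, np.float32)
        out = sn(Var(np.full((4, 2, 5, 5), 3.0))).data
        np.testing.assert_allclose(out, 0.7, atol=1e-2)

    def test_softmax_weights_sum_to_one(self):
        w = softmax_weights(Var(np.array([0.3, -1.2, 2.0]))).data
        assert w.sum() == pytest.approx(1.0, abs=1e-6)

    def test_empty_batch_rejected(self):
        sn = SwitchableNorm2d(1, "t")
        with pytest.raises(ValueError):
            sn(Var(np.zeros((0, 1, 2, 2))))


class TestAutogradNumerics:
    def test_conv_weight_gradient_matches_numeric(self, rng):
        x = Var(rng.normal(size=(2, 3, 6, 6)))
        w = Var(rng.normal(size=(4, 3, 3, 3)) * 0.1, requires_grad=True)
        b = Var(np.zeros(4), requires_grad=True)

        def loss():
            return (conv2d(x, w, b) ** 2).mean()

        l0 = loss()
        l0.backward()
        g = w.grad.copy()
        eps = np.float32(1e-2)
        idx = (2, 1, 0, 2)
        w.data[idx] += eps
        lp = float(loss().data)
        w.data[idx] -= 2 * eps
        lm = float(loss().data)
        assert g[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-2, abs=1e-4)

    def test_maxpool_routes_gradient_to_argmax(self):
        x = Var(np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4), requires_grad=True)
        out = maxpool2d(x, 2).sum()
        out.backward()
        expected = np.zeros((1, 1, 4, 4))
        for i in (1, 3):
            for j in (1, 3):
                expected[0, 0, i, j] = 1
        np.testing.assert_array_equal(x.grad, expected)


class TestArchitecture:
    @pytest.mark.parametrize("modality,size", [("CT", 64), ("PET", 128)])
    def test_structural_invariants(self, modality, size):
        net = build_cnn(modality)
        spec = net.spec()
        spec.validate()
        assert spec.n_weighted_layers == 23
        assert spec.n_pool_layers == 5
        assert spec.feature_channels == 512
        assert spec.feature_layer == "block4_pool_2"
        assert spec.input_size == size

    def test_unknown_modality_rejected(self):
        with pytest.raises(ValueError):
            build_cnn("MRI")

    def test_feature_vector_length_512(self, rng):
        net = build_cnn("CT")
        net.set_training(False)
        v = net.features(Var(rng.normal(size=(1, 1, 64, 64)).astype(np.float32)))
        assert v.data.shape == (1, 512)

    def test_save_load_roundtrip(self, rng, tmp_path):
        net = build_cnn("CT", seed=3)
        path = str(tmp_path / "model.npz")
        net.save(path)
        net2 = CNN25D.load(path)
        x = rng.normal(size=(2, 64, 64))
        np.testing.assert_allclose(net.predict_proba(x), net2.predict_proba(x), atol=1e-6)


def _patch_set(rng, axial_only=False):
    ps = PatchSet(lesion_id="t")
    for modality, size in (("CT", 64), ("PET", 128)):
        base = rng.random((size, size))
        for plane in ("axial", "sagittal", "coronal"):
            ps.patches[(modality, plane)] = base if axial_only else rng.random((size, size))
    return ps


class TestDeepFeatures:
    def test_output_length_3072_and_names(self, rng):
        ct, pet = build_cnn("CT"), build_cnn("PET")
        feats = extract_deep_features(ct, pet, _patch_set(rng))
        assert len(feats) == 3072
        assert "DF_CT_axial_c0" in feats and "DF_PET_coronal_c511" in feats
        assert all(np.isfinite(v) for v in feats.values())

    def test_duplicated_axial_patch_gives_identical_plane_blocks(self, rng):
        ct, pet = build_cnn("CT"), build_cnn("PET")
        feats = extract_deep_features(ct, pet, _patch_set(rng, axial_only=True))
        for mod in ("CT", "PET"):
            a = [feats[f"DF_{mod}_axial_c{k}"] for k in range(512)]
            s = [feats[f"DF_{mod}_sagittal_c{k}"] for k in range(512)]
            np.testing.assert_allclose(a, s, atol=1e-7)

    def test_zero_patch_features_lesion_independent(self, rng):
        ct, pet = build_cnn("CT"), build_cnn("PET")
        zero = PatchSet(lesion_id="z")
        for modality, size in (("CT", 64), ("PET", 128)):
            for plane in ("axial", "sagittal", "coronal"):
                zero.patches[(modality, plane)] = np.zeros((size, size))
        f1 = extract_deep_features(ct, pet, zero)
        f2 = extract_deep_features(ct, pet, zero)
        assert f1 == f2

    def test_missing_plane_rejected(self, rng):
        ct, pet = build_cnn("CT"), build_cnn("PET")
        ps = _patch_set(rng)
        del ps.patches[("PET", "coronal")]
        with pytest.raises(ValueError):
            extract_deep_features(ct, pet, ps)


class TestTraining:
    def test_loss_decreases_and_deterministic(self, rng):
        n = 24
        X = rng.normal(0.3, 0.1, size=(n, 64, 64))
        y = np.array([0, 1] * (n // 2))
        X[y == 1] += 0.4  # separable intensity shift
        cfg = TrainConfig(epochs=3, seed=7, batch_size=8)
        _, h1 = train_cnn(X, y, cfg, modality="CT")
        _, h2 = train_cnn(X, y, cfg, modality="CT")
        assert h1["loss"][-1] < h1["loss"][0]
        assert h1["loss"] == h2["loss"]

    def test_planted_contrast_learned(self, rng):
        """Patches whose classes differ in texture scale are classified
        above chance after a short training run."""
        n = 40
        X = np.empty((n, 64, 64))
        y = np.array([0, 1] * (n // 2))
        from scipy.ndimage import gaussian_filter

        for i in range(n):
            noise = rng.normal(size=(64, 64))
            X[i] = gaussian_filter(noise, 3.0 if y[i] else 1.0)
            X[i] = (X[i] - X[i].min()) / (np.ptp(X[i]) + 1e-9)
        model, hist = train_cnn(X, y, TrainConfig(epochs=6, seed=1, batch_size=8), modality="CT")
        assert hist["accuracy"][-1] > 0.8

    def test_huge_l2_shrinks_weights(self, rng):
        """With lambda = 1e3 the penalty gradient dominates and conv weights
        end much smaller than in the unregularized run."""
        n = 8
        X = rng.normal(size=(n, 64, 64))
        y = np.array([0, 1] * (n // 2))

        def wnorm(l2):
            model, _ = train_cnn(
                X, y, TrainConfig(epochs=10, seed=0, batch_size=8, l2=l2), modality="CT"
            )
            return float(np.linalg.norm(model.convs[0].weight.data))

        assert wnorm(1e3) < 0.5 * wnorm(0.0)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_cnn(rng.normal(size=(8, 64, 64)), np.ones(8), TrainConfig(epochs=1), modality="CT")
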