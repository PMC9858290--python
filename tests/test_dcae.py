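"""Autoencoder shapes, training behaviour, synthesis, persistence."""

import numpy as np
import pytest

from leukonet import (DCAE, DCAESpec, GTPlan, ImageSample, SpecError,
                      TrainingConfig)
from leukonet.nn import conv2d
from leukonet.nn.layers import _im2col  # noqa: F401  (engine internals exist)


def _toy_model(size=16, seed=0):
    return DCAE(DCAESpec(input_size=size), seed=seed)


def test_spec_latent_arithmetic():
    assert DCAESpec(input_size=224).latent_shape == (28, 28, 128)
    assert DCAESpec(input_size=56).latent_shape == (7, 7, 128)
    assert DCAESpec(input_size=224).encoder_grids == [
        (112, 112, 32), (56, 56, 64), (28, 28, 128)]


def test_spec_rejects_unreachable_latent():
    with pytest.raises(SpecError):
        DCAESpec(input_size=100)  # not divisible by 8
    with pytest.raises(SpecError):
        DCAESpec(decoder_filters=(64, 128, 32))  # not a mirror


def test_build_deterministic_under_seed():
    a, b = _toy_model(seed=3), _toy_model(seed=3)
    for pa, pb in zip(a._net.params, b._net.params):
        assert np.array_equal(pa.value, pb.value)
    c = _toy_model(seed=4)
    assert any(not np.array_equal(pa.value, pc.value)
               for pa, pc in zip(a._net.params, c._net.params))


def test_encode_decode_shapes(rng):
    m = _toy_model(16)
    x = rng.random((3, 16, 16, 3), dtype=np.float32)
    z = m.encode(x)
    assert z.shape == (3, 2, 2, 128)
    y = m.decode(z)
    assert y.shape == (3, 16, 16, 3)
    assert y.min() >= 0.0 and y.max() <= 1.0
    # shape conservation through a second pass
    assert m.encode(y).shape == z.shape


def test_encode_wrong_shape_rejected(rng):
    m = _toy_model(16)
    with pytest.raises(ValueError, match="shape"):
        m.encode(rng.random((2, 8, 8, 3), dtype=np.float32))
    with pytest.raises(ValueError, match="shape"):
        m.decode(rng.random((2, 3, 3, 128), dtype=np.float32))


def test_zero_image_zero_bias_gives_zero_latent():
    m = _toy_model(16)
    z = m.encode(np.zeros((1, 16, 16, 3), dtype=np.float32))
    assert np.allclose(z, 0.0)  # conv of zeros is zero; leaky-relu(0)=0


def test_encoder_matches_layerwise_oracle(rng):
    """One conv+pool stage recomputed with the functional conv and a block max."""
    m = _toy_model(16)
    x = rng.random((16, 16, 3), dtype=np.float32)
    conv1 = m.encoder.layers[0]
    ref = conv2d(x, conv1.w.value, conv1.b.value,
                 activation="leaky_relu", alpha=m.spec.leaky_alpha)
    pooled = ref.reshape(8, 2, 8, 2, 32).max(axis=(1, 3))
    stage = m.encoder.layers[1].forward(
        m.encoder.layers[0].forward(x[None], training=False), training=False)
    assert np.allclose(stage[0], pooled, atol=1e-5)


def test_fit_epochs_zero_is_identity(myeloblast_images_56):
    m = DCAE(DCAESpec(input_size=56), seed=0)
    before = [p.value.copy() for p in m._net.params]
    res = m.fit(myeloblast_images_56[:8], TrainingConfig(epochs=0))
    assert res.history["loss"] == []
    for p, old in zip(m._net.params, before):
        assert np.array_equal(p.value, old)


def test_fit_memorizes_constant_image():
    img = np.full((1, 16, 16, 3), 0.25, dtype=np.float32)
    m = _toy_model(16, seed=1)
    res = m.fit(img, TrainingConfig(learning_rate=0.5, epochs=300, batch_size=1,
                                    seed=1, target_loss=5e-4))
    assert m.reconstruction_mse(img) < 1e-3
    assert res.final_loss <= res.history["loss"][0]


def test_loss_history_mostly_decreasing(myeloblast_images_56):
    m = DCAE(DCAESpec(input_size=56), seed=2)
    res = m.fit(myeloblast_images_56, TrainingConfig(
        learning_rate=0.1, epochs=8, batch_size=16, seed=2))
    h = res.history["loss"]
    assert len(h) == 8
    drops = sum(1 for a, b in zip(h, h[1:]) if b <= a)
    assert drops >= 0.8 * (len(h) - 1)
    assert h[-1] <= h[0]


def test_reconstruction_mse_closed_forms(rng):
    m = _toy_model(16)
    x = rng.random((2, 16, 16, 3), dtype=np.float32)
    assert np.mean((x - x) ** 2) == 0.0
    # shifted-by-0.1 reconstruction has MSE 0.01 (computed directly)
    y = x + 0.1
    assert np.isclose(np.mean((x - y) ** 2), 0.01, atol=1e-6)


def test_synthesize_counts_labels_determinism(myeloblast_images_56):
    m = DCAE(DCAESpec(input_size=56), seed=0)
    pool = [ImageSample(p, label="myeloblast", source_id=f"s{i}")
            for i, p in enumerate(myeloblast_images_56[:10])]
    out = m.synthesize(pool, 12, GTPlan(seed=0), seed=5)
    assert len(out) == 12
    assert all(o.label == "myeloblast" for o in out)
    out2 = m.synthesize(pool, 12, GTPlan(seed=0), seed=5)
    for a, b in zip(out, out2):
        assert np.array_equal(a.pixels, b.pixels)
    # outputs differ from their sources (the autoencoder is not invertible)
    diffs = [np.abs(o.pixels - pool[0].pixels).mean() for o in out]
    assert min(diffs) > 0.0


def test_synthesize_argument_errors(myeloblast_images_56):
    m = DCAE(DCAESpec(input_size=56), seed=0)
    pool = [ImageSample(myeloblast_images_56[0], label="myeloblast")]
    with pytest.raises(ValueError):
        m.synthesize(pool, 0)
    with pytest.raises(ValueError):
        m.synthesize([], 5)


def test_checkpoint_round_trip(tmp_path, rng):
    m = _toy_model(16, seed=9)
    x = rng.random((2, 16, 16, 3), dtype=np.float32)
    m.save(tmp_path / "m.h5")
    loaded = DCAE.load(tmp_path / "m.h5")
    assert loaded.spec == m.spec
    assert np.allclose(loaded.encode(x), m.encode(x), atol=1e-6)
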