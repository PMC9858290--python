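"""Stage-I/II classifier shapes, training on separable latents, inference."""

import numpy as np
import pytest

from leukonet import (Stage1Classifier, Stage1Spec, Stage2Classifier,
                      Stage2Spec, TrainingConfig, argmax_class)
from leukonet.taxonomy import ATYPICAL_CLASSES, TaxonomyError

SMALL = (7, 7, 8)  # reduced-channel latent for fast tests


def _blobs(rng, n_per, centers, shape=SMALL):
    xs, ys = [], []
    for k, c in enumerate(centers):
        xs.append(c + 0.3 * rng.normal(size=(n_per, *shape)))
        ys += [k] * n_per
    return np.concatenate(xs).astype(np.float32), np.array(ys)


def test_stage1_default_shape_chain():
    spec = Stage1Spec()
    assert spec.grid_chain() == [14, 7, 7]
    assert spec.flattened_size() == 7 * 7 * 256 == 12544


def test_stage2_default_shape_chain():
    spec = Stage2Spec()
    assert spec.grid_chain() == [28, 28, 14, 7]
    assert spec.flattened_size() == 7 * 7 * 256 == 12544


def test_build_deterministic():
    spec = Stage1Spec(input_shape=SMALL, conv_filters=(4, 8, 8))
    a = Stage1Classifier(spec, seed=5)
    b = Stage1Classifier(spec, seed=5)
    for pa, pb in zip(a.net.params, b.net.params):
        assert np.array_equal(pa.value, pb.value)


def test_stage1_learns_separable_blobs(rng):
    spec = Stage1Spec(input_shape=SMALL, conv_filters=(4, 8, 8), dense_units=16)
    clf = Stage1Classifier(spec, seed=0)
    x, y = _blobs(rng, 60, [-1.0, 1.0])
    res = clf.fit(x, y, TrainingConfig(learning_rate=0.05, epochs=20,
                                       batch_size=16, seed=0))
    assert res.history["accuracy"][-1] >= 0.99
    assert len(res.history["loss"]) == 20
    assert res.final_loss <= res.history["loss"][0]


def test_stage1_single_class_rejected(rng):
    clf = Stage1Classifier(Stage1Spec(input_shape=SMALL, conv_filters=(4, 4, 4)))
    x = rng.random((10, *SMALL), dtype=np.float32)
    with pytest.raises(ValueError, match="both classes"):
        clf.fit(x, np.ones(10))


def test_stage1_predictions_are_probabilities(rng):
    clf = Stage1Classifier(Stage1Spec(input_shape=SMALL, conv_filters=(4, 4, 4)))
    x = rng.random((5, *SMALL), dtype=np.float32)
    p = clf.predict_proba(x)
    assert p.shape == (5,)
    assert np.all((p >= 0) & (p <= 1))
    assert np.array_equal(p, clf.predict_proba(x))  # inference determinism


def test_inference_batch_invariant(rng):
    """Predicting one sample equals predicting it inside a batch."""
    clf = Stage1Classifier(Stage1Spec(input_shape=SMALL, conv_filters=(4, 4, 4)), seed=1)
    x = rng.random((9, *SMALL), dtype=np.float32)
    batched = clf.predict_proba(x, batch_size=9)
    singles = np.array([clf.predict_proba(x[i:i + 1])[0] for i in range(9)])
    assert np.allclose(batched, singles, atol=1e-5)


def test_epochs_zero_leaves_params(rng):
    clf = Stage1Classifier(Stage1Spec(input_shape=SMALL, conv_filters=(4, 4, 4)))
    before = [p.value.copy() for p in clf.net.params]
    x, y = _blobs(rng, 4, [-1.0, 1.0])
    clf.fit(x, y, TrainingConfig(epochs=0))
    for p, old in zip(clf.net.params, before):
        assert np.array_equal(p.value, old)


def test_stage2_learns_eight_clusters(rng):
    spec = Stage2Spec(input_shape=SMALL, conv_filters=(4, 4, 8, 8), dense_units=16,
                      pool_after=(2, 3))
    clf = Stage2Classifier(spec, seed=0)
    centers = np.linspace(-2, 2, 8)
    x, y = _blobs(rng, 30, centers)
    res = clf.fit(x, y, TrainingConfig(learning_rate=0.05, epochs=80,
                                       batch_size=16, seed=0))
    assert res.history["accuracy"][-1] >= 0.95
    assert len(res.history["loss"]) == 80


def test_stage2_probability_vector_contract(rng):
    clf = Stage2Classifier(Stage2Spec(input_shape=SMALL, conv_filters=(4, 4, 4, 4)))
    x = rng.random((6, *SMALL), dtype=np.float32)
    probs = clf.predict_proba(x)
    assert probs.shape == (6, 8)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    pi = clf.predict_subtype(x[0])
    assert pi.shape == (8,)
    assert np.allclose(clf.predict_subtype(x[0]), pi)


def test_stage2_label_validation(rng):
    clf = Stage2Classifier(Stage2Spec(input_shape=SMALL, conv_filters=(4, 4, 4, 4)))
    x = rng.random((4, *SMALL), dtype=np.float32)
    with pytest.raises(TaxonomyError):
        clf.fit(x, ["myeloblast", "monocyte", "myeloblast", "monoblast"])


def test_argmax_class_canonical_order_and_ties():
    one_hot = np.zeros(8)
    one_hot[4] = 1.0
    assert argmax_class(one_hot) == "myeloblast"
    assert argmax_class(np.full(8, 0.125)) == "erythroblast"  # tie -> lowest index
    pi = np.full(8, 0.001)
    pi[4] = 0.99
    assert argmax_class(pi) == "myeloblast"


def test_softmax_sums_for_many_draws(rng):
    clf = Stage2Classifier(Stage2Spec(input_shape=SMALL, conv_filters=(4, 4, 4, 4)))
    x = rng.normal(size=(1000, *SMALL)).astype(np.float32) * 3
    assert np.allclose(clf.predict_proba(x).sum(axis=1), 1.0, atol=1e-5)


def test_l2_zero_dropout_zero_reduces_to_plain_cnn(rng):
    """The regularised model with l2=0, dropout=0 is the plain CNN ablation."""
    plain = Stage1Spec(input_shape=SMALL, conv_filters=(4, 4, 4),
                       dropout_rate=0.0, l2_coefficient=0.0)
    clf = Stage1Classifier(plain, seed=0)
    assert not any(type(l).__name__ == "Dropout" for l in clf.net.layers)
    x, y = _blobs(rng, 8, [-1.0, 1.0])
    clf.fit(x, y, TrainingConfig(learning_rate=0.01, epochs=1, batch_size=8, seed=0))


def test_checkpoint_round_trip(tmp_path, rng):
    spec = Stage2Spec(input_shape=SMALL, conv_filters=(4, 4, 4, 4))
    clf = Stage2Classifier(spec, seed=2)
    x = rng.random((3, *SMALL), dtype=np.float32)
    clf.save(tmp_path / "s2.h5")
    loaded = Stage2Classifier.load(tmp_path / "s2.h5")
    assert np.allclose(loaded.predict_proba(x), clf.predict_proba(x), atol=1e-6)
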