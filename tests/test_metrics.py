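"""Metric arithmetic against brute-force oracles and printed worked examples."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leukonet import (EvaluationReport, class_metrics, confusion_matrix,
                      f_score, multiclass_auc, overall_accuracy, roc_auc)
from leukonet.taxonomy import ATYPICAL_CLASSES, TaxonomyError


def cm_oracle(true, pred, order):
    k = len(order)
    idx = {c: i for i, c in enumerate(order)}
    out = np.zeros((k, k), dtype=int)
    for t, p in zip(true, pred):
        out[idx[t], idx[p]] += 1
    return out


def auc_oracle(y, s):
    """Exhaustive positive/negative pair comparison, ties counted 1/2."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_confusion_matrix_perfect_and_collapsed():
    order = ["a", "b", "c"]
    cm = confusion_matrix(["a", "b", "c"], ["a", "b", "c"], order)
    assert np.array_equal(cm, np.eye(3, dtype=int))
    cm2 = confusion_matrix(["a", "b", "c"], ["a", "a", "a"], order)
    assert cm2[:, 0].sum() == 3 and cm2[:, 1:].sum() == 0


def test_confusion_matrix_matches_counting_oracle():
    rng = np.random.default_rng(0)
    order = list("abcd")
    for _ in range(20):
        true = rng.choice(order, size=100).tolist()
        pred = rng.choice(order, size=100).tolist()
        assert np.array_equal(confusion_matrix(true, pred, order),
                              cm_oracle(true, pred, order))


def test_confusion_matrix_unknown_label():
    with pytest.raises(TaxonomyError):
        confusion_matrix(["a", "z"], ["a", "a"], ["a", "b"])


def test_class_metrics_hand_counted():
    cm = np.array([[8, 2], [1, 9]])
    r1 = class_metrics(cm, 1)
    assert math.isclose(r1.precision, 9 / 11)
    assert math.isclose(r1.sensitivity, 0.9)
    assert math.isclose(r1.specificity, 0.8)
    r0 = class_metrics(cm, 0)
    assert math.isclose(r0.precision, 8 / 9)
    assert math.isclose(r0.sensitivity, 0.8)


def test_class_metrics_diagonal_and_degenerate():
    cm = np.diag([3, 4, 5])
    for k in range(3):
        r = class_metrics(cm, k)
        assert (r.precision, r.sensitivity, r.specificity) == (1.0, 1.0, 1.0)
    # class never predicted and absent: precision undefined (flagged nan)
    cm2 = np.array([[5, 0], [0, 0]])
    r = class_metrics(cm2, 1)
    assert math.isnan(r.precision) and math.isnan(r.sensitivity)
    assert not r.defined["precision"]
    # predicted but never correct -> precision 0, not nan
    cm3 = np.array([[3, 2], [0, 0]])
    assert class_metrics(cm3, 1).precision == 0.0


# the printed per-class (precision, sensitivity) -> F worked examples
TABLE_PAIRS = [
    ("erythroblast", 1.00, 0.94, 0.97),
    ("lymphocyte_atypical", 0.50, 1.00, 0.67),
    ("metamyelocyte", 0.33, 0.50, 0.40),
    ("monoblast", 1.00, 0.86, 0.92),
    ("myeloblast", 0.99, 0.99, 0.99),
    ("promyelocyte_bilobed", 0.20, 1.00, 0.33),
    ("promyelocyte", 0.67, 0.53, 0.59),
]


@pytest.mark.parametrize("label,p,r,f_printed", TABLE_PAIRS)
def test_f_score_reproduces_printed_values(label, p, r, f_printed):
    assert abs(f_score(p, r) - f_printed) <= 0.005


def test_f_score_identity_and_flags():
    for p in (0.1, 0.5, 0.93):
        assert math.isclose(f_score(p, p), p)
    assert math.isnan(f_score(0.0, 0.0))
    assert f_score(0.0, 0.9) == 0.0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(p=st.floats(0.0, 1.0), r=st.floats(0.0, 1.0))
def test_f_score_bounded_by_max(p, r):
    f = f_score(p, r)
    if not math.isnan(f):
        assert f <= max(p, r) + 1e-12
        if p == 0.0 or r == 0.0:
            assert f == 0.0


def test_overall_accuracy():
    assert overall_accuracy(np.diag([2, 3])) == 1.0
    assert overall_accuracy(np.array([[0, 4], [5, 0]])) == 0.0
    rng = np.random.default_rng(2)
    cm = rng.integers(0, 20, size=(5, 5))
    cm[0, 0] += 1  # ensure nonzero total
    assert math.isclose(overall_accuracy(cm), np.trace(cm) / cm.sum())


def test_roc_auc_degenerate_cases():
    assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5
    with pytest.raises(ValueError):
        roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


def test_roc_auc_matches_pairwise_oracle():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n = int(rng.integers(6, 20))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = np.round(rng.random(n), 1)  # coarse scores force ties
        assert abs(roc_auc(y, s) - auc_oracle(y, s)) < 1e-12


def test_roc_auc_complement_symmetry():
    rng = np.random.default_rng(4)
    for _ in range(100):
        n = int(rng.integers(6, 30))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        s = rng.normal(size=n)  # continuous, tie-free a.s.
        assert math.isclose(roc_auc(y, s) + roc_auc(y, -s), 1.0, abs_tol=1e-9)


def test_multiclass_auc_reduction_and_edges():
    order = ["a", "b", "c"]
    truth = ["a", "a", "b", "b", "c", "c"]
    rng = np.random.default_rng(5)
    probs = rng.random((6, 3))
    probs /= probs.sum(1, keepdims=True)
    per, macro = multiclass_auc(truth, probs, order)
    for j, cls in enumerate(order):
        y = [int(t == cls) for t in truth]
        assert math.isclose(per[cls], roc_auc(y, probs[:, j]))
    assert math.isclose(macro, np.mean(list(per.values())))

    one_hot = np.eye(3)[[0, 0, 1, 1, 2, 2]]
    per2, macro2 = multiclass_auc(truth, one_hot, order)
    assert macro2 == 1.0 and all(v == 1.0 for v in per2.values())

    uniform = np.full((6, 3), 1 / 3)
    per3, macro3 = multiclass_auc(truth, uniform, order)
    assert macro3 == 0.5

    # absent class flagged and excluded
    per4, macro4 = multiclass_auc(["a", "a", "b"], np.eye(3)[[0, 0, 1]], order)
    assert math.isnan(per4["c"])


def test_evaluation_report_assembles():
    truth = ["myeloblast"] * 5 + ["monoblast"] * 3
    pred = ["myeloblast"] * 4 + ["monoblast"] + ["monoblast"] * 3
    rep = EvaluationReport.from_predictions(truth, pred, ATYPICAL_CLASSES)
    assert rep.cm.sum() == 8
    assert math.isclose(rep.accuracy, 7 / 8)
    d = rep.to_dict()
    assert d["per_class"]["myeloblast"]["sensitivity"] == 0.8
    assert "overall" in d and d["overall"]["accuracy"] == 0.875
    assert "myeloblast" in rep.summary()
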