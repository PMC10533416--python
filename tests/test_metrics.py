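"""Metric oracles: Dice, total Dice vs accuracy, CM errors, GED."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crowdseg as cs


def test_dice_class_hand_counts():
    truth = np.zeros((2, 2), int)
    truth[0, 1] = truth[1, 1] = 1
    pred = np.zeros((2, 2), int)
    pred[0, 0] = pred[0, 1] = 1
    # overlap {(0,1)}: 2*1/(2+2) = 0.5
    assert cs.dice_class(pred, truth, 1) == pytest.approx(0.5)
    assert cs.dice_class(truth, truth, 1) == 1.0
    assert cs.dice_class(1 - truth, truth, 1) == 0.0
    with pytest.raises(ValueError):
        cs.dice_class(pred, truth, 7, n_classes=2)


def test_dice_both_empty_is_one():
    empty = np.zeros((3, 3), int)
    assert cs.dice_class(empty, empty, 1) == 1.0


def test_dice_symmetry_for_hard_inputs():
    rng = np.random.default_rng(0)
    a, b = rng.integers(0, 3, (2, 6, 6))
    for c in range(3):
        assert cs.dice_class(a, b, c) == cs.dice_class(b, a, c)


def test_dice_accepts_probability_maps():
    truth = np.array([[0, 1]])
    probs = np.array([[[0.9, 0.1], [0.2, 0.8]]])
    assert cs.dice_class(probs, truth, 1) == 1.0
    assert cs.total_dice(probs, truth) == 1.0


def test_total_dice_hand_count_and_extremes():
    a = np.array([[0, 1], [1, 0]])
    assert cs.total_dice(a, a) == 1.0
    assert cs.total_dice(a, 1 - a) == 0.0
    b = a.copy()
    b[0, 0] = 1  # 3 of 4 agree: 2*3/(4+4)
    assert cs.total_dice(b, a) == pytest.approx(0.75)


@settings(max_examples=25, derandomize=True)
@given(seed=st.integers(0, 1000))
def test_total_dice_equals_pixel_accuracy_on_hard_maps(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 4, (5, 7))
    b = rng.integers(0, 4, (5, 7))
    brute = sum(int(x == y) for x, y in zip(a.ravel(), b.ravel())) / a.size
    assert cs.total_dice(a, b) == pytest.approx(brute)


def test_cm_rmse_hand_value_and_identities():
    est = {0: np.array([[0.6, 0.2], [0.4, 0.8]])}
    true = {0: np.array([[0.5, 0.3], [0.5, 0.7]])}
    # four entries each off by 0.1: sqrt(4*0.01/4)
    assert cs.cm_rmse(est, true) == pytest.approx(0.1)
    assert cs.cm_rmse(true, true) == 0.0
    # one column off by +0.1/-0.1 at a single pixel: sqrt((0.01+0.01)/4)
    single = {0: np.array([[[[0.6, 0.3], [0.4, 0.7]]]])}  # one-pixel field
    assert cs.cm_rmse(single, true) == pytest.approx(np.sqrt(0.005))
    assert cs.cm_rmse(est, None) is None  # truth undefined, not zero


def test_cm_incompetence_hand_value_and_linearity():
    uniform = {0: np.full((2, 2), 0.5)}
    identity = {0: np.eye(2)}
    assert cs.cm_incompetence(uniform, identity) == pytest.approx(0.5)
    assert cs.cm_incompetence(identity, identity) == 0.0
    half = {0: np.eye(2) * 0.5 + np.full((2, 2), 0.25)}
    assert cs.cm_incompetence(uniform, identity) == pytest.approx(
        2 * cs.cm_incompetence(half, identity))


def test_cm_errors_reject_mismatched_annotators():
    with pytest.raises(ValueError):
        cs.cm_rmse({0: np.eye(2)}, {1: np.eye(2)})


def test_ged_closed_forms():
    A = np.zeros((4, 4), int)
    B = A.copy()
    B[:2] = 1
    assert cs.generalized_energy_distance([A], [A]) == pytest.approx(0.0)
    d = 1 - cs.total_dice(A, B)
    assert cs.generalized_energy_distance([A], [B]) == pytest.approx(2 * d)
    with pytest.raises(ValueError):
        cs.generalized_energy_distance([], [A])


def test_ged_matches_bruteforce_pairwise_means():
    rng = np.random.default_rng(1)
    S = [rng.integers(0, 2, (4, 4)) for _ in range(2)]
    Y = [rng.integers(0, 2, (4, 4)) for _ in range(2)]
    d = lambda a, b: 1 - cs.total_dice(a, b)
    cross = np.mean([d(s, y) for s, y in itertools.product(S, Y)])
    ss = np.mean([d(a, b) for a, b in itertools.product(S, S)])
    yy = np.mean([d(a, b) for a, b in itertools.product(Y, Y)])
    assert cs.generalized_energy_distance(S, Y) == pytest.approx(2 * cross - ss - yy)


@settings(max_examples=20, derandomize=True)
@given(seed=st.integers(0, 500), ns=st.integers(1, 4), ny=st.integers(1, 4))
def test_ged_nonnegative_for_dice_kernel(seed, ns, ny):
    rng = np.random.default_rng(seed)
    S = [rng.integers(0, 2, (4, 4)) for _ in range(ns)]
    Y = [rng.integers(0, 2, (4, 4)) for _ in range(ny)]
    assert cs.generalized_energy_distance(S, Y) >= -1e-12


def test_metric_report_serialisation():
    rep = cs.evaluate_segmentation(np.zeros((2, 2), int), np.zeros((2, 2), int), 2)
    d = rep.to_dict()
    assert d["total_dice"] == 1.0
    assert "0" in d["dice_per_class"]
    assert rep.flat()["cm_rmse"] is None
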