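"""Synthetic annotator simulator: determinism, morphology, exact-CM corruption."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crowdseg as cs
from conftest import binary_cm


def test_generate_shapes_deterministic_and_nonempty():
    a = cs.generate_shapes(4, 32, 32, 2, seed=7)
    b = cs.generate_shapes(4, 32, 32, 2, seed=7)
    for s1, s2 in zip(a, b):
        assert np.array_equal(s1.image, s2.image)
        assert np.array_equal(s1.mask, s2.mask)
    assert all((s.mask > 0).any() for s in a)


def test_generate_shapes_covers_all_classes():
    samples = cs.generate_shapes(100, 32, 32, 2, seed=1)
    labels = np.concatenate([s.mask.ravel() for s in samples])
    assert set(np.unique(labels)) == {0, 1}
    three = cs.generate_shapes(12, 32, 32, 3, seed=0)
    assert set(np.unique(np.concatenate([s.mask.ravel() for s in three]))) == {0, 1, 2}


def test_generate_shapes_rejects_bad_dims():
    with pytest.raises(ValueError):
        cs.generate_shapes(1, 4, 4, 2, seed=0)
    with pytest.raises(ValueError):
        cs.generate_shapes(0, 32, 32, 2, seed=0)
    with pytest.raises(ValueError):
        cs.generate_shapes(1, 32, 32, 1, seed=0)


@pytest.mark.parametrize("kind", ["over_segmenter", "under_segmenter", "class_confuser"])
def test_zero_strength_is_identity(kind):
    mask = cs.generate_shapes(1, 32, 32, 2, seed=3)[0].mask
    p = cs.AnnotatorPersona(kind=kind, annotator_id=0, strength=0)
    assert np.array_equal(cs.apply_morpho_annotator(mask, p, seed=0), mask)


def test_dilation_matches_hand_computed_square():
    # 3x3 square dilated by a radius-1 square element grows to 5x5
    mask = np.zeros((9, 9), dtype=int)
    mask[3:6, 3:6] = 1
    p = cs.AnnotatorPersona(kind="over_segmenter", annotator_id=0, strength=1)
    out = cs.apply_morpho_annotator(mask, p, seed=0)
    expected = np.zeros((9, 9), dtype=int)
    expected[2:7, 2:7] = 1
    assert np.array_equal(out, expected)


def test_erosion_can_remove_small_lesions():
    mask = np.zeros((16, 16), dtype=int)
    mask[4:6, 4:6] = 1  # 2x2 lesion vanishes under radius-1 erosion
    p = cs.AnnotatorPersona(kind="under_segmenter", annotator_id=0, strength=1)
    assert cs.apply_morpho_annotator(mask, p, seed=0).sum() == 0


def test_class_confuser_certainty_removes_source_class():
    mask = cs.generate_shapes(1, 32, 32, 3, seed=2)[0].mask
    p = cs.AnnotatorPersona(kind="class_confuser", annotator_id=0, strength=1.0,
                            swap_map={1: 2})
    out = cs.apply_morpho_annotator(mask, p, seed=0, n_classes=3)
    assert not (out == 1).any()
    assert ((mask == 1) <= (out == 2)).all()


@settings(max_examples=20, derandomize=True)
@given(r=st.integers(0, 2), seed=st.integers(0, 10))
def test_closing_contains_original_convex_shape(r, seed):
    # dilation then erosion with equal radius never shrinks a convex shape
    mask = np.zeros((24, 24), dtype=int)
    rng = np.random.default_rng(seed)
    a, b = sorted(rng.integers(6, 18, size=2))
    mask[a : b + 1, a : b + 1] = 1
    over = cs.AnnotatorPersona(kind="over_segmenter", annotator_id=0, strength=r)
    under = cs.AnnotatorPersona(kind="under_segmenter", annotator_id=0, strength=r)
    closed = cs.apply_morpho_annotator(
        cs.apply_morpho_annotator(mask, over, seed=0), under, seed=0
    )
    assert ((mask == 1) <= (closed == 1)).all()


def test_cm_annotator_identity_and_validation():
    mask = cs.generate_shapes(1, 32, 32, 2, seed=4)[0].mask
    assert np.array_equal(cs.apply_cm_annotator(mask, np.eye(2), seed=0), mask)
    with pytest.raises(ValueError):
        cs.apply_cm_annotator(mask, np.array([[0.9, 0.3], [0.2, 0.7]]), seed=0)


def test_cm_annotator_empirical_frequencies_within_3_sigma():
    # all-background mask: P(label 1) = cm[1, 0] = 0.1
    mask = np.zeros((100, 100), dtype=int)
    noisy = cs.apply_cm_annotator(mask, binary_cm(0.9), seed=3)
    n = mask.size
    sigma = np.sqrt(0.1 * 0.9 / n)
    assert abs(noisy.mean() - 0.1) < 3 * sigma
    # uniform cm: frequencies ~ 1/2 each regardless of input
    uniform = np.full((2, 2), 0.5)
    noisy = cs.apply_cm_annotator(mask, uniform, seed=4)
    assert abs(noisy.mean() - 0.5) < 3 * np.sqrt(0.25 / n)


def test_cm_annotator_empirical_full_matrix():
    # per-entry agreement with the specified CM over >= 1e4 pixels per class
    rng = np.random.default_rng(0)
    mask = (rng.random((160, 160)) < 0.5).astype(int)  # ~12800 per class
    cm = np.array([[0.8, 0.3], [0.2, 0.7]])
    noisy = cs.apply_cm_annotator(mask, cm, seed=9)
    for j in range(2):
        sel = mask == j
        n = sel.sum()
        assert n >= 10_000
        for i in range(2):
            phat = (noisy[sel] == i).mean()
            sigma = np.sqrt(cm[i, j] * (1 - cm[i, j]) / n)
            assert abs(phat - cm[i, j]) < 3 * sigma


def test_build_dataset_density_counts_and_determinism():
    gts = cs.generate_shapes(10, 16, 16, 2, seed=0)
    personas = [cs.AnnotatorPersona(kind="cm_corruptor", annotator_id=i, cm=binary_cm(0.9))
                for i in range(3)]
    dense = cs.build_dataset(gts, personas, label_density="dense", seed=1)
    assert sum(len(m) for m in dense.noisy_masks) == 30
    single = cs.build_dataset(gts, personas, label_density="single", seed=1)
    assert sum(len(m) for m in single.noisy_masks) == 10
    assert all(len(s) == 1 for s in single.annotator_sets)
    again = cs.build_dataset(gts, personas, label_density="single", seed=1)
    assert again.annotator_sets == single.annotator_sets
    for m1, m2 in zip(single.noisy_masks, again.noisy_masks):
        for aid in m1:
            assert np.array_equal(m1[aid], m2[aid])


def test_build_dataset_rejects_empty_personas():
    gts = cs.generate_shapes(2, 16, 16, 2, seed=0)
    with pytest.raises(ValueError):
        cs.build_dataset(gts, [], label_density="dense", seed=0)


def test_true_cms_recorded_only_for_cm_corruptors(mixed_personas):
    gts = cs.generate_shapes(4, 16, 16, 2, seed=0)
    ds = cs.build_dataset(gts, mixed_personas, label_density="dense", seed=0)
    assert set(ds.true_cms) == {3, 4}
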