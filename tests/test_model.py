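"""Coupled-model contracts: simplex invariants, CM algebra, cost accounting."""

import numpy as np
import pytest

import crowdseg as cs
from crowdseg.model import finish_cms


def _image(seed=0, shape=(16, 16)):
    return np.random.default_rng(seed).standard_normal(shape)


def test_consensus_is_on_simplex(tiny_model):
    p = tiny_model.forward_consensus(_image())
    assert p.probs.shape == (16, 16, 2)
    assert np.abs(p.probs.sum(-1) - 1).max() < 1e-5
    assert (p.probs >= 0).all()


def test_identical_images_get_identical_outputs(tiny_model):
    batch = np.stack([_image(3), _image(3)])
    probs, _ = tiny_model.forward_tensors(batch)
    assert np.array_equal(probs.data[0], probs.data[1])


def test_annotator_cms_are_column_stochastic(tiny_model):
    cm = tiny_model.forward_annotator_cms(_image(1), 2)
    full = cm.as_full()
    assert full.shape == (16, 16, 2, 2)
    assert np.abs(full.sum(-2) - 1).max() < 1e-5
    assert (full >= 0).all()
    with pytest.raises(ValueError):
        tiny_model.forward_annotator_cms(_image(1), 5)


def test_zeroed_consensus_head_gives_uniform_probabilities(tiny_model):
    model = cs.CoupledModel(tiny_model.config, seed=0)
    model.load_state_arrays(tiny_model.state_arrays())
    model.seg_head.w.data[:] = 0.0
    model.seg_head.b.data[:] = 0.0
    probs = model.forward_consensus(_image(4)).probs
    assert np.allclose(probs, 1.0 / tiny_model.config.n_classes)


def test_warmup_training_keeps_trace_near_maximum():
    """A short trace-maximisation warm-up drives the mean CM trace toward L."""
    personas = [cs.AnnotatorPersona(
        kind="cm_corruptor", annotator_id=0, cm=np.eye(2))]
    gts = cs.generate_shapes(4, 16, 16, 2, seed=0)
    ds = cs.build_dataset(gts, personas, label_density="dense", seed=0)
    model, _ = cs.train(
        ds,
        cs.ModelConfig(n_classes=2, n_annotators=1, encoder_channels=(4,)),
        cs.TrainConfig(epochs=150, batch_size=2, seed=0,
                       warmup_iters=10**6, lambda_=0.4),  # warm-up throughout
    )
    cm = model.forward_annotator_cms(ds.images[0], 0)
    assert cm.trace().mean() > 0.9 * 2


def test_untrained_cms_are_near_identity(tiny_model):
    # diagonal logit offset keeps pre-warm-up CMs diagonally dominant
    cm = tiny_model.forward_annotator_cms(_image(2), 0)
    assert cm.trace().mean() > 0.9 * tiny_model.config.n_classes


def test_global_mode_broadcasts_one_cm_per_annotator():
    cfg = cs.ModelConfig(n_classes=3, n_annotators=2, cm_mode="global",
                         encoder_channels=(4,))
    model = cs.CoupledModel(cfg, seed=0)
    cm = model.forward_annotator_cms(_image(0), 1)
    full = cm.as_full()
    assert np.array_equal(full[0, 0], full[7, 11])
    other = model.forward_annotator_cms(_image(5), 1).as_full()
    assert np.array_equal(full, other)  # input-independent


def test_annotator_distribution_identity_uniform_and_hand_value():
    h = w = 4
    p = np.full((h, w, 2), 0.0)
    p[..., 0], p[..., 1] = 0.7, 0.3
    eye = np.broadcast_to(np.eye(2), (h, w, 2, 2))
    out = cs.annotator_distribution(eye, p)
    assert np.allclose(out.probs, p)
    uni = np.full((h, w, 2, 2), 0.5)
    out = cs.annotator_distribution(uni, p)
    assert np.allclose(out.probs, 0.5)
    cm = np.broadcast_to(np.array([[0.9, 0.2], [0.1, 0.8]]), (h, w, 2, 2))
    out = cs.annotator_distribution(cm, p)
    assert np.allclose(out.probs[..., 0], 0.9 * 0.7 + 0.2 * 0.3)  # 0.69
    assert np.allclose(out.probs[..., 1], 0.1 * 0.7 + 0.8 * 0.3)  # 0.31
    with pytest.raises(ValueError):
        cs.annotator_distribution(np.ones((2, 2, 2, 2)) / 2, p)


def test_annotator_distribution_is_linear_in_p():
    rng = np.random.default_rng(0)
    cm = rng.random((4, 4, 3, 3))
    cm /= cm.sum(axis=-2, keepdims=True)
    p1 = rng.dirichlet(np.ones(3), size=(4, 4))
    p2 = rng.dirichlet(np.ones(3), size=(4, 4))
    alpha = 0.3
    lhs = cs.annotator_distribution(cm, alpha * p1 + (1 - alpha) * p2).probs
    rhs = (alpha * cs.annotator_distribution(cm, p1).probs
           + (1 - alpha) * cs.annotator_distribution(cm, p2).probs)
    assert np.allclose(lhs, rhs, atol=1e-12)


def test_expand_lowrank_rank_and_normalisation():
    rng = np.random.default_rng(1)
    b1 = rng.random((2, 2, 4, 1))
    b2 = rng.random((2, 2, 4, 1))
    raw = np.einsum("...il,...jl->...ij", b1, b2)
    assert np.linalg.matrix_rank(raw[0, 0]) <= 1  # rank bound pre-normalisation
    full = cs.expand_lowrank(b1, b2)
    assert np.abs(full.sum(-2) - 1).max() < 1e-9
    # expanding then applying equals the factored product route
    p = rng.dirichlet(np.ones(4), size=(2, 2))
    direct = np.einsum("...il,...l->...i", b1,
                       np.einsum("...jl,...j->...l", b2, p / raw.sum(-2)))
    assert np.allclose(cs.annotator_distribution(full, p).probs, direct)
    with pytest.raises(ValueError):
        cs.expand_lowrank(rng.random((2, 2, 4, 4)), rng.random((2, 2, 4, 4)))


def test_factored_model_emits_stochastic_cms():
    cfg = cs.ModelConfig(n_classes=4, n_annotators=2, rank=1,
                         encoder_channels=(4,))
    model = cs.CoupledModel(cfg, seed=0)
    cm = model.forward_annotator_cms(_image(0), 0)
    full = cm.as_full()
    assert full.shape == (16, 16, 4, 4)
    assert np.abs(full.sum(-2) - 1).max() < 1e-5
    assert (full >= 0).all()


@pytest.mark.parametrize("w,h,L,rank,expected", [
    (192, 192, 4, "full", (589_824, 1_032_192)),
    (192, 192, 4, 1, (294_912, 405_504)),
    (1, 1, 2, "full", (4, 6)),
])
def test_cm_cost_formulas(w, h, L, rank, expected):
    assert cs.cm_cost(w, h, L, rank) == expected


def test_lowrank_cost_strictly_below_full_for_small_rank():
    for L in (4, 8, 16):
        full = cs.cm_cost(64, 64, L, "full")
        for l in range(1, L // 2):
            fac = cs.cm_cost(64, 64, L, l)
            assert fac[0] < full[0] and fac[1] < full[1]


def test_cm_cost_rejects_rank_without_saving():
    with pytest.raises(ValueError):
        cs.cm_cost(8, 8, 4, 4)


def test_two_stage_freeze_and_state_roundtrip(tiny_model):
    arrays = tiny_model.state_arrays()
    clone = cs.CoupledModel(tiny_model.config, seed=99)
    clone.load_state_arrays(arrays)
    img = _image(7)
    assert np.array_equal(clone.forward_consensus(img).probs,
                          tiny_model.forward_consensus(img).probs)


def test_dominant_normalisation_keeps_diagonal_largest_in_column():
    cfg = cs.ModelConfig(n_classes=3, n_annotators=1, encoder_channels=(4,))
    model = cs.CoupledModel(cfg, seed=1)
    _, raw = model.forward_tensors(_image(3))
    full = finish_cms(raw, cfg).data[0, :, :, 0]
    diag = np.diagonal(full, axis1=-2, axis2=-1)  # (H, W, L) per column j
    assert (full <= diag[:, :, None, :] + 1e-12).all()
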