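"""Loss closed forms, masking, warm-up sign, and trace identifiability."""

import numpy as np
import pytest

import crowdseg as cs
from crowdseg.autodiff import Tensor
from crowdseg.losses import combined_loss


def test_noisy_ce_closed_forms():
    mask = np.array([[0, 1], [1, 0]])
    onehot = np.eye(2)[mask]
    assert cs.noisy_ce(onehot, mask) == pytest.approx(0.0, abs=1e-9)
    uniform = np.full((2, 2, 2), 0.5)
    assert cs.noisy_ce(uniform, mask) == pytest.approx(np.log(2))
    assert cs.noisy_ce(uniform, mask, present=0.0) == 0.0
    with pytest.raises(ValueError):
        cs.noisy_ce(uniform, np.array([[0, 2], [1, 0]]))


def test_trace_penalty_closed_forms():
    eye = np.broadcast_to(np.eye(2), (3, 3, 2, 2))
    assert cs.trace_penalty(eye) == pytest.approx(2.0)
    uniform = np.full((3, 3, 2, 2), 0.5)
    assert cs.trace_penalty(uniform) == pytest.approx(1.0)
    cm = np.broadcast_to(np.array([[0.9, 0.2], [0.1, 0.8]]), (4, 4, 2, 2))
    assert cs.trace_penalty(cm) == pytest.approx(1.7)
    spatial = cs.SpatialCM(annotator_id=0, full=np.ascontiguousarray(cm))
    assert cs.trace_penalty(spatial) == pytest.approx(1.7)


class _StubModel:
    """Fixed-output model: one-hot consensus, identity CMs."""

    def __init__(self, labels, L=2, R=1):
        self.config = cs.ModelConfig(n_classes=L, n_annotators=R,
                                     encoder_channels=(4,),
                                     cm_normalization="softmax")
        self._labels = labels

    def forward_tensors(self, images):
        n, h, w = self._labels.shape
        L, R = self.config.n_classes, self.config.n_annotators
        probs = Tensor(np.eye(L)[self._labels])
        cms = Tensor(np.broadcast_to(np.eye(L), (n, h, w, R, L, L)).copy())
        return probs, cms


def _batch(labels, R=1):
    n, h, w = labels.shape
    return {
        "images": np.zeros((n, h, w)),
        "labels": np.repeat(labels[:, None], R, axis=1),
        "present": np.ones((n, R)),
    }


def test_combined_loss_closed_form_and_lambda_linearity():
    labels = np.array([[[0, 1], [1, 0]]])
    model = _StubModel(labels)
    # perfect one-hot fit + identity CMs: CE = 0, so loss = lambda * L
    cfg = cs.LossConfig(lambda_=0.01, warmup_iters=0)
    loss = combined_loss(_batch(labels), model, cfg, step=10)
    assert float(loss.data) == pytest.approx(0.01 * 2, abs=1e-9)
    zero = combined_loss(_batch(labels), model, cs.LossConfig(lambda_=0.0), step=10)
    assert float(zero.data) == pytest.approx(0.0, abs=1e-9)
    double = combined_loss(_batch(labels), model, cs.LossConfig(lambda_=0.02, warmup_iters=0), step=10)
    assert float(double.data) - float(zero.data) == pytest.approx(
        2 * (float(loss.data) - float(zero.data)))


def test_warmup_flips_trace_sign():
    labels = np.array([[[0, 1], [1, 0]]])
    model = _StubModel(labels)
    cfg = cs.LossConfig(lambda_=0.01, warmup_iters=100)
    warm = combined_loss(_batch(labels), model, cfg, step=0)
    post = combined_loss(_batch(labels), model, cfg, step=100)
    assert float(warm.data) == pytest.approx(-0.02, abs=1e-9)
    assert float(post.data) == pytest.approx(0.02, abs=1e-9)


def test_absent_annotator_receives_zero_gradient():
    cfg = cs.ModelConfig(n_classes=2, n_annotators=2, cm_mode="global",
                         encoder_channels=(4,))
    model = cs.CoupledModel(cfg, seed=0)
    rng = np.random.default_rng(0)
    batch = {
        "images": rng.standard_normal((2, 8, 8)),
        "labels": rng.integers(0, 2, size=(2, 2, 8, 8)),
        "present": np.array([[1.0, 0.0], [1.0, 0.0]]),  # annotator 1 absent
    }
    loss = combined_loss(batch, model, cs.LossConfig(lambda_=0.01, warmup_iters=0), step=5)
    loss.backward()
    g = model.global_logits.grad
    assert g is not None
    assert np.abs(g[1]).max() == 0.0  # absent annotator's CM parameters untouched
    assert np.abs(g[0]).max() > 0.0


def test_loss_decreases_on_toy_problem():
    # ~200 foreground/background pixels, 200 optimiser steps halve the loss
    personas = [cs.AnnotatorPersona(kind="cm_corruptor", annotator_id=0,
                                    cm=np.array([[0.9, 0.1], [0.1, 0.9]]))]
    gts = cs.generate_shapes(4, 16, 16, 2, seed=0)
    ds = cs.build_dataset(gts, personas, label_density="dense", seed=0)
    model, hist = cs.train(
        ds,
        cs.ModelConfig(n_classes=2, n_annotators=1, encoder_channels=(4, 8)),
        cs.TrainConfig(epochs=200, batch_size=4, seed=0, warmup_iters=5, lambda_=0.01),
    )
    assert len(hist["loss"]) == 200 * 1
    assert hist["loss"][-1] < 0.5 * hist["loss"][0]


@pytest.mark.parametrize("k", [0, 1])
def test_trace_minimisation_recovers_correct_class_column(k):
    """Single-pixel binary identifiability: the minimum-trace solution that
    reproduces the observed noisy distributions matches the true CMs in the
    correct-class column, up to the grid resolution."""
    A1 = np.array([[0.9, 0.2], [0.1, 0.8]])
    A2 = np.array([[0.7, 0.1], [0.3, 0.9]])
    res = cs.min_trace_feasible_cms([A1, A2], true_class=k, grid=21)
    assert res["n_feasible"] > 0
    assert res["max_col_error"] <= res["grid_step"] + 1e-9


def test_trace_oracle_rejects_non_binary():
    with pytest.raises(ValueError):
        cs.min_trace_feasible_cms([np.eye(3)], true_class=0)
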