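"""Optimisation loops and inference for the coupled model.

``train`` minimises the combined noisy-CE + trace objective with Adam over
mini-batches, either jointly over both networks (default) or in two
successive stages — (a) the full objective over all parameters, then (b)
the segmentation network alone with the annotator head frozen, so the
consensus is refined against the fixed product of annotator experts.
``predict`` uses only the segmentation head: the consensus label map is the
per-pixel argmax of the class probabilities (ties resolve to the lowest
class index), independent of which annotators labelled the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Adam
from .losses import LossConfig, combined_loss
from .model import ConsensusProbMap, CoupledModel, ModelConfig
from .synth import AnnotatedDataset

__all__ = ["TrainConfig", "train", "predict", "estimate_mean_cms", "make_batches"]


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    mode: str = "joint"  # "joint" | "two_stage"
    warmup_iters: int = 500
    lambda_: float = 0.01

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.mode not in ("joint", "two_stage"):
            raise ValueError("mode must be 'joint' or 'two_stage'")


def _dataset_arrays(dataset: AnnotatedDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[int, int]]:
    """Stack a dataset into (images, labels, present) training arrays.

    Annotator ids are mapped to contiguous indices 0..R-1 (sorted order);
    absent annotators get an all-zero label plane and presence 0.
    """
    ids = dataset.annotator_ids
    index = {aid: i for i, aid in enumerate(ids)}
    n = len(dataset)
    h, w = dataset.images[0].shape[:2]
    images = np.stack([np.asarray(im, float) for im in dataset.images])
    labels = np.zeros((n, len(ids), h, w), dtype=np.int64)
    present = np.zeros((n, len(ids)))
    for i, masks in enumerate(dataset.noisy_masks):
        for aid, mask in masks.items():
            labels[i, index[aid]] = mask
            present[i, index[aid]] = 1.0
    return images, labels, present, index


def make_batches(n: int, batch_size: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]


def train(dataset: AnnotatedDataset, model_cfg: ModelConfig,
          train_cfg: TrainConfig) -> tuple[CoupledModel, dict]:
    """Fit the coupled model on a noisily annotated dataset.

    Returns the trained model and a history dict with the per-step and
    per-epoch losses.  Deterministic given ``train_cfg.seed`` (weight
    init and shuffling both derive from it).
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    images, labels, present, index = _dataset_arrays(dataset)
    if model_cfg.n_annotators != len(index):
        raise ValueError(
            f"model configured for {model_cfg.n_annotators} annotators, "
            f"dataset has {len(index)}"
        )
    model = CoupledModel(model_cfg, seed=train_cfg.seed)
    model.annotator_index = index
    loss_cfg = LossConfig(lambda_=train_cfg.lambda_, warmup_iters=train_cfg.warmup_iters)
    rng = np.random.default_rng(train_cfg.seed + 1)
    history: dict = {"loss": [], "epoch_loss": [], "stage": []}

    def run_stage(params, epochs, step0):
        opt = Adam(params, lr=train_cfg.learning_rate)
        step = step0
        for _ in range(epochs):
            epoch_losses = []
            for idx in make_batches(len(dataset), train_cfg.batch_size, rng):
                batch = {
                    "images": images[idx],
                    "labels": labels[idx],
                    "present": present[idx],
                }
                loss = combined_loss(batch, model, loss_cfg, step=step)
                opt.zero_grad()
                loss.backward()
                opt.step()
                history["loss"].append(float(loss.data))
                epoch_losses.append(float(loss.data))
                step += 1
            history["epoch_loss"].append(float(np.mean(epoch_losses)))
        return step

    if train_cfg.mode == "joint":
        run_stage(model.parameters(), train_cfg.epochs, 0)
        history["stage"] = ["joint"] * train_cfg.epochs
    else:
        stage_a = max(1, train_cfg.epochs // 2)
        stage_b = max(1, train_cfg.epochs - stage_a)
        step = run_stage(model.parameters(), stage_a, 0)
        # stage (b): annotator head frozen, only segmentation params update
        run_stage(model.backbone_parameters() + model.seg_parameters(), stage_b, step)
        history["stage"] = ["annotator"] * stage_a + ["segmentation"] * stage_b
    return model, history


def predict(model: CoupledModel, image: np.ndarray) -> tuple[np.ndarray, ConsensusProbMap]:
    """Consensus label map and probabilities for one image.

    Only the segmentation network is used; np.argmax resolves exact ties to
    the lowest class index.
    """
    probs = model.forward_consensus(image)
    return probs.argmax(), probs


def estimate_mean_cms(model: CoupledModel, images: list[np.ndarray],
                      weights: str = "consensus") -> dict[int, np.ndarray]:
    """Image- and pixel-averaged estimated CM per annotator.

    ``weights="consensus"`` (default) averages each CM column j with weight
    equal to the consensus probability of class j at that pixel: a column
    describes behaviour *given* true class j, and pixels where class j is
    absent carry no information about it (only the correct-class column is
    identifiable).  ``weights="uniform"`` averages plainly over all pixels.
    Returns {annotator_id: (L, L)} using the model's annotator index when
    one was attached during training.
    """
    from .model import finish_cms

    if weights not in ("consensus", "uniform"):
        raise ValueError("weights must be 'consensus' or 'uniform'")
    index = getattr(model, "annotator_index", None) or {
        r: r for r in range(model.config.n_annotators)
    }
    L = model.config.n_classes
    num = {aid: np.zeros((L, L)) for aid in index}
    den = {aid: np.zeros((1, L)) for aid in index}
    for image in images:
        probs, raw = model.forward_tensors(np.asarray(image))
        full = finish_cms(raw, model.config).data
        p = probs.data[0]  # (H, W, L)
        w = p if weights == "consensus" else np.ones_like(p)
        for aid, r in index.items():
            A = full[r] if full.ndim == 3 else full[0, :, :, r]
            if A.ndim == 2:  # global: constant over pixels
                num[aid] += A * w.sum(axis=(0, 1))
            else:
                num[aid] += np.einsum("hwij,hwj->ij", A, w)
            den[aid] += w.sum(axis=(0, 1))
    return {aid: num[aid] / den[aid] for aid in index}
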