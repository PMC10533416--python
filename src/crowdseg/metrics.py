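"""Evaluation metrics: Dice, CM errors, generalized energy distance.

* ``dice_class`` — per-class Dice 2|A_c & B_c| / (|A_c| + |B_c|); soft
  probability maps are argmax-thresholded first by default (a ``soft`` flag
  computes the soft overlap instead); both-empty is defined as 1.
* ``total_dice`` — whole-image Dice treating all classes jointly, which for
  hard single-label maps reduces to pixel accuracy.
* ``cm_rmse`` / ``cm_incompetence`` — root-mean-square and mean-absolute
  elementwise error between estimated and true per-pixel CMs, averaged over
  annotators, pixels and matrix entries (background pixels included).  True
  CMs exist only for pixelwise-independent simulated corruption; when truth
  is unavailable both return ``None`` (explicitly undefined, never 0).
* ``generalized_energy_distance`` — squared GED
  2 E[d(S,Y)] - E[d(S,S')] - E[d(Y,Y')] between model samples and annotator
  labels with kernel d = 1 - total Dice; expectations are means over all
  ordered pairs (self-pairs included).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .model import SpatialCM

__all__ = [
    "MetricReport",
    "dice_class",
    "average_dice",
    "total_dice",
    "cm_rmse",
    "cm_incompetence",
    "generalized_energy_distance",
]


def _harden(pred: np.ndarray) -> np.ndarray:
    pred = np.asarray(pred)
    return pred.argmax(axis=-1) if pred.ndim == 3 and np.issubdtype(
        pred.dtype, np.floating) else pred


def dice_class(pred: np.ndarray, truth: np.ndarray, c: int,
               n_classes: int | None = None, soft: bool = False) -> float:
    """Dice coefficient for class ``c``; empty-vs-empty is 1.

    ``n_classes`` bounds the valid class range; when omitted it is inferred
    from the inputs (and a class absent from both maps scores 1).
    """
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if n_classes is None:
        n_classes = int(truth.max()) + 1
        if pred.ndim == 3 and np.issubdtype(pred.dtype, np.floating):
            n_classes = max(n_classes, pred.shape[-1])
        else:
            n_classes = max(n_classes, int(pred.max()) + 1, c + 1)
    if not 0 <= c < n_classes:
        raise ValueError(f"unknown class {c}")
    t = (truth == c).astype(float)
    if soft and pred.ndim == 3:
        p = pred[..., c]
    else:
        p = (_harden(pred) == c).astype(float)
    if p.shape != t.shape:
        raise ValueError("shape mismatch between pred and truth")
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (p * t).sum() / denom)


def average_dice(pred: np.ndarray, truth: np.ndarray, n_classes: int,
                 include_background: bool = False) -> float:
    """Mean of the per-class Dice values (foreground classes by default)."""
    start = 0 if include_background else 1
    return float(np.mean([dice_class(pred, truth, c, n_classes=n_classes)
                          for c in range(start, n_classes)]))


def total_dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Whole-image overlap Dice; for hard maps this equals pixel accuracy."""
    p = _harden(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("shape mismatch between pred and truth")
    return float(2.0 * (p == t).sum() / (p.size + t.size))


def _cm_arrays(cms) -> dict[int, np.ndarray]:
    """Normalise CM input to {annotator_id: array} with (..., L, L) arrays."""
    if cms is None:
        return {}
    if isinstance(cms, dict):
        out = {}
        for k, v in cms.items():
            out[k] = v.as_full() if isinstance(v, SpatialCM) else np.asarray(v, float)
        return out
    if isinstance(cms, SpatialCM):
        return {cms.annotator_id: cms.as_full()}
    raise TypeError("expected a dict of CM arrays or a SpatialCM")


def _paired_errors(est, true):
    est, true = _cm_arrays(est), _cm_arrays(true)
    if not true or not est:
        return None
    if set(est) != set(true):
        raise ValueError("estimated and true CMs cover different annotators")
    diffs = []
    for aid in est:
        e, t = est[aid], true[aid]
        e, t = np.broadcast_arrays(e, t)  # (L,L) truth broadcasts over pixels
        diffs.append((e - t).ravel())
    return np.concatenate(diffs)


def cm_rmse(est, true) -> float | None:
    """Root mean squared elementwise CM error; None when truth is undefined."""
    d = _paired_errors(est, true)
    return None if d is None else float(np.sqrt(np.mean(d**2)))


def cm_incompetence(est, true) -> float | None:
    """Mean absolute elementwise CM error; None when truth is undefined."""
    d = _paired_errors(est, true)
    return None if d is None else float(np.mean(np.abs(d)))


def generalized_energy_distance(model_samples, annotator_labels, d=None) -> float:
    """Squared generalized energy distance between two sets of label maps.

    ``d`` defaults to 1 - total Dice.  Means run over all ordered pairs,
    including self-pairs, so two singleton sets {A}, {B} give 2*d(A, B).
    """
    if d is None:
        d = lambda a, b: 1.0 - total_dice(a, b)
    S = [np.asarray(s) for s in model_samples]
    Y = [np.asarray(y) for y in annotator_labels]
    if not S or not Y:
        raise ValueError("both sets must be non-empty")
    cross = np.mean([d(s, y) for s in S for y in Y])
    within_s = np.mean([d(a, b) for a in S for b in S])
    within_y = np.mean([d(a, b) for a in Y for b in Y])
    return float(2.0 * cross - within_s - within_y)


@dataclass
class MetricReport:
    """One evaluation row: Dice family, CM errors, GED."""

    dice_per_class: dict[int, float]
    average_dice: float
    total_dice: float
    cm_rmse: float | None = None
    cm_incompetence: float | None = None
    ged: float | None = None

    def to_dict(self) -> dict:
        out = asdict(self)
        out["dice_per_class"] = {str(k): v for k, v in self.dice_per_class.items()}
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def flat(self) -> dict:
        """Flattened scalar columns for tabular output (None -> NA later)."""
        row = {f"dice_class_{c}": v for c, v in self.dice_per_class.items()}
        row.update(average_dice=self.average_dice, total_dice=self.total_dice,
                   cm_rmse=self.cm_rmse, cm_incompetence=self.cm_incompetence,
                   ged=self.ged)
        return row


def evaluate_segmentation(pred, truth, n_classes: int,
                          est_cms=None, true_cms=None,
                          model_samples=None, annotator_labels=None) -> MetricReport:
    """Assemble a MetricReport for one prediction (CM/GED parts optional)."""
    per_class = {c: dice_class(pred, truth, c, n_classes=n_classes)
                 for c in range(n_classes)}
    fg = [per_class[c] for c in range(1, n_classes)]
    ged = None
    if model_samples is not None and annotator_labels is not None:
        ged = generalized_energy_distance(model_samples, annotator_labels)
    return MetricReport(
        dice_per_class=per_class,
        average_dice=float(np.mean(fg)) if fg else per_class[0],
        total_dice=total_dice(pred, truth),
        cm_rmse=cm_rmse(est_cms, true_cms),
        cm_incompetence=cm_incompetence(est_cms, true_cms),
        ged=ged,
    )
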