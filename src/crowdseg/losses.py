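"""Noisy-label cross-entropy with trace regularisation.

The training objective sums, over images n and annotators r, the indicator
I(annotator r labelled image n) times

    CE(A^(r)(x_n) p(x_n), noisy_mask_n^(r))  +  lambda * tr(A^(r)(x_n)),

i.e. cross-entropy between each annotator's estimated label distribution and
their observed noisy mask, plus the mean per-pixel trace of the estimated
confusion matrices.  Minimising the CE ties the product A p to the observed
noisy label distributions; minimising the trace pushes the fitted annotators
to be as unreliable as is consistent with the data, which (for diagonally
dominant mean CMs) disentangles annotation noise from the consensus.  During
a warm-up period the sign of the trace term is flipped so the annotator
network first *maximises* the trace, keeping the CMs near identity and hence
diagonally dominant.

Pixel reduction is a mean (not a sum) so lambda is image-size invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .model import AnnotatorProbMap, CoupledModel, SpatialCM, finish_cms

__all__ = [
    "LossConfig",
    "noisy_ce",
    "trace_penalty",
    "combined_loss",
    "min_trace_feasible_cms",
]

_PROB_FLOOR = 1e-12


@dataclass
class LossConfig:
    lambda_: float = 0.01
    warmup_iters: int = 500

    def __post_init__(self):
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")

    def trace_sign(self, step: int) -> float:
        """-1 during warm-up (maximise trace), +1 afterwards."""
        return -1.0 if step < self.warmup_iters else 1.0


def _probs_of(x) -> Tensor | np.ndarray:
    if isinstance(x, AnnotatorProbMap):
        return x.probs
    return x


def noisy_ce(annot_dist, noisy_mask: np.ndarray, present: float = 1.0):
    """Mean over pixels of -log annot_dist[pixel, observed label].

    ``present`` is the indicator I(annotator labelled this image); an absent
    annotator contributes exactly 0.  Accepts a NumPy array (returns float)
    or an autodiff Tensor (returns a Tensor) of shape (..., L).
    """
    probs = _probs_of(annot_dist)
    mask = np.asarray(noisy_mask)
    data = probs.data if isinstance(probs, Tensor) else np.asarray(probs)
    L = data.shape[-1]
    if mask.min() < 0 or mask.max() >= L:
        raise ValueError(f"labels must lie in [0, {L - 1}]")
    if float(present) == 0.0:
        return Tensor(0.0) if isinstance(probs, Tensor) else 0.0
    onehot = np.eye(L)[mask]
    if isinstance(probs, Tensor):
        logp = probs.clip_min(_PROB_FLOOR).log()
        return (logp * Tensor(onehot)).sum(axis=-1).mean() * (-float(present))
    logp = np.log(np.maximum(data, _PROB_FLOOR))
    return float(-(onehot * logp).sum(axis=-1).mean() * float(present))


def trace_penalty(cm):
    """Mean over pixels of the per-pixel CM trace.

    Accepts a SpatialCM, a NumPy array or a Tensor of shape (..., L, L).
    """
    if isinstance(cm, SpatialCM):
        return float(cm.trace().mean())
    if isinstance(cm, Tensor):
        L = cm.data.shape[-1]
        eye = Tensor(np.eye(L))
        return (cm * eye).sum(axis=(-2, -1)).mean()
    cm = np.asarray(cm, float)
    return float(np.trace(cm, axis1=-2, axis2=-1).mean())


def combined_loss(batch: dict, model: CoupledModel, config: LossConfig,
                  step: int = 10**9) -> Tensor:
    """Differentiable total loss on one mini-batch.

    ``batch`` holds ``images`` (N,H,W[,C]), integer ``labels`` (N,R,H,W)
    and ``present`` (N,R) in {0,1}.  Per sample the loss sums over present
    annotators the pixel-mean noisy CE plus ``lambda`` times the pixel-mean
    CM trace (sign flipped while ``step < warmup_iters``), then averages
    over the batch.
    """
    images, labels, present = batch["images"], batch["labels"], batch["present"]
    labels = np.asarray(labels)
    present = np.asarray(present, float)
    n, R = present.shape
    L = model.config.n_classes
    if labels.min() < 0 or labels.max() >= L:
        raise ValueError(f"labels must lie in [0, {L - 1}]")
    probs, raw_cms = model.forward_tensors(images)
    cms = finish_cms(raw_cms, model.config)
    h, w = probs.data.shape[1], probs.data.shape[2]
    p5 = probs.reshape(n, h, w, 1, L, 1)
    # matmul broadcasts both the full (N,H,W,R,L,L) and global (R,L,L) cases
    dists = (cms @ p5).reshape(n, h, w, R, L)
    logp = dists.clip_min(_PROB_FLOOR).log()
    onehot = np.zeros((n, h, w, R, L))
    for r in range(R):
        onehot[np.arange(n)[:, None, None],
               np.arange(h)[None, :, None],
               np.arange(w)[None, None, :], r, labels[:, r]] = 1.0
    ce = -(logp * Tensor(onehot)).sum(axis=-1).mean(axis=(1, 2))  # (N,R)
    eye = Tensor(np.eye(L))
    if cms.data.ndim == 3:  # global mode: (R,L,L)
        traces = (cms * eye).sum(axis=(-2, -1))  # (R,)
    else:
        traces = (cms * eye).sum(axis=(-2, -1)).mean(axis=(1, 2))  # (N,R)
    sign = config.trace_sign(step)
    per = (ce + traces * (sign * config.lambda_)) * Tensor(present)
    return per.sum(axis=-1).mean()


# ---------------------------------------------------------------------------
# trace-minimisation identifiability check (binary, single-pixel)
# ---------------------------------------------------------------------------


def min_trace_feasible_cms(true_cms: list[np.ndarray], true_class: int,
                           grid: int = 21, tol: float | None = None) -> dict:
    """Grid-search the trace-minimisation recovery claim on one binary pixel.

    For a single pixel with one-hot truth e_k and R annotators with known
    2x2 column-stochastic CMs whose average is diagonally dominant, the
    observed noisy label distribution of annotator r is column k of its CM.
    This enumerates all grid combinations of estimated diagonals
    (d0_r, d1_r) per annotator and consensus q = p(class 0), keeps those
    that (a) reproduce every observed noisy distribution within ``tol`` and
    (b) have a diagonally dominant mean estimated CM, and returns the
    minimum-mean-trace solutions.  Under the identifiability result the kth
    column of every annotator's CM is unique at the minimum, so
    ``max_col_error`` should be at most the grid resolution.

    Dominance is taken within columns (diagonal entry of each column exceeds
    the off-diagonal entries of that column): for column-stochastic CMs this
    says each true class is most often reported as itself, and it is what
    excludes label-permuted solutions.
    """
    true_cms = [np.asarray(a, float) for a in true_cms]
    if any(a.shape != (2, 2) for a in true_cms):
        raise ValueError("binary (2x2) CMs only")
    k = int(true_class)
    R = len(true_cms)
    step = 1.0 / (grid - 1)
    if tol is None:
        tol = 1e-9  # feasibility = exact match on the grid
    observed = [a[:, k] for a in true_cms]  # noisy dist = column k of true CM
    axes = [np.linspace(0.0, 1.0, grid)] * (2 * R + 1)
    mesh = np.meshgrid(*axes, indexing="ij")
    flat = [m.ravel() for m in mesh]
    q = flat[-1]
    d0 = flat[0:2 * R:2]
    d1 = flat[1:2 * R:2]
    feasible = np.ones_like(q, dtype=bool)
    for r in range(R):
        pred0 = d0[r] * q + (1.0 - d1[r]) * (1.0 - q)
        feasible &= np.abs(pred0 - observed[r][0]) <= tol
    mean_d0 = sum(d0) / R
    mean_d1 = sum(d1) / R
    # column dominance of the mean estimate: d_jj > (1 - d_jj) per column
    feasible &= (mean_d0 > 0.5) & (mean_d1 > 0.5)
    if not feasible.any():
        raise RuntimeError("no feasible grid point; refine the grid")
    trace = (mean_d0 + mean_d1)[feasible]
    idx = np.flatnonzero(feasible)
    winners = idx[np.abs(trace - trace.min()) < 1e-9]
    max_err = 0.0
    for w in winners:
        for r in range(R):
            col = np.array([d0[r][w], 1.0 - d0[r][w]]) if k == 0 else \
                np.array([1.0 - d1[r][w], d1[r][w]])
            max_err = max(max_err, float(np.abs(col - true_cms[r][:, k]).max()))
    return {
        "max_col_error": max_err,
        "grid_step": step,
        "n_feasible": int(feasible.sum()),
        "n_minima": int(len(winners)),
        "min_mean_trace": float(trace.min()),
    }
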