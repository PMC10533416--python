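"""Classical label-fusion baselines: mean, majority vote, and STAPLE.

STAPLE (Simultaneous Truth and Performance Level Estimation) alternates
between (E) a per-pixel posterior over the true class proportional to the
prior times the product of each annotator's CM likelihoods, and (M)
re-estimating one global LxL column-stochastic CM per annotator from the
posterior-weighted label counts.  The observed-data log-likelihood is
non-decreasing across iterations (standard EM monotonicity).

Ties in all hard outputs resolve to the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

__all__ = ["StapleState", "mean_fusion", "majority_vote", "staple_em", "staple_estep"]

_LOG_FLOOR = 1e-12


@dataclass
class StapleState:
    """Converged EM state: consensus posterior, CMs, prior, diagnostics."""

    consensus_probs: np.ndarray  # (H, W, L)
    cms: np.ndarray  # (R, L, L), column-stochastic
    prior: np.ndarray  # (L,)
    n_iter: int
    log_likelihoods: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def consensus_labels(self) -> np.ndarray:
        return self.consensus_probs.argmax(axis=-1)


def _stack_masks(noisy_masks, n_classes: int | None) -> tuple[np.ndarray, int]:
    if isinstance(noisy_masks, dict):
        noisy_masks = [noisy_masks[k] for k in sorted(noisy_masks)]
    masks = np.stack([np.asarray(m) for m in noisy_masks])
    if masks.ndim != 3:
        raise ValueError("expected a stack of 2D label maps with equal shapes")
    L = int(masks.max()) + 1 if n_classes is None else int(n_classes)
    if masks.min() < 0 or masks.max() >= L:
        raise ValueError(f"labels must lie in [0, {L - 1}]")
    return masks, L


def mean_fusion(noisy_masks, n_classes: int | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel average of one-hot annotations.

    Returns ``(soft, hard)`` where soft has shape (H, W, L) and hard is its
    argmax with ties going to the lowest class.
    """
    masks, L = _stack_masks(noisy_masks, n_classes)
    soft = np.eye(L)[masks].mean(axis=0)
    return soft, soft.argmax(axis=-1)


def majority_vote(noisy_masks, n_classes: int | None = None) -> np.ndarray:
    """Per-pixel mode of the annotations (= argmax of the mean one-hots)."""
    return mean_fusion(noisy_masks, n_classes)[1]


def _estep(flat: np.ndarray, cms: np.ndarray, log_prior: np.ndarray
           ) -> tuple[np.ndarray, float]:
    """Posterior over the true class per pixel and the data log-likelihood."""
    R = flat.shape[0]
    log_cms = np.log(np.maximum(cms, _LOG_FLOOR))
    ll = log_prior[None, :] + sum(log_cms[r, flat[r], :] for r in range(R))  # (P, L)
    norm = logsumexp(ll, axis=1)
    return np.exp(ll - norm[:, None]), float(norm.sum())


def staple_estep(noisy_masks, cms: np.ndarray, prior: np.ndarray,
                 n_classes: int | None = None) -> np.ndarray:
    """One STAPLE E-step: per-pixel posterior prop. to prior * prod_r CM likelihoods."""
    masks, L = _stack_masks(noisy_masks, n_classes)
    flat = masks.reshape(masks.shape[0], -1)
    post, _ = _estep(flat, np.asarray(cms, float),
                     np.log(np.maximum(np.asarray(prior, float), _LOG_FLOOR)))
    return post.reshape(masks.shape[1], masks.shape[2], L)


def staple_em(noisy_masks, prior: np.ndarray | None = None,
              n_classes: int | None = None, tol: float = 1e-6,
              max_iter: int = 100, init_diag: float = 0.8) -> StapleState:
    """Classic STAPLE with one global CM per annotator.

    ``prior`` is a fixed class-frequency vector on the simplex (defaults to
    the empirical label frequency over all annotations).  CMs start at
    diagonal ``init_diag`` with the rest spread uniformly off-diagonal; EM
    stops when the largest absolute CM change drops below ``tol`` or after
    ``max_iter`` iterations.  True classes that receive no posterior mass
    get a uniform CM column.
    """
    masks, L = _stack_masks(noisy_masks, n_classes)
    R = masks.shape[0]
    flat = masks.reshape(R, -1)  # (R, P)
    if prior is None:
        prior = np.bincount(flat.ravel(), minlength=L) / flat.size
    prior = np.asarray(prior, float)
    if prior.shape != (L,) or abs(prior.sum() - 1.0) > 1e-6 or (prior < 0).any():
        raise ValueError("prior must be a length-L simplex vector")
    off = (1.0 - init_diag) / (L - 1) if L > 1 else 0.0
    cms = np.full((R, L, L), off)
    cms[:, np.arange(L), np.arange(L)] = init_diag
    log_prior = np.log(np.maximum(prior, _LOG_FLOOR))
    logliks: list[float] = []
    converged = False
    n_iter = 0
    onehots = np.eye(L)[flat]  # (R, P, L) observed one-hots
    for n_iter in range(1, max_iter + 1):
        post, loglik = _estep(flat, cms, log_prior)
        logliks.append(loglik)
        # M-step: CM columns from posterior-weighted counts
        counts = np.einsum("rpi,pj->rij", onehots, post)  # (R, L, L)
        col_tot = counts.sum(axis=1, keepdims=True)
        # a true class with (essentially) no posterior mass gets a uniform column
        new_cms = np.where(col_tot > 1e-6,
                           counts / np.maximum(col_tot, _LOG_FLOOR), 1.0 / L)
        delta = np.abs(new_cms - cms).max()
        cms = new_cms
        if delta < tol:
            converged = True
            break
    # final E-step with converged CMs
    post, loglik = _estep(flat, cms, log_prior)
    logliks.append(loglik)
    return StapleState(
        consensus_probs=post.reshape(masks.shape[1], masks.shape[2], L),
        cms=cms,
        prior=prior,
        n_iter=n_iter,
        log_likelihoods=logliks,
        converged=converged,
    )
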