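"""Coupled segmentation + annotator-confusion networks.

One shared U-Net encoder-decoder backbone feeds two sibling output heads:

* a **consensus head** with L channels whose per-pixel softmax estimates the
  (unobserved) expert consensus label probabilities p(y | x), and
* an **annotator head** that, for each of R annotators, emits a per-pixel
  LxL confusion matrix A^(r)(x) whose (i, j) entry models the probability of
  the annotator reporting class i when the true class is j.  Columns are
  made stochastic with a softmax along the observed-label axis.  A rank-l
  factorisation (A = B1 B2^T with nonnegative W x H x L x l factors) and a
  "global" ablation (one input-independent LxL matrix per annotator) are
  also available.

The estimated distribution of annotator r's labels is the per-pixel
matrix-vector product A^(r)(x) p(x); at inference only the consensus head is
used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "ModelConfig",
    "ConsensusProbMap",
    "SpatialCM",
    "AnnotatorProbMap",
    "CoupledModel",
    "annotator_distribution",
    "expand_lowrank",
    "cm_cost",
]

_EPS = 1e-12


@dataclass
class ModelConfig:
    n_classes: int
    n_annotators: int
    in_channels: int = 1
    rank: int | str = "full"  # "full" or an integer l < n_classes
    cm_mode: str = "spatial"  # "spatial" | "global"
    encoder_channels: tuple[int, ...] = (32, 64, 128, 256)
    norm: str = "instance"
    diag_bias: float = 2.0  # identity-logit offset so initial CMs are near-identity
    # "dominant": project each CM column onto the diagonally dominant set,
    # A[:, j] = (softmax(z)[:, j] + e_j) / 2, the hypothesis class in which
    # trace minimisation provably recovers the correct-class column.
    # "softmax": plain column softmax.
    cm_normalization: str = "dominant"

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.cm_mode not in ("spatial", "global"):
            raise ValueError("cm_mode must be 'spatial' or 'global'")
        if not self.encoder_channels:
            raise ValueError("encoder_channels must be nonempty")
        if self.rank != "full":
            if not (1 <= int(self.rank) < self.n_classes):
                raise ValueError("factored rank must satisfy 1 <= l < L")
        if self.cm_normalization not in ("dominant", "softmax"):
            raise ValueError("cm_normalization must be 'dominant' or 'softmax'")


@dataclass
class ConsensusProbMap:
    """Per-pixel class probabilities, shape (H, W, L)."""

    probs: np.ndarray

    def __post_init__(self):
        s = self.probs.sum(axis=-1)
        if np.abs(s - 1.0).max() > 1e-5 or (self.probs < -1e-7).any():
            raise ValueError("probabilities must lie on the simplex")

    def argmax(self) -> np.ndarray:
        return self.probs.argmax(axis=-1)


@dataclass
class AnnotatorProbMap:
    """Estimated label distribution of one annotator, shape (H, W, L)."""

    probs: np.ndarray
    annotator_id: int = 0


@dataclass
class SpatialCM:
    """Per-pixel LxL column-stochastic CMs of one annotator.

    Either ``full`` of shape (H, W, L, L) or nonnegative ``factors``
    (B1, B2), each of shape (H, W, L, l).
    """

    annotator_id: int
    full: np.ndarray | None = None
    factors: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        if (self.full is None) == (self.factors is None):
            raise ValueError("provide exactly one of full or factors")
        if self.full is not None:
            cols = self.full.sum(axis=-2)
            if np.abs(cols - 1.0).max() > 1e-5 or (self.full < -1e-7).any():
                raise ValueError("CM columns must be stochastic")

    def as_full(self) -> np.ndarray:
        if self.full is not None:
            return self.full
        return expand_lowrank(*self.factors)

    def trace(self) -> np.ndarray:
        """Per-pixel trace, shape (H, W)."""
        full = self.as_full()
        return np.trace(full, axis1=-2, axis2=-1)


def expand_lowrank(b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Expand rank-l factors to full per-pixel column-stochastic CMs.

    Computes B1 B2^T per pixel, clamps below at zero and normalises each
    column to sum to 1 (a vanishing column falls back to uniform).
    """
    b1, b2 = np.asarray(b1, float), np.asarray(b2, float)
    if b1.shape != b2.shape:
        raise ValueError("factors must share a shape")
    L, l = b1.shape[-2], b1.shape[-1]
    if l >= L:
        raise ValueError("factored rank must satisfy l < L (no saving otherwise)")
    m = np.maximum(np.einsum("...il,...jl->...ij", b1, b2), 0.0)
    cols = m.sum(axis=-2, keepdims=True)
    uniform = np.full_like(m, 1.0 / L)
    return np.where(cols > _EPS, m / np.maximum(cols, _EPS), uniform)


def annotator_distribution(cm: SpatialCM | np.ndarray,
                           p: ConsensusProbMap | np.ndarray) -> AnnotatorProbMap:
    """Per-pixel matrix-vector product A(x) p(x).

    Column-stochastic A and simplex p guarantee the output is a valid
    probability map.
    """
    annotator_id = 0
    if isinstance(cm, SpatialCM):
        annotator_id = cm.annotator_id
        cm = cm.as_full()
    probs = p.probs if isinstance(p, ConsensusProbMap) else np.asarray(p, float)
    cm = np.asarray(cm, float)
    if cm.shape[:-2] != probs.shape[:-1] or cm.shape[-1] != probs.shape[-1]:
        raise ValueError(f"shape mismatch: cm {cm.shape} vs p {probs.shape}")
    out = np.einsum("...ij,...j->...i", cm, probs)
    return AnnotatorProbMap(probs=out, annotator_id=annotator_id)


def cm_cost(width: int, height: int, n_classes: int,
            rank: int | str = "full") -> tuple[int, int]:
    """Variable count and FLOPs of the per-pixel CM representation.

    Full CMs hold W*H*L^2 variables and the annotator-distribution product
    costs W*H*(2L-1)*L FLOPs; the rank-l factorisation reduces these to
    2*W*H*L*l variables and W*H*(4L(l-0.25)-l) FLOPs.
    """
    if min(width, height, n_classes) < 1:
        raise ValueError("dimensions must be >= 1")
    wh = width * height
    L = n_classes
    if rank == "full":
        return wh * L * L, wh * (2 * L - 1) * L
    l = int(rank)
    if not 1 <= l < L:
        raise ValueError("factored rank must satisfy 1 <= l < L")
    n_params = 2 * wh * L * l
    n_flops = wh * (4 * L * (l - 0.25) - l)
    return int(n_params), int(round(n_flops))


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def finish_cms(raw_cms, config: ModelConfig) -> Tensor:
    """Turn the annotator head's raw output into full column-stochastic CMs.

    Factored output (B1, B2) is expanded per pixel and column-normalised;
    with ``cm_normalization="dominant"`` every column is then mixed halfway
    with the identity column, A[:, j] = (S[:, j] + e_j) / 2, which keeps the
    diagonal entry strictly largest in its column.
    """
    L = config.n_classes
    if isinstance(raw_cms, tuple):
        b1, b2 = raw_cms
        m = b1 @ b2.transpose(0, 1, 2, 3, 5, 4)  # (N,H,W,R,L,L), nonnegative
        cols = m.sum(axis=-2, keepdims=True)
        cms = (m + _EPS) / (cols + L * _EPS)
    else:
        cms = raw_cms
    if config.cm_normalization == "dominant":
        cms = cms * 0.5 + Tensor(0.5 * np.eye(L))
    return cms


def _he_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class _Conv:
    def __init__(self, rng, c_in, c_out, k=3):
        self.w = Tensor(_he_init(rng, (c_out, c_in, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class _InstanceNorm:
    """Instance normalisation over spatial dims, learnable affine."""

    def __init__(self, channels, eps=1e-5):
        self.gamma = Tensor(np.ones((1, channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1)), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=(2, 3), keepdims=True)
        xhat = centred * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class _Block:
    """conv -> instance norm -> ReLU, repeated."""

    def __init__(self, rng, c_in, c_out, n_convs=2, norm="instance"):
        self.layers = []
        for i in range(n_convs):
            conv = _Conv(rng, c_in if i == 0 else c_out, c_out)
            norm_layer = _InstanceNorm(c_out) if norm == "instance" else None
            self.layers.append((conv, norm_layer))

    def __call__(self, x: Tensor) -> Tensor:
        for conv, norm in self.layers:
            x = conv(x)
            if norm is not None:
                x = norm(x)
            x = ad.relu(x)
        return x

    def parameters(self):
        out = []
        for conv, norm in self.layers:
            out += conv.parameters()
            if norm is not None:
                out += norm.parameters()
        return out


class CoupledModel:
    """Shared U-Net backbone with consensus and annotator-CM heads.

    The backbone downsamples len(encoder_channels)-1 times (2x2 max pooling)
    and mirrors back up with nearest-neighbour upsampling and skip
    concatenation; all layers except the two final 1x1 heads are shared
    between the segmentation and annotator networks.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = list(config.encoder_channels)
        L, R = config.n_classes, config.n_annotators
        self.enc = []
        c_prev = config.in_channels
        for c in ch:
            self.enc.append(_Block(rng, c_prev, c, norm=config.norm))
            c_prev = c
        self.dec = []
        for c in ch[-2::-1]:  # skip connection carries c channels at each level
            self.dec.append(_Block(rng, c_prev + c, c, norm=config.norm))
            c_prev = c
        self.seg_head = _Conv(rng, c_prev, L, k=1)
        if config.cm_mode == "global":
            logits = np.zeros((R, L, L))
            logits[:, np.arange(L), np.arange(L)] = config.diag_bias
            self.global_logits = Tensor(logits, requires_grad=True)
            self.cm_head = None
        else:
            self.global_logits = None
            if config.rank == "full":
                self.cm_head = _Conv(rng, c_prev, R * L * L, k=1)
                # bias the diagonal logits so untrained CMs start near identity
                bias = self.cm_head.b.data.reshape(R, L, L)
                bias[:, np.arange(L), np.arange(L)] = config.diag_bias
            else:
                l = int(config.rank)
                self.cm_head = _Conv(rng, c_prev, R * 2 * L * l, k=1)

    # -- parameter groups --------------------------------------------------
    def backbone_parameters(self) -> list[Tensor]:
        out = []
        for b in self.enc + self.dec:
            out += b.parameters()
        return out

    def seg_parameters(self) -> list[Tensor]:
        return self.seg_head.parameters()

    def annotator_parameters(self) -> list[Tensor]:
        if self.global_logits is not None:
            return [self.global_logits]
        return self.cm_head.parameters()

    def parameters(self) -> list[Tensor]:
        return self.backbone_parameters() + self.seg_parameters() + self.annotator_parameters()

    # -- forward -----------------------------------------------------------
    def _check_image(self, images: np.ndarray) -> np.ndarray:
        """Coerce (H,W), (H,W,C), (N,H,W) or (N,H,W,C) to NCHW."""
        images = np.asarray(images, float)
        if images.ndim == 2:
            images = images[None, :, :, None]
        elif images.ndim == 3:
            if images.shape[-1] == self.config.in_channels:
                images = images[None]  # one (H, W, C) image
            else:
                images = images[..., None]  # (N, H, W) single-channel batch
        x = images.transpose(0, 3, 1, 2)
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} channel(s), got {x.shape[1]}"
            )
        depth = len(self.config.encoder_channels) - 1
        if x.shape[2] % (1 << depth) or x.shape[3] % (1 << depth):
            raise ValueError(f"spatial dims must be divisible by {1 << depth}")
        return x

    def _backbone(self, x: Tensor) -> Tensor:
        skips = []
        for i, block in enumerate(self.enc):
            x = block(x)
            if i < len(self.enc) - 1:
                skips.append(x)
                x = ad.maxpool2(x)
        for block, skip in zip(self.dec, reversed(skips)):
            x = ad.upsample2(x)
            x = ad.concat([x, skip], axis=1)
            x = block(x)
        return x

    def forward_tensors(self, images: np.ndarray
                        ) -> tuple[Tensor, Tensor | tuple[Tensor, Tensor]]:
        """Differentiable forward pass used by the training loop.

        Returns ``(consensus_probs, raw_cms)`` where consensus_probs has
        shape (N, H, W, L) and raw_cms is a (N, H, W, R, L, L) column-softmax
        tensor, a (R, L, L) tensor in global mode, or a pair of nonnegative
        factor tensors (N, H, W, R, L, l) in the factored case; pass raw_cms
        through :func:`finish_cms` to obtain the final CMs.
        """
        x = Tensor(self._check_image(images))
        n, _, h, w = x.data.shape
        L, R = self.config.n_classes, self.config.n_annotators
        feat = self._backbone(x)
        seg_logits = self.seg_head(feat).transpose(0, 2, 3, 1)  # (N,H,W,L)
        probs = ad.softmax(seg_logits, axis=-1)
        if self.global_logits is not None:
            cms = ad.softmax(self.global_logits, axis=-2)  # (R,L,L), columns stochastic
            return probs, cms
        raw = self.cm_head(feat).transpose(0, 2, 3, 1)  # (N,H,W,RC)
        if self.config.rank == "full":
            raw = raw.reshape(n, h, w, R, L, L)
            cms = ad.softmax(raw, axis=-2)  # softmax along observed axis i
            return probs, cms
        l = int(self.config.rank)
        raw = raw.reshape(n, h, w, R, 2, L, l)
        factors = raw.softplus()  # nonnegative factors
        return probs, (_slice_axis(factors, 4, 0), _slice_axis(factors, 4, 1))

    def forward_consensus(self, image: np.ndarray) -> ConsensusProbMap:
        """Consensus class probabilities for one image, shape (H, W, L)."""
        probs, _ = self.forward_tensors(image)
        return ConsensusProbMap(probs=probs.data[0])

    def forward_annotator_cms(self, image: np.ndarray, annotator_id: int) -> SpatialCM:
        """Per-pixel CMs of one annotator for one image."""
        R = self.config.n_annotators
        if not 0 <= annotator_id < R:
            raise ValueError(f"unknown annotator {annotator_id} (R={R})")
        _, raw = self.forward_tensors(image)
        if isinstance(raw, tuple) and self.config.cm_normalization == "softmax":
            b1, b2 = raw
            return SpatialCM(annotator_id=annotator_id,
                             factors=(b1.data[0, :, :, annotator_id],
                                      b2.data[0, :, :, annotator_id]))
        cms = finish_cms(raw, self.config).data
        if self.global_logits is not None:
            h, wd = np.asarray(image).shape[:2]
            full = np.broadcast_to(cms[annotator_id], (h, wd) + cms[annotator_id].shape)
            return SpatialCM(annotator_id=annotator_id, full=np.ascontiguousarray(full))
        return SpatialCM(annotator_id=annotator_id, full=cms[0, :, :, annotator_id])

    # -- (de)serialisation --------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, float).copy()


def _slice_axis(t: Tensor, axis: int, index: int) -> Tensor:
    """Differentiable single-index slice along ``axis``."""
    sl = [slice(None)] * t.data.ndim
    sl[axis] = index
    sl = tuple(sl)

    def bwd(out):
        def fn():
            g = np.zeros_like(t.data)
            g[sl] = out.grad
            t._accum(g)
        return fn

    return Tensor._result(t.data[sl], (t,), bwd)
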