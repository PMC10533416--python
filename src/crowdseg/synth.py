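"""Seeded synthetic multi-annotator segmentation datasets.

Generates simple geometric ground-truth images (a stand-in for digit or
lesion imagery), then corrupts the true masks with configurable annotator
personas:

* ``over_segmenter`` — morphological dilation of every foreground class
  (systematically draws boundaries too generously),
* ``under_segmenter`` — morphological erosion (misses lesion margins, may
  drop small lesions entirely),
* ``class_confuser`` — swaps pixels of one class for another with a fixed
  probability (mixes up two tissue classes),
* ``cm_corruptor`` — resamples every pixel's label independently from the
  column of a prescribed LxL column-stochastic confusion matrix.

Only ``cm_corruptor`` personas have a well-defined per-pixel true confusion
matrix (the corruption is pixelwise independent by construction); for the
morphological personas the corruption is spatially structured and no true CM
is recorded.  Background is always class 0 and masks are 0-based integer
maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as _disk
from skimage.morphology import dilation, erosion, footprint_rectangle

__all__ = [
    "GroundTruthSample",
    "AnnotatorPersona",
    "AnnotatedDataset",
    "generate_shapes",
    "apply_morpho_annotator",
    "apply_cm_annotator",
    "apply_persona",
    "build_dataset",
]

_MORPHO_KINDS = ("over_segmenter", "under_segmenter", "class_confuser")
_ALL_KINDS = _MORPHO_KINDS + ("cm_corruptor",)


@dataclass
class GroundTruthSample:
    """A clean image with its true segmentation mask."""

    image: np.ndarray  # (H, W) or (H, W, C) float
    mask: np.ndarray  # (H, W) int in [0, L-1]
    seed: int

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask must share spatial dims")


@dataclass
class AnnotatorPersona:
    """A parameterised corruption process standing in for one noisy rater.

    ``strength`` is the morphological radius (over/under-segmenter) or the
    swap probability (class_confuser); ``cm`` is the column-stochastic
    confusion matrix of a ``cm_corruptor``.  ``swap_map`` maps source class
    i to target class j for the class_confuser; by default i -> (i+1) mod L,
    resolved against the dataset's number of classes at application time.
    """

    kind: str
    annotator_id: int
    strength: float = 0.0
    cm: np.ndarray | None = None
    swap_map: dict[int, int] | None = None

    def __post_init__(self):
        if self.kind not in _ALL_KINDS:
            raise ValueError(f"unknown persona kind: {self.kind!r}")
        if self.strength < 0:
            raise ValueError("strength must be >= 0")
        if self.kind == "cm_corruptor":
            if self.cm is None:
                raise ValueError("cm_corruptor persona requires a cm")
            _check_column_stochastic(np.asarray(self.cm, dtype=float))


@dataclass
class AnnotatedDataset:
    """Images with per-annotator noisy masks plus (synthetic-only) truth."""

    images: list[np.ndarray]
    noisy_masks: list[dict[int, np.ndarray]]  # per sample: annotator_id -> mask
    n_classes: int
    label_density: str = "dense"
    truth_masks: list[np.ndarray] | None = None
    true_cms: dict[int, np.ndarray] = field(default_factory=dict)  # id -> (L, L)
    personas: list[AnnotatorPersona] = field(default_factory=list)

    def __post_init__(self):
        if any(len(m) < 1 for m in self.noisy_masks):
            raise ValueError("every sample must be annotated by at least one person")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def annotator_sets(self) -> list[list[int]]:
        """S(x): the annotator ids that labelled each sample."""
        return [sorted(m.keys()) for m in self.noisy_masks]

    @property
    def annotator_ids(self) -> list[int]:
        ids: set[int] = set()
        for m in self.noisy_masks:
            ids.update(m.keys())
        return sorted(ids)


def _check_column_stochastic(cm: np.ndarray, tol: float = 1e-6) -> None:
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("cm must be a square matrix")
    if (cm < -tol).any() or np.abs(cm.sum(axis=0) - 1.0).max() > tol:
        raise ValueError("cm columns must be nonnegative and sum to 1")


def generate_shapes(n: int, width: int, height: int, n_classes: int,
                    seed: int, noise_sd: float = 0.1,
                    min_size_frac: float = 1 / 8,
                    max_size_frac: float = 1 / 4) -> list[GroundTruthSample]:
    """Generate ``n`` images of random discs/rectangles on a dark background.

    Each foreground class gets a distinct mean intensity so segmentation is
    learnable from the image alone; i.i.d. Gaussian noise (sd ``noise_sd``)
    is added on top.  Foreground classes are cycled across samples so every
    class appears in the dataset.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_classes < 2:
        raise ValueError("need at least 2 classes (background + 1)")
    if width < 8 or height < 8:
        raise ValueError(f"image dims must be >= 8, got {width}x{height}")
    rng = np.random.default_rng(seed)
    samples = []
    for idx in range(n):
        mask = np.zeros((height, width), dtype=np.int64)
        # guarantee presence of the cycled class, then add extra shapes
        classes = [1 + idx % (n_classes - 1)]
        for _ in range(rng.integers(0, 2)):
            classes.append(int(rng.integers(1, n_classes)))
        side = min(height, width)
        lo = max(2, int(side * min_size_frac))
        hi = max(lo + 1, int(side * max_size_frac))
        for c in classes:
            if rng.random() < 0.5:
                r = int(rng.integers(lo, hi))
                cy = int(rng.integers(r, height - r))
                cx = int(rng.integers(r, width - r))
                rr, cc = _disk((cy, cx), r, shape=mask.shape)
                mask[rr, cc] = c
            else:
                h = int(rng.integers(2 * lo, 2 * hi))
                w = int(rng.integers(2 * lo, 2 * hi))
                y0 = int(rng.integers(0, height - h))
                x0 = int(rng.integers(0, width - w))
                mask[y0 : y0 + h, x0 : x0 + w] = c
        intensity = mask.astype(float) / (n_classes - 1)
        image = intensity + noise_sd * rng.standard_normal(mask.shape)
        samples.append(GroundTruthSample(image=image, mask=mask, seed=seed + idx))
    return samples


def apply_morpho_annotator(mask: np.ndarray, persona: AnnotatorPersona,
                           seed: int, n_classes: int | None = None) -> np.ndarray:
    """Corrupt a label map with a morphological/class-swap persona.

    Dilation and erosion use a square structuring element of radius
    ``persona.strength`` applied to each foreground class in turn; the
    class_confuser swaps each pixel of class i to ``swap_map[i]`` with
    probability ``persona.strength``.
    """
    if persona.kind not in _MORPHO_KINDS:
        raise ValueError(f"not a morphological persona: {persona.kind!r}")
    mask = np.asarray(mask)
    L = n_classes if n_classes is not None else int(mask.max()) + 1
    out = mask.copy()
    if persona.kind == "class_confuser":
        p = float(persona.strength)
        if not 0.0 <= p <= 1.0:
            raise ValueError("class_confuser strength is a probability")
        if p == 0.0:
            return out
        swap = persona.swap_map or {i: (i + 1) % L for i in range(1, L)}
        rng = np.random.default_rng(seed)
        flip = rng.random(mask.shape) < p
        for src, dst in swap.items():
            out[(mask == src) & flip] = dst
        return out
    radius = int(persona.strength)
    if radius == 0:
        return out
    footprint = footprint_rectangle((2 * radius + 1, 2 * radius + 1))
    if persona.kind == "over_segmenter":
        for c in range(1, L):
            grown = dilation(mask == c, footprint)
            out[grown & (mask == 0)] = c
    else:  # under_segmenter
        for c in range(1, L):
            kept = erosion(mask == c, footprint)
            out[(mask == c) & ~kept] = 0
    return out


def apply_cm_annotator(mask: np.ndarray, cm: np.ndarray, seed: int) -> np.ndarray:
    """Resample every pixel's label from column ``mask[pixel]`` of ``cm``.

    The corruption is pixelwise independent, so ``cm`` is exactly the true
    per-pixel confusion matrix of this simulated annotator.
    """
    cm = np.asarray(cm, dtype=float)
    _check_column_stochastic(cm)
    L = cm.shape[0]
    mask = np.asarray(mask)
    if mask.max() >= L:
        raise ValueError("mask contains labels outside the cm's class range")
    rng = np.random.default_rng(seed)
    u = rng.random(mask.shape)
    cdf = np.cumsum(cm, axis=0)  # (L, L): cdf[:, j] for true class j
    # noisy label = first i with cdf[i, true] > u
    thresholds = cdf[:, mask]  # (L, H, W)
    return (u[None] > thresholds).sum(axis=0).astype(mask.dtype)


def apply_persona(sample: GroundTruthSample, persona: AnnotatorPersona,
                  seed: int, n_classes: int) -> np.ndarray:
    if persona.kind == "cm_corruptor":
        return apply_cm_annotator(sample.mask, persona.cm, seed)
    return apply_morpho_annotator(sample.mask, persona, seed, n_classes)


def build_dataset(samples: list[GroundTruthSample],
                  personas: list[AnnotatorPersona],
                  label_density: str = "dense",
                  seed: int = 0,
                  n_classes: int | None = None) -> AnnotatedDataset:
    """Label every sample with the personas, densely or one-per-sample.

    ``dense``: every persona annotates every sample.  ``single``: exactly
    one persona, chosen uniformly at random, annotates each sample (so
    |S(x)| = 1).  Deterministic given ``seed``.
    """
    if not personas:
        raise ValueError("need at least one persona")
    if label_density not in ("dense", "single"):
        raise ValueError("label_density must be 'dense' or 'single'")
    if n_classes is None:
        n_classes = int(max(s.mask.max() for s in samples)) + 1
        for p in personas:
            if p.cm is not None:
                n_classes = max(n_classes, p.cm.shape[0])
    rng = np.random.default_rng(seed)
    noisy: list[dict[int, np.ndarray]] = []
    for i, sample in enumerate(samples):
        if label_density == "dense":
            chosen = personas
        else:
            chosen = [personas[rng.integers(len(personas))]]
        entry = {}
        for p in chosen:
            # independent per (sample, annotator) corruption stream
            entry[p.annotator_id] = apply_persona(
                sample, p, seed=seed + 1000003 * (i + 1) + p.annotator_id, n_classes=n_classes
            )
        noisy.append(entry)
    true_cms = {p.annotator_id: np.asarray(p.cm, dtype=float)
                for p in personas if p.kind == "cm_corruptor"}
    return AnnotatedDataset(
        images=[s.image for s in samples],
        noisy_masks=noisy,
        n_classes=n_classes,
        label_density=label_density,
        truth_masks=[s.mask for s in samples],
        true_cms=true_cms,
        personas=list(personas),
    )
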