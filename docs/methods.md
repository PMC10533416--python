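# Methods

## Problem and model

A set of images `x_n` carries noisy segmentation masks `ỹ_n^(r)` from
annotators `r ∈ S(x_n)`, with every image labelled by at least one person
and no reference segmentation available. The model assumes annotators are
independent of each other and across pixels *given* the true label, so the
probability of an observed noisy label at a pixel factorises as

    p(ỹ^(r) = i | x) = Σ_j  a^(r)(x)_{ij} · p(y = j | x),

where `A^(r)(x) = [a_{ij}]` is an L×L column-stochastic confusion matrix
(CM) — entry (i, j) is the probability annotator r reports class i when the
true class is j — estimated *per pixel, per image, per annotator*, and
`p(y | x)` is the consensus label distribution.

Two coupled convolutional networks estimate the two factors: a
**segmentation network** emitting the consensus probability map `p̂_θ(x)`
(shape W×H×L) and an **annotator network** emitting `Â_φ^(r)(x)` (shape
W×H×L×L per annotator). The estimated distribution of annotator r's labels
is the per-pixel product `p̂^(r) = Â^(r) p̂`, compared against the observed
noisy mask with cross-entropy. At inference only the segmentation network is
used; the prediction is the per-pixel argmax (exact ties resolve to the
lowest class index).

### Objective

The training loss sums over images and annotators present in `S(x)`:

    L(θ, φ) = Σ_n Σ_r 1[r ∈ S(x_n)] · [ CE(Â^(r)(x_n) p̂(x_n), ỹ_n^(r))
                                         + λ · tr(Â^(r)(x_n)) ]

Cross-entropy alone cannot separate annotation noise from the consensus:
any pair (Â, p̂) whose product matches the observed noisy distribution is a
global optimum. Minimising the mean CM trace selects, among those, the
solution that attributes as much disagreement as possible to the annotators.
When the mean CM at a pixel is diagonally dominant this recovers the true
correct-class CM columns (the other columns are not identifiable from a
single one-hot consensus; see the identifiability check below). During a
warm-up period the sign of the trace term is flipped so the annotator
network first *maximises* the trace, holding the CMs near identity (hence
diagonally dominant) while the consensus map forms.

Pixel reduction is a mean rather than a sum, so λ has the same meaning at
any image size. Probabilities are clamped at 1e−12 before logs.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `lambda_` | 0.01 | trace coefficient; 0 disables regularisation |
| `warmup_iters` | 500 (library), 60 in the bundled studies | steps of trace maximisation |
| `diag_bias` | +2 | initial diagonal logit offset of the CM head |
| `rank` | `"full"` | or integer l < L for the factored CM head |
| `cm_mode` | `"spatial"` | `"global"` learns one input-independent CM per annotator |
| `cm_normalization` | `"dominant"` | see below; `"softmax"` is the plain column softmax |
| optimiser | Adam, lr 1e−3 | seeds cover init and shuffling |

### CM head normalisation

The annotator head emits raw scores per pixel; a softmax along the
observed-label axis makes each column of the CM stochastic. By default the
column is then mixed halfway with the corresponding identity column,
`Â[:, j] = (softmax(z)[:, j] + e_j) / 2`, which keeps the diagonal entry
strictly the largest in its column. This projects the estimate onto the
hypothesis class in which trace minimisation is provably identifiable. The
projection matters in practice: under purely pixelwise-independent
corruption the cross-entropy leaves the consensus softness unconstrained,
and with an unconstrained softmax head the trace term then rewards
anti-dominant columns — training runs drift into a solution where the
noisiest annotator's CM freezes near identity, the consensus absorbs that
annotator's noise, and regularisation *increases* the CM error. With the
dominant parameterisation the cleanest annotator anchors the consensus at
one-hot and the trace term converges to the true diagonals. The cost is
expressiveness: a column can put at most 1/2 of its mass off-diagonal, so
annotators that are worse than that (e.g. an over-segmenter at boundary
pixels it always mislabels) are modelled at the cap. The plain softmax
head remains available via `cm_normalization="softmax"`.

### Low-rank factorisation

Each full spatial CM holds `W·H·L²` variables, and the product `Â p̂` costs
`W·H·(2L−1)·L` FLOPs. The factored head emits two nonnegative
(softplus-transformed) W×H×L×l tensors B1, B2 with `Â ∝ B1 B2ᵀ`
column-normalised, reducing the counts to `2·W·H·L·l` variables and
`W·H·(4L(l−0.25)−l)` FLOPs (`cm_cost` implements both formulas). Because
the factors are nonnegative, the normalised product can also be applied to
`p̂` without materialising the L×L matrix. Under the dominant
normalisation the identity mixing is applied after expansion.

### Architecture

A single U-Net backbone is shared by both networks except for the final
1×1 heads: encoder blocks of two 3×3 convolutions with instance
normalisation and ReLU, 2×2 max-pooling between levels, nearest-neighbour
upsampling with skip concatenation on the way up. The consensus head has L
channels; the annotator head has R·L·L (or R·2·L·l when factored). The
global-CM ablation replaces the annotator head with R learnable L×L logit
matrices. The default channel plan is (32, 64, 128, 256); the bundled
studies use (8, 16) at 32×32, which is ample for the synthetic shapes.
The network stack runs on a small reverse-mode automatic-differentiation
engine over NumPy written for this package (`crowdseg.autodiff`); gradients
are verified against central finite differences in the test suite.

Training modes: `joint` (default) optimises both networks under the
combined loss; `two_stage` first runs the combined objective, then freezes
the annotator head and updates only the segmentation path against the fixed
product of annotator experts.

## Synthetic annotators

`generate_shapes` draws random discs and rectangles (one guaranteed
foreground shape per image, classes cycled so all appear) with
class-dependent intensity plus Gaussian noise (sd 0.1) — learnable imagery
standing in for digits or lesions, with no claim to real morphology.
Personas corrupt the true mask:

* `over_segmenter` / `under_segmenter`: per-class dilation/erosion with a
  square structuring element of radius `strength` (dilation claims only
  background pixels; erosion may delete small lesions entirely);
* `class_confuser`: swaps class i to `swap_map[i]` with probability
  `strength`; by default each nonzero class maps to `(i+1) mod L`
  (background is left alone so the persona "mixes up two classes" rather
  than hallucinating lesions);
* `cm_corruptor`: resamples every pixel independently from the column of a
  given column-stochastic CM.

Only `cm_corruptor` personas have a well-defined per-pixel true CM
(pixelwise-independent corruption); morphological corruption is spatially
structured, so CM-error metrics are computed against `cm_corruptor`
annotators only. Label density is `dense` (everyone labels everything) or
`single` (one uniformly chosen annotator per image). All corruption is
seeded per (sample, annotator) and bit-reproducible.

What the simulator does *not* emulate: anatomically realistic shapes and
textures, annotator correlations (fatigue, shared training), intensity-
dependent ambiguity, or 3D structure. Passing tests therefore demonstrate
the estimation machinery under its stated assumptions, not performance on
real clinical data.

## Estimating the mean CM per annotator

Reported per-annotator CMs average the per-pixel estimates with weights
equal to the consensus probability of each column's class at that pixel:
column j of the CM describes behaviour *given* true class j, and pixels
where class j is absent carry no information about that column (only the
correct-class column is identifiable). A pixel-uniform average
(`weights="uniform"`) is available but mixes in the unidentified columns.

## Fusion baselines and metrics

* `mean_fusion` / `majority_vote`: per-pixel average of one-hot annotations
  and its argmax (the two hard outputs coincide; all ties resolve to the
  lowest class).
* `staple_em`: classic STAPLE with one global L×L CM per annotator —
  E-step posterior ∝ prior × Π_r CM likelihoods, M-step from
  posterior-weighted counts; fixed empirical class prior by default, CMs
  initialised at diagonal 0.8, stop at max CM change < 1e−6 or 100
  iterations; the observed-data log-likelihood is non-decreasing. True
  classes with no posterior mass get uniform columns. The consensus agrees
  with SimpleITK's MultiLabelSTAPLE on test instances.
* Metrics: per-class Dice (argmax-thresholded by default, soft optional;
  both-empty = 1), total Dice over all classes jointly (equals pixel
  accuracy for hard maps), CM root-MSE and mean-absolute error
  ("incompetence"), and the squared generalized energy distance
  `2E[d(S,Y)] − E[d(S,S′)] − E[d(Y,Y′)]` with `d = 1 − total Dice`, means
  over all ordered pairs. The model's sample set for GED is each
  annotator's plug-in prediction `argmax(Â^(r) p̂)`. CM metrics return an
  explicit `None` when no true CMs exist.

## Identifiability check

`min_trace_feasible_cms` enumerates, for one binary pixel with one-hot
truth `e_k` and R annotators with known CMs, every grid combination of
estimated CM diagonals and consensus probability that reproduces the
observed noisy distributions exactly, keeps those whose mean estimated CM
is diagonally dominant *within columns*, and returns the minimum-trace
solutions. On the tested instances the correct-class column of every
annotator's CM is unique at the minimum (error ≤ one grid step).
Dominance must be read column-wise for column-stochastic CMs; with a
row-wise reading the enumeration exhibits label-swapped solutions of lower
trace, so the column-wise condition is the one under which the uniqueness
claim holds — and is what the `"dominant"` CM head enforces.

## Bundled studies (`crowdseg.benchmarks`)

Problem sizes are chosen so each study runs in minutes on one CPU core
while leaving the optimisation long enough for the trace term to
equilibrate: 32×32 images, shape sizes 1/5–2/5 of the image side
(foreground ≈ 35%), batch 4, warm-up 60 steps, channels (8, 16); the
recovery study trains on 120 samples for 50 epochs (≈1500 steps), the
ranking studies on 120–135 training samples for 40 (dense) or 30
(single-label) epochs.

* **CM recovery** — three `cm_corruptor` annotators with diagonals
  0.9/0.8/0.7, dense labels, λ ∈ {0.01, 0}. With the trace term the mean
  estimated diagonals land within ±0.1 of truth and the CM root-MSE is
  strictly below the λ = 0 run, mean over three seeds. The same recovery
  holds qualitatively with a single label per image at ±0.15.
* **Method ranking (dense)** — five annotators (over-segmenter strength 2,
  class confuser 0.3, exact-CM raters 0.95/0.8/0.65), dense labels,
  consensus Dice on a held-out 20% split, three seeds, comparing the
  coupled model, its global-CM ablation, STAPLE, majority vote and mean
  fusion. The pool is deliberately in the regime where each baseline's
  assumptions are exercised: heterogeneous reliabilities (so reliability
  weighting beats unweighted voting) and exactly one systematically biased
  morphological annotator. With several mutually corroborating
  over-segmenters STAPLE drops below majority vote (their agreement
  masquerades as reliability), and with a perfectly balanced pool every
  method converges to the ceiling and the comparison is uninformative —
  both regimes are real behaviour, not defects. In this dense study both
  neural models exceed 99.5% Dice and their mutual difference is within
  seed noise, so the spatial-vs-global comparison is made in the
  single-label study instead.
* **Spatial vs global CMs (single label)** — the same pool with exactly
  one annotation per image. Per-image fusion degenerates here (the
  consensus of one mask is that mask), and the pooled neural models must
  explain each annotator's systematic errors from cross-image structure:
  the image-dependent spatial CM model beats the global-CM ablation by a
  clear, seed-stable margin, the regime where the distinction genuinely
  matters.

## Numerical choices and degenerate inputs

Probability floors at 1e−12 before logs and divisions; softmax computed via
a max-shifted log-sum-exp; max-pooling splits gradient across exact ties;
Adam (β = 0.9/0.999, ε = 1e−8); float64 throughout. Empty datasets, empty
persona lists, non-stochastic CMs, out-of-range labels, unknown annotators
and shape mismatches are rejected with explicit errors. An all-one-class
STAPLE input yields that class as consensus with uniform columns for unseen
classes. Dataset round-trips are bit-exact for masks; PNG images are 16-bit
affine-quantised (max error ≈ range/65535) while NIfTI stores float64
exactly.

## Known limitations

* The dominant CM head caps off-diagonal column mass at 1/2, biasing CMs of
  extremely unreliable annotators toward the cap.
* Identifiability of non-correct-class CM columns is fundamentally limited;
  consensus-weighted averaging reports only what the data determine.
* The NumPy engine is single-threaded apart from BLAS; full-size (256-channel,
  192×192) configurations are constructible but impractically slow without a
  GPU framework.
* STAPLE is the classic global-CM variant; spatially varying STAPLE
  extensions are out of scope.
* The simulator is 2D and binary/multi-class integer masks only.
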