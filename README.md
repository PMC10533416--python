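# crowdseg

Learning a consensus segmentation — and each annotator's reliability — from
noisy multi-annotator labels alone.

Medical image segmentation datasets are usually labelled by several raters
who disagree: some systematically over-segment, some under-segment, some mix
up classes, and no reference standard exists. `crowdseg` implements a
coupled-network approach to this problem: a **segmentation network**
estimates the unobserved expert-consensus label probabilities p̂\_θ(x), and
an **annotator network** estimates, for every annotator r, a per-pixel
L×L column-stochastic confusion matrix Â\_φ^(r)(x) whose (i, j) entry is the
probability that annotator reports class i when the true class is j. The
product Â^(r)(x)·p̂\_θ(x) models each annotator's observed noisy labels, and
both networks are trained jointly by minimising

  Σₙ Σᵣ 1[r labelled xₙ] · [ CE(Â^(r)(xₙ)·p̂\_θ(xₙ), ỹₙ^(r)) + λ·tr(Â^(r)(xₙ)) ]

The trace term makes the decomposition identifiable: among all ways to split
the observed disagreement between "the consensus is uncertain" and "the
annotators are unreliable", it selects the most-unreliable-annotators
solution, which recovers the true confusion matrices when the mean CM is
diagonally dominant. Because the networks are shared across images, the
approach keeps working when each image carries only a single annotation —
where per-image methods such as STAPLE degrade.

The package is aimed at method researchers and dataset curators who want to
fuse multi-rater masks, rank annotators by estimated competence, or benchmark
fusion methods under controlled noise. It ships:

* the coupled model (full-rank, rank-l factored, or global-CM ablation) on a
  small self-contained NumPy autodiff engine — no GPU framework required;
* a seeded synthetic multi-annotator simulator (over-/under-segmenters,
  class confusers, and exact-CM corruptors with known ground-truth CMs);
* classical fusion baselines: mean, majority vote, and STAPLE (EM);
* evaluation metrics: per-class/total Dice, CM root-MSE and incompetence
  score, generalized energy distance;
* dataset I/O (PNG / NIfTI + JSON manifest), an experiment driver, and a
  `crowdseg` command-line interface.

## Worked example

Simulate three raters with known confusion matrices, train the coupled
model, and read the estimated reliabilities back off the annotator network:

```python
import numpy as np
import crowdseg as cs

def cm(d):  # symmetric binary CM with diagonal d
    return np.array([[d, 1 - d], [1 - d, d]])

personas = [
    cs.AnnotatorPersona(kind="cm_corruptor", annotator_id=i, cm=cm(d))
    for i, d in enumerate((0.9, 0.8, 0.7))
]
shapes = cs.generate_shapes(120, 32, 32, n_classes=2, seed=0,
                            min_size_frac=1/5, max_size_frac=2/5)
data = cs.build_dataset(shapes, personas, label_density="dense", seed=0)

model, history = cs.train(
    data,
    cs.ModelConfig(n_classes=2, n_annotators=3, encoder_channels=(8, 16)),
    cs.TrainConfig(epochs=50, batch_size=4, seed=0, warmup_iters=60, lambda_=0.01),
)

labels, probs = cs.predict(model, data.images[0])
print("consensus Dice:", round(cs.average_dice(labels, data.truth_masks[0], 2), 3))

est = cs.estimate_mean_cms(model, data.images[:40])
for aid, true_cm in data.true_cms.items():
    print(f"annotator {aid}: true diag {np.diag(true_cm)}, "
          f"estimated diag {np.diag(est[aid]).round(3)}")
print("CM root-MSE:", round(cs.cm_rmse(est, data.true_cms), 4))

state = cs.staple_em([data.noisy_masks[0][r] for r in range(3)], n_classes=2)
print("STAPLE Dice:", round(cs.average_dice(state.consensus_labels, data.truth_masks[0], 2), 3))
```

Output (a few minutes on one CPU core):

```
consensus Dice: 1.0
annotator 0: true diag [0.9 0.9], estimated diag [0.901 0.91 ]
annotator 1: true diag [0.8 0.8], estimated diag [0.803 0.82 ]
annotator 2: true diag [0.7 0.7], estimated diag [0.697 0.711]
CM root-MSE: 0.0103
STAPLE Dice: 0.87
```

The consensus matches the hidden truth, and the per-annotator diagonals —
the probability each rater labels a pixel correctly — are recovered to
within about 0.02 from the noisy masks alone, ranking the annotators by
competence. STAPLE, fusing the same three masks of this image in isolation,
reaches Dice 0.87.

The same comparison at scale (five methods × three seeds, CSV/JSON output):

```python
df = cs.run_experiment(cs.ExperimentConfig(
    methods=("ours", "ours_global_cm", "staple", "mode", "mean"),
    seeds=(0, 1, 2), out_dir="results"))
```

From the shell, the same functionality is exposed as
`crowdseg simulate | train | predict | fuse | evaluate | experiment`
(see `crowdseg --help`).

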