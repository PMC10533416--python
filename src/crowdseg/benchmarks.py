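"""Reference synthetic studies: CM parameter recovery and method ranking.

Two fixed experimental protocols used by the test suite and the
reproduction script:

* :func:`cm_recovery_study` — dense labels from three exact-CM annotators
  (diagonals 0.9 / 0.8 / 0.7), train the coupled model with and without
  trace regularisation, and compare the consensus-weighted mean estimated
  CMs against the known truth (per-annotator diagonal error and root-MSE).
* :func:`method_ranking_study` — five annotators spanning the corruption
  types (one over-segmenter, one class confuser, three exact-CM raters with
  a wide skill range) fused by the coupled model, its global-CM ablation,
  STAPLE, majority vote and mean; consensus Dice is measured on a held-out
  test split.
* :func:`single_label_study` — the same annotator pool but exactly one
  annotation per image, the regime where per-image fusion is impossible and
  image-dependent spatial CMs separate most clearly from the global-CM
  ablation.

Problem sizes (32x32 images, 120 training samples, 50 epochs at batch 4)
are chosen so each study runs in a few minutes on one CPU core while
keeping the optimisation long enough for the trace term to equilibrate.
"""

from __future__ import annotations

import numpy as np

from . import synth
from .io import ExperimentConfig, run_experiment
from .metrics import cm_rmse
from .model import ModelConfig
from .synth import AnnotatorPersona
from .training import TrainConfig, estimate_mean_cms, train

__all__ = [
    "RECOVERY_DIAGS",
    "cm_recovery_study",
    "method_ranking_study",
    "single_label_study",
]

RECOVERY_DIAGS = (0.9, 0.8, 0.7)

_SIZE_FRACS = {"min_size_frac": 1 / 5, "max_size_frac": 2 / 5}


def _binary_cm(diag: float) -> np.ndarray:
    return np.array([[diag, 1.0 - diag], [1.0 - diag, diag]])


def cm_recovery_study(seeds=(0, 1, 2), n_samples: int = 120, size: int = 32,
                      epochs: int = 50, batch_size: int = 4,
                      warmup_iters: int = 60, lambdas=(0.01, 0.0),
                      label_density: str = "dense",
                      encoder_channels=(8, 16)) -> dict:
    """Train with each trace coefficient on fresh data per seed.

    Returns, per lambda: the mean (over seeds) estimated CM diagonal per
    annotator, its absolute error against truth, and the mean root-MSE of
    the full estimated-vs-true CMs.
    """
    diags = np.array(RECOVERY_DIAGS)
    personas = [AnnotatorPersona(kind="cm_corruptor", annotator_id=i,
                                 cm=_binary_cm(d))
                for i, d in enumerate(RECOVERY_DIAGS)]
    per_lambda: dict = {lam: {"diag": [], "rmse": []} for lam in lambdas}
    for seed in seeds:
        gts = synth.generate_shapes(n_samples, size, size, 2, seed=seed,
                                    **_SIZE_FRACS)
        ds = synth.build_dataset(gts, personas, label_density=label_density,
                                 seed=seed)
        for lam in lambdas:
            model_cfg = ModelConfig(n_classes=2, n_annotators=3,
                                    encoder_channels=tuple(encoder_channels))
            train_cfg = TrainConfig(epochs=epochs, batch_size=batch_size,
                                    seed=seed, warmup_iters=warmup_iters,
                                    lambda_=lam)
            model, _ = train(ds, model_cfg, train_cfg)
            est = estimate_mean_cms(model, ds.images[:40])
            per_lambda[lam]["diag"].append(
                [float(np.diag(est[i]).mean()) for i in range(3)])
            per_lambda[lam]["rmse"].append(cm_rmse(est, ds.true_cms))
    out: dict = {"true_diags": diags.tolist(), "seeds": list(seeds)}
    for lam in lambdas:
        mean_diag = np.mean(per_lambda[lam]["diag"], axis=0)
        out[lam] = {
            "mean_diags": mean_diag.tolist(),
            "diag_abs_error": np.abs(mean_diag - diags).tolist(),
            "cm_rmse": float(np.mean(per_lambda[lam]["rmse"])),
        }
    return out


def method_ranking_study(seeds=(0, 1, 2),
                         methods=("ours", "ours_global_cm", "staple",
                                  "mode", "mean"),
                         n_samples: int = 160, size: int = 32,
                         epochs: int = 40, batch_size: int = 4,
                         warmup_iters: int = 60,
                         label_density: str = "dense") -> dict:
    """Mean consensus Dice (and GED / CM errors) per method over seeds."""
    cfg = ExperimentConfig(
        methods=tuple(methods), seeds=tuple(seeds),
        n_samples=n_samples, width=size, height=size, n_classes=2,
        label_density=label_density, split=(0.75, 0.05, 0.2),
        epochs=epochs, batch_size=batch_size, warmup_iters=warmup_iters,
        **_SIZE_FRACS,
    )
    df = run_experiment(cfg)
    agg = df[df["seed"] == "mean±std"].set_index("method")
    out = {}
    for m in methods:
        out[m] = {
            "average_dice": float(agg.loc[m, "average_dice"]),
            "total_dice": float(agg.loc[m, "total_dice"]),
            "ged": float(agg.loc[m, "ged"]),
        }
        rmse = agg.loc[m, "cm_rmse"]
        out[m]["cm_rmse"] = None if rmse is None or (isinstance(rmse, float) and np.isnan(rmse)) else float(rmse)
    return out


def single_label_study(seeds=(0, 1, 2), n_samples: int = 180,
                       epochs: int = 30, **kwargs) -> dict:
    """Spatial vs global CMs with one annotation per image.

    Per-image fusion degenerates here (the consensus of one mask is that
    mask), so only the two pooled neural models are compared.
    """
    return method_ranking_study(
        seeds=seeds, methods=("ours", "ours_global_cm"),
        n_samples=n_samples, epochs=epochs, label_density="single", **kwargs)
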