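"""Dataset persistence, experiment configuration and the comparison driver.

Datasets are written as a directory: one image file and one mask file per
(sample, annotator), plus a JSON manifest tying samples to annotator ids,
persona configurations, seeds and ground-truth paths.  Two interchangeable
backends are supported — 16-bit PNG (images are affinely quantised, scale
and offset recorded in the manifest; masks are exact 8-bit label maps) and
NIfTI (.nii.gz, exact float images).

``run_experiment`` reproduces the comparison-table layout on synthetic
data: for each requested method and seed it computes consensus Dice
(per-class, average, total), CM errors where true CMs exist, and the
generalized energy distance, then aggregates mean +/- std across seeds and
writes CSV + JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from logging.handlers import RotatingFileHandler
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .fusion import majority_vote, mean_fusion, staple_em
from .metrics import evaluate_segmentation
from .model import ModelConfig
from .synth import AnnotatedDataset, AnnotatorPersona
from .training import TrainConfig, estimate_mean_cms, predict, train

__all__ = [
    "ExperimentConfig",
    "save_dataset",
    "load_dataset",
    "split_dataset",
    "subset_dataset",
    "run_experiment",
    "setup_logging",
    "persona_to_dict",
    "persona_from_dict",
]

log = logging.getLogger("crowdseg")

KNOWN_METHODS = ("ours", "ours_no_trace", "ours_global_cm", "staple", "mean", "mode")


def setup_logging(log_file: str | Path | None = None,
                  level: int = logging.INFO) -> None:
    """Log to stderr, plus a rotating file when ``log_file`` is given."""
    log.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(h)
    if log_file is not None:
        fh = RotatingFileHandler(log_file, maxBytes=2**20, backupCount=3)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)


# ---------------------------------------------------------------------------
# persona / config (de)serialisation
# ---------------------------------------------------------------------------


def persona_to_dict(p: AnnotatorPersona) -> dict:
    d = {"kind": p.kind, "annotator_id": p.annotator_id, "strength": p.strength}
    if p.cm is not None:
        d["cm"] = np.asarray(p.cm).tolist()
    if p.swap_map is not None:
        d["swap_map"] = {str(k): v for k, v in p.swap_map.items()}
    return d


def persona_from_dict(d: dict) -> AnnotatorPersona:
    return AnnotatorPersona(
        kind=d["kind"],
        annotator_id=int(d["annotator_id"]),
        strength=float(d.get("strength", 0.0)),
        cm=np.asarray(d["cm"], float) if "cm" in d else None,
        swap_map={int(k): int(v) for k, v in d["swap_map"].items()}
        if "swap_map" in d else None,
    )


# ---------------------------------------------------------------------------
# dataset persistence
# ---------------------------------------------------------------------------


def _write_image(path: Path, arr: np.ndarray, fmt: str) -> dict:
    if fmt == "nifti":
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(arr, np.float64), np.eye(4)), path)
        return {}
    import imageio.v3 as iio

    lo, hi = float(arr.min()), float(arr.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    q = np.round((arr - lo) / scale).astype(np.uint16)
    iio.imwrite(path, q)
    return {"offset": lo, "scale": scale}


def _read_image(path: Path, meta: dict, fmt: str) -> np.ndarray:
    if fmt == "nifti":
        import nibabel as nib

        return np.asarray(nib.load(path).dataobj, dtype=np.float64)
    import imageio.v3 as iio

    q = iio.imread(path).astype(np.float64)
    return q * meta.get("scale", 1.0) + meta.get("offset", 0.0)


def _write_mask(path: Path, mask: np.ndarray, fmt: str) -> None:
    if fmt == "nifti":
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(mask, np.uint8), np.eye(4)), path)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, np.asarray(mask, np.uint8))


def _read_mask(path: Path, fmt: str) -> np.ndarray:
    if fmt == "nifti":
        import nibabel as nib

        return np.asarray(nib.load(path).dataobj).astype(np.int64)
    import imageio.v3 as iio

    return iio.imread(path).astype(np.int64)


def save_dataset(dataset: AnnotatedDataset, outdir: str | Path,
                 image_format: str = "png") -> Path:
    """Write a dataset directory with a JSON manifest; returns the manifest path."""
    if image_format not in ("png", "nifti"):
        raise ValueError("image_format must be 'png' or 'nifti'")
    ext = ".png" if image_format == "png" else ".nii.gz"
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = []
    for i, (image, masks) in enumerate(zip(dataset.images, dataset.noisy_masks)):
        entry: dict = {"id": i, "image": f"sample{i:04d}_image{ext}", "masks": {}}
        entry.update(_write_image(outdir / entry["image"], image, image_format))
        for aid, mask in masks.items():
            name = f"sample{i:04d}_annot{aid}{ext}"
            _write_mask(outdir / name, mask, image_format)
            entry["masks"][str(aid)] = name
        if dataset.truth_masks is not None:
            name = f"sample{i:04d}_truth{ext}"
            _write_mask(outdir / name, dataset.truth_masks[i], image_format)
            entry["truth"] = name
        samples.append(entry)
    manifest = {
        "n_classes": dataset.n_classes,
        "label_density": dataset.label_density,
        "image_format": image_format,
        "samples": samples,
        "true_cms": {str(k): np.asarray(v).tolist() for k, v in dataset.true_cms.items()},
        "personas": [persona_to_dict(p) for p in dataset.personas],
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_dataset(path: str | Path) -> AnnotatedDataset:
    """Load a dataset directory written by :func:`save_dataset`."""
    path = Path(path)
    manifest_path = path if path.name == "manifest.json" else path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest found at {manifest_path}")
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    fmt = manifest["image_format"]
    images, noisy, truths = [], [], []
    for entry in manifest["samples"]:
        img_path = root / entry["image"]
        if not img_path.exists():
            raise FileNotFoundError(f"sample {entry['id']}: missing image {img_path}")
        images.append(_read_image(img_path, entry, fmt))
        masks = {}
        for aid, name in entry["masks"].items():
            mask_path = root / name
            if not mask_path.exists():
                raise FileNotFoundError(
                    f"sample {entry['id']}: missing mask for annotator {aid}: {mask_path}"
                )
            masks[int(aid)] = _read_mask(mask_path, fmt)
        noisy.append(masks)
        if "truth" in entry:
            truths.append(_read_mask(root / entry["truth"], fmt))
    return AnnotatedDataset(
        images=images,
        noisy_masks=noisy,
        n_classes=int(manifest["n_classes"]),
        label_density=manifest["label_density"],
        truth_masks=truths if truths else None,
        true_cms={int(k): np.asarray(v, float)
                  for k, v in manifest.get("true_cms", {}).items()},
        personas=[persona_from_dict(d) for d in manifest.get("personas", [])],
    )


def subset_dataset(dataset: AnnotatedDataset, indices) -> AnnotatedDataset:
    indices = list(indices)
    return AnnotatedDataset(
        images=[dataset.images[i] for i in indices],
        noisy_masks=[dataset.noisy_masks[i] for i in indices],
        n_classes=dataset.n_classes,
        label_density=dataset.label_density,
        truth_masks=None if dataset.truth_masks is None
        else [dataset.truth_masks[i] for i in indices],
        true_cms=dict(dataset.true_cms),
        personas=list(dataset.personas),
    )


def split_dataset(dataset: AnnotatedDataset, fractions=(0.8, 0.1, 0.1),
                  seed: int = 0) -> tuple[AnnotatedDataset, ...]:
    """Seeded random train/val/test split by sample."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    order = np.random.default_rng(seed).permutation(len(dataset))
    bounds = np.cumsum([int(round(f * len(dataset))) for f in fractions[:-1]])
    parts = np.split(order, bounds)
    return tuple(subset_dataset(dataset, p) for p in parts)


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one comparison table on synthetic data."""

    methods: tuple[str, ...] = ("ours", "staple", "mode", "mean")
    seeds: tuple[int, ...] = (0,)
    # dataset: either a directory to load, or simulation parameters
    dataset_path: str | None = None
    n_samples: int = 120
    width: int = 32
    height: int = 32
    n_classes: int = 2
    min_size_frac: float = 1 / 5
    max_size_frac: float = 2 / 5
    image_noise_sd: float = 0.1
    personas: tuple[AnnotatorPersona, ...] = ()
    label_density: str = "dense"
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    # training
    epochs: int = 15
    batch_size: int = 8
    learning_rate: float = 1e-3
    warmup_iters: int = 30
    lambda_: float = 0.01
    encoder_channels: tuple[int, ...] = (8, 16)
    out_dir: str | None = None

    def __post_init__(self):
        if not self.methods:
            raise ValueError("need at least one method")
        if not self.seeds:
            raise ValueError("need at least one seed")
        unknown = set(self.methods) - set(KNOWN_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def _default_personas(n_classes: int) -> tuple[AnnotatorPersona, ...]:
    """Five annotators spanning the corruption types with a wide skill range.

    One systematic over-segmenter (spatially structured boundary noise), one
    class confuser and three exact-CM raters from careful (0.95) to poor
    (0.65): heterogeneous reliabilities exercise reliability weighting, and
    the structured component separates spatial from global CM models.
    """
    def cm(d):
        return np.array([[d, 1 - d], [1 - d, d]])

    if n_classes != 2:
        raise ValueError("default personas are binary; provide personas explicitly")
    return (
        AnnotatorPersona(kind="over_segmenter", annotator_id=0, strength=2),
        AnnotatorPersona(kind="class_confuser", annotator_id=1, strength=0.3),
        AnnotatorPersona(kind="cm_corruptor", annotator_id=2, cm=cm(0.95)),
        AnnotatorPersona(kind="cm_corruptor", annotator_id=3, cm=cm(0.8)),
        AnnotatorPersona(kind="cm_corruptor", annotator_id=4, cm=cm(0.65)),
    )


def _fusion_eval(method: str, ds: AnnotatedDataset):
    """Per-sample fusion consensus, mean estimated CMs, model sample sets."""
    preds, cm_sums, sample_sets = [], {}, []
    n_cm = 0
    for masks in ds.noisy_masks:
        stack = [masks[k] for k in sorted(masks)]
        if method == "mean":
            _, hard = mean_fusion(stack, n_classes=ds.n_classes)
        elif method == "mode":
            hard = majority_vote(stack, n_classes=ds.n_classes)
        else:  # staple
            state = staple_em(stack, n_classes=ds.n_classes)
            hard = state.consensus_labels
            for aid, cm in zip(sorted(masks), state.cms):
                cm_sums[aid] = cm_sums.get(aid, 0.0) + cm
            n_cm += 1
        preds.append(hard)
        sample_sets.append([hard])
    est_cms = {aid: s / n_cm for aid, s in cm_sums.items()} if n_cm else None
    return preds, est_cms, sample_sets


def _neural_eval(method: str, train_ds: AnnotatedDataset, test_ds: AnnotatedDataset,
                 cfg: ExperimentConfig, seed: int):
    lam = 0.0 if method == "ours_no_trace" else cfg.lambda_
    model_cfg = ModelConfig(
        n_classes=train_ds.n_classes,
        n_annotators=len(train_ds.annotator_ids),
        cm_mode="global" if method == "ours_global_cm" else "spatial",
        encoder_channels=tuple(cfg.encoder_channels),
    )
    train_cfg = TrainConfig(
        epochs=cfg.epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, seed=seed,
        warmup_iters=cfg.warmup_iters, lambda_=lam,
    )
    model, _ = train(train_ds, model_cfg, train_cfg)
    preds, sample_sets = [], []
    for image in test_ds.images:
        labels, probs = predict(model, image)
        preds.append(labels)
        # model "samples": each annotator's plug-in prediction argmax(A_r p)
        _, raw = model.forward_tensors(np.asarray(image))
        from .model import finish_cms

        full = finish_cms(raw, model.config).data
        per_annot = []
        for r in range(model.config.n_annotators):
            A = full[r] if full.ndim == 3 else full[0, :, :, r]
            dist = np.einsum("...ij,...j->...i", A, probs.probs)
            per_annot.append(dist.argmax(axis=-1))
        sample_sets.append(per_annot)
    est_cms = estimate_mean_cms(model, test_ds.images)
    return preds, est_cms, sample_sets


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run every (method, seed) cell and aggregate mean +/- std across seeds."""
    setup_logging()
    rows = []
    for seed in cfg.seeds:
        if cfg.dataset_path is not None:
            dataset = load_dataset(cfg.dataset_path)
        else:
            personas = cfg.personas or _default_personas(cfg.n_classes)
            gts = synth.generate_shapes(cfg.n_samples, cfg.width, cfg.height,
                                        cfg.n_classes, seed=seed,
                                        noise_sd=cfg.image_noise_sd,
                                        min_size_frac=cfg.min_size_frac,
                                        max_size_frac=cfg.max_size_frac)
            dataset = synth.build_dataset(list(gts), list(personas),
                                          label_density=cfg.label_density,
                                          seed=seed, n_classes=cfg.n_classes)
        train_ds, _, test_ds = split_dataset(dataset, cfg.split, seed=seed)
        if dataset.truth_masks is None:
            raise ValueError("experiment driver requires ground-truth masks")
        for method in cfg.methods:
            log.info("running method=%s seed=%d", method, seed)
            if method in ("mean", "mode", "staple"):
                preds, est_cms, sample_sets = _fusion_eval(method, test_ds)
            else:
                preds, est_cms, sample_sets = _neural_eval(
                    method, train_ds, test_ds, cfg, seed)
            reports = []
            for i, pred in enumerate(preds):
                truth = test_ds.truth_masks[i]
                annot = [test_ds.noisy_masks[i][k] for k in sorted(test_ds.noisy_masks[i])]
                reports.append(evaluate_segmentation(
                    pred, truth, dataset.n_classes,
                    model_samples=sample_sets[i], annotator_labels=annot,
                ))
            row: dict = {"method": method, "seed": seed}
            flats = [r.flat() for r in reports]
            for key in flats[0]:
                vals = [f[key] for f in flats if f[key] is not None]
                row[key] = float(np.mean(vals)) if vals else None
            # CM metrics against truth (defined only for cm_corruptor annotators)
            from .metrics import cm_incompetence, cm_rmse

            if est_cms is not None and dataset.true_cms:
                est = {a: est_cms[a] for a in dataset.true_cms if a in est_cms}
                row["cm_rmse"] = cm_rmse(est, dataset.true_cms)
                row["cm_incompetence"] = cm_incompetence(est, dataset.true_cms)
            else:
                row["cm_rmse"] = None
                row["cm_incompetence"] = None
            rows.append(row)
    df = pd.DataFrame(rows)
    aggs = []
    for method, grp in df.groupby("method", sort=False):
        agg = {"method": method, "seed": "mean±std"}
        for col in grp.columns:
            if col in ("method", "seed"):
                continue
            vals = grp[col].dropna()
            agg[col] = float(vals.mean()) if len(vals) else None
            agg[col + "_std"] = float(vals.std(ddof=0)) if len(vals) else None
        aggs.append(agg)
    result = pd.concat([df, pd.DataFrame(aggs)], ignore_index=True)
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_csv(out / "results.csv", index=False)
        (out / "results.json").write_text(result.to_json(orient="records", indent=2))
        (out / "config.json").write_text(json.dumps(
            dataclasses.asdict(cfg) | {
                "personas": [persona_to_dict(p) for p in
                             (cfg.personas or _default_personas(cfg.n_classes))]},
            indent=2, default=str))
    return result
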