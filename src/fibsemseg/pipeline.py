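"""End-to-end orchestration: training, full-volume prediction, experiments.

A run is described by an :class:`ExperimentConfig`; every stage draws its
randomness from a seed derived by stable hashing of the stage name with the
master seed, so runs are exactly reproducible and adding a stage does not
shift the streams of the others.

The canonical study design: several datasets (volumes) each contribute
annotated square regions; regions are split 60/20/20 into train/val/test;
a class-balanced 2.5% pixel sample from the training squares (optionally
augmented) trains the forest; performance is reported on the *full* square
regions of each split, pooled by pixel count; the smooth-threshold
postprocessing is tuned on the validation regions; finally whole volumes
are scored slice by slice and postprocessed to estimate porosity.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .classifier import (
    ForestModel,
    RFConfig,
    SearchSpace,
    predict_scores,
    random_search,
    train_forest,
)
from .features import FeatureMatrix, ScaleSpaceConfig, assemble_features, gaussian_scale_space, slice_features
from .metrics import MetricsReport, evaluate, optimize_global_threshold, porosity
from .postprocess import PostprocessConfig, apply_postprocess, tune_postprocess
from .preprocess import ImageVolume, correct_gradient
from .sampling import (
    AugmentationParams,
    RegionSpec,
    augment_features,
    sample_pixels,
    select_regions,
    split_regions,
)
from .synthetic import SyntheticConfig, generate_structure, render_fibsem

__all__ = [
    "ExperimentConfig",
    "Dataset",
    "TrainingResult",
    "stage_seed",
    "build_synthetic_dataset",
    "run_training",
    "run_prediction",
    "learning_curve",
]


def stage_seed(master: int, stage: str) -> int:
    """Derive a stage seed by hashing the stage name with the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass(frozen=True)
class ExperimentConfig:
    """All tunables of a full run, with the study defaults."""

    scale_space: ScaleSpaceConfig = field(default_factory=ScaleSpaceConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    augment: AugmentationParams | None = None
    search: SearchSpace | None = None
    post: PostprocessConfig = field(
        default_factory=lambda: PostprocessConfig(sigma_xy=2.0, threshold=0.5)
    )
    sample_fraction: float = 0.025
    balanced: bool = True
    region_size: int = 256
    nbhd_size: int = 384
    nbhd_depth: int = 7
    regions_per_dataset: int = 100
    split_counts: tuple[int, int, int] = (60, 20, 20)
    tune_post: bool = True
    master_seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Dataset:
    """One volume with its annotation regions and per-region label masks."""

    name: str
    volume: ImageVolume
    regions: list[RegionSpec]
    labels: list[np.ndarray]
    structure: np.ndarray | None = None  # ground truth, synthetic data only

    def split(self, tag: str) -> list[int]:
        return [i for i, r in enumerate(self.regions) if r.split == tag]


@dataclass
class TrainingResult:
    """Everything a training run produced."""

    model: ForestModel
    augment: AugmentationParams
    reports_raw: dict[str, MetricsReport]
    reports_post: dict[str, MetricsReport]
    post: PostprocessConfig
    search_log: pd.DataFrame | None
    config_hash: str
    region_scores: dict[str, list[tuple[str, np.ndarray, np.ndarray]]]
    # split -> list of (dataset name, score image, label image) per region


def build_synthetic_dataset(
    syn: SyntheticConfig,
    cfg: ExperimentConfig,
    name: str = "synthetic",
    split_counts: tuple[int, int, int] | None = None,
    seed: int | None = None,
) -> Dataset:
    """Simulate a volume, gradient-correct it, and annotate random regions.

    Ground-truth labels for each square region are read off the generated
    phase map, standing in for expert manual segmentation.  Squares are
    placed without mutual overlap so no labelled pixel can appear in two
    data splits (on small synthetic volumes overlap would otherwise be
    likely).
    """
    seed = stage_seed(cfg.master_seed, f"regions:{name}") if seed is None else seed
    structure = generate_structure(syn)
    image = render_fibsem(structure, syn)
    image = correct_gradient(image)
    counts = split_counts or cfg.split_counts
    regions = select_regions(
        structure.shape,
        n=sum(counts),
        seed=seed,
        size=cfg.region_size,
        nbhd_size=cfg.nbhd_size,
        nbhd_depth=cfg.nbhd_depth,
        dataset=name,
        exclusive=True,
    )
    regions = split_regions(regions, counts, seed=seed + 1)
    labels = [
        structure[r.x0 : r.x0 + r.size, r.y0 : r.y0 + r.size, r.z] for r in regions
    ]
    return Dataset(name=name, volume=image, regions=regions, labels=labels, structure=structure)


def _filtered_volumes(datasets: list[Dataset], cfg: ExperimentConfig) -> dict[str, list[np.ndarray]]:
    return {d.name: gaussian_scale_space(d.volume, cfg.scale_space) for d in datasets}


def _sampled_features(
    datasets: list[Dataset],
    filtered: dict[str, list[np.ndarray]],
    split: str,
    cfg: ExperimentConfig,
    seed: int,
    region_subset: dict[str, list[int]] | None = None,
) -> FeatureMatrix:
    """Class-balanced pixel sample of one split, pooled across datasets."""
    blocks, labels = [], []
    for d in datasets:
        idx = region_subset[d.name] if region_subset is not None else d.split(split)
        if not idx:
            continue
        sample = sample_pixels(
            [d.regions[i] for i in idx],
            [d.labels[i] for i in idx],
            fraction=cfg.sample_fraction,
            balanced=cfg.balanced,
            seed=stage_seed(seed, f"sample:{d.name}:{split}"),
        )
        fm = assemble_features(filtered[d.name], sample.coords, cfg.scale_space, sample.labels)
        blocks.append(fm.values)
        labels.append(sample.labels)
    if not blocks:
        raise ValueError(f"no regions tagged {split!r}")
    return FeatureMatrix(
        np.concatenate(blocks), cfg.scale_space.columns(), np.concatenate(labels)
    )


def _score_regions(
    model: ForestModel,
    datasets: list[Dataset],
    filtered: dict[str, list[np.ndarray]],
    split: str,
    cfg: ExperimentConfig,
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Score every pixel of the full square regions of one split."""
    out = []
    for d in datasets:
        for i in d.split(split):
            r = d.regions[i]
            fm = assemble_features(filtered[d.name], r.pixel_coords(), cfg.scale_space)
            scores = predict_scores(model, fm.values).reshape(r.size, r.size)
            out.append((d.name, scores, np.asarray(d.labels[i])))
    return out


def _pooled_report(
    scored: list[tuple[str, np.ndarray, np.ndarray]],
    threshold: float = 0.5,
    post: PostprocessConfig | None = None,
) -> MetricsReport:
    """Pixel-pooled metrics over full regions, raw or postprocessed."""
    labels = np.concatenate([lab.ravel() for _, _, lab in scored])
    scores = np.concatenate([s.ravel() for _, s, _ in scored])
    if post is None:
        preds = (scores >= threshold).astype(np.uint8)
    else:
        preds = np.concatenate([apply_postprocess(s, post).ravel() for _, s, _ in scored])
    return evaluate(labels, preds, scores=scores)


def run_training(datasets: list[Dataset], cfg: ExperimentConfig) -> TrainingResult:
    """Train the forest and evaluate it on the full regions of every split.

    Stages: scale-space filtering, per-split balanced pixel sampling,
    optional augmentation / random hyperparameter search, forest training,
    full-region scoring, and (optionally) postprocessing tuning against the
    validation regions.
    """
    filtered = _filtered_volumes(datasets, cfg)
    seed = cfg.master_seed

    train_fm = _sampled_features(datasets, filtered, "train", cfg, stage_seed(seed, "train-sample"))
    rf_cfg, aug = cfg.rf, cfg.augment or AugmentationParams()
    search_log = None
    if cfg.search is not None:
        val_fm = _sampled_features(datasets, filtered, "val", cfg, stage_seed(seed, "val-sample"))
        rf_cfg, aug, search_log = random_search(
            train_fm,
            val_fm,
            cfg.search,
            augment=cfg.augment is not None,
            seed=stage_seed(seed, "search"),
        )
    if aug.sigma_a > 0 or aug.sigma_b > 0:
        train_fm = augment_features(train_fm, aug, seed=stage_seed(seed, "augment"))
    model = train_forest(train_fm, rf_cfg, seed=stage_seed(seed, "forest"))

    region_scores = {
        split: _score_regions(model, datasets, filtered, split, cfg)
        for split in ("train", "val", "test")
    }
    reports_raw = {split: _pooled_report(scored) for split, scored in region_scores.items()}

    post = cfg.post
    if cfg.tune_post:
        val = region_scores["val"]
        post, _ = tune_postprocess(
            [s for _, s, _ in val],
            [lab for _, _, lab in val],
            base=cfg.post,
            start=(cfg.post.sigma_xy, cfg.post.threshold),
        )
    reports_post = {
        split: _pooled_report(scored, post=post) for split, scored in region_scores.items()
    }
    return TrainingResult(
        model=model,
        augment=aug,
        reports_raw=reports_raw,
        reports_post=reports_post,
        post=post,
        search_log=search_log,
        config_hash=cfg.config_hash(),
        region_scores=region_scores,
    )


def run_prediction(
    model: ForestModel,
    volume: ImageVolume,
    cfg: ExperimentConfig,
    post: PostprocessConfig | None = None,
    batch_slices: int = 8,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Score every voxel of a volume and return the final segmentation.

    Slices are scored in batches (features near z boundaries use the
    mirror-extended filtered volumes); scores are then postprocessed and
    the porosity of the resulting mask reported.  The result is independent
    of the batch size because slices never share state.
    """
    filtered = gaussian_scale_space(volume, cfg.scale_space)
    nx, ny, nz = volume.shape
    scores = np.empty((nx, ny, nz))
    for z0 in range(0, nz, batch_slices):
        for z in range(z0, min(z0 + batch_slices, nz)):
            fm = slice_features(filtered, z, cfg.scale_space)
            scores[:, :, z] = predict_scores(model, fm).reshape(nx, ny)
    mask = apply_postprocess(scores, post or cfg.post)
    return mask, porosity(mask), scores


def global_threshold_baseline(
    datasets: list[Dataset], cfg: ExperimentConfig
) -> dict[str, dict[str, float]]:
    """Per-dataset global-threshold baseline, the no-learning comparison.

    For each dataset the threshold is optimized on the pooled train+val
    square regions (there are no hyperparameters, so the two sets can be
    combined) and evaluated on the test regions.
    """
    out: dict[str, dict[str, float]] = {}
    for d in datasets:
        def _patches(tags: tuple[str, ...]) -> tuple[list[np.ndarray], list[np.ndarray]]:
            imgs, labs = [], []
            for i, r in enumerate(d.regions):
                if r.split in tags:
                    imgs.append(d.volume.data[r.x0 : r.x0 + r.size, r.y0 : r.y0 + r.size, r.z])
                    labs.append(np.asarray(d.labels[i]))
            return imgs, labs

        fit_imgs, fit_labs = _patches(("train", "val"))
        thr, fit_miou = optimize_global_threshold(fit_imgs, fit_labs)
        test_imgs, test_labs = _patches(("test",))
        test_pred = [(img >= thr).astype(np.uint8) for img in test_imgs]
        report = evaluate(
            np.concatenate([l.ravel() for l in test_labs]),
            np.concatenate([p.ravel() for p in test_pred]),
        )
        out[d.name] = {
            "threshold": thr,
            "fit_miou": fit_miou,
            "test_miou": report.miou,
            "test_accuracy": report.accuracy,
        }
    return out


def learning_curve(
    datasets: list[Dataset],
    cfg: ExperimentConfig,
    sizes: list[int],
    repeats: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Test performance versus the number of training regions.

    For each size, ``repeats`` forests are trained on random subsets of the
    training regions (fixed hyperparameters, fresh pixel samples) and the
    pooled test mIoU and accuracy recorded; the table reports mean and
    standard deviation per size.
    """
    filtered = _filtered_volumes(datasets, cfg)
    train_idx = {d.name: d.split("train") for d in datasets}
    n_train = sum(len(v) for v in train_idx.values())
    if max(sizes) > n_train:
        raise ValueError(f"requested {max(sizes)} training regions, only {n_train} available")
    seed = stage_seed(cfg.master_seed, "learning-curve") if seed is None else seed
    rng = np.random.default_rng(seed)

    flat = [(name, i) for name, idxs in train_idx.items() for i in idxs]
    rows = []
    for size in sizes:
        mious, accs = [], []
        for rep in range(repeats):
            pick = rng.choice(len(flat), size=size, replace=False)
            subset: dict[str, list[int]] = {d.name: [] for d in datasets}
            for j in pick:
                name, i = flat[j]
                subset[name].append(i)
            fm = _sampled_features(
                datasets, filtered, "train", cfg,
                int(rng.integers(0, 2**31)), region_subset=subset,
            )
            if cfg.augment is not None:
                fm = augment_features(fm, cfg.augment, seed=int(rng.integers(0, 2**31)))
            model = train_forest(fm, cfg.rf, seed=int(rng.integers(0, 2**31)))
            scored = _score_regions(model, datasets, filtered, "test", cfg)
            report = _pooled_report(scored)
            mious.append(report.miou)
            accs.append(report.accuracy)
        rows.append(
            {
                "n_regions": size,
                "n_repeats": repeats,
                "miou_mean": float(np.mean(mious)),
                "miou_sd": float(np.std(mious, ddof=1)) if repeats > 1 else 0.0,
                "accuracy_mean": float(np.mean(accs)),
                "accuracy_sd": float(np.std(accs, ddof=1)) if repeats > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
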