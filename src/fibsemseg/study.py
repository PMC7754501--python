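"""The built-in shine-through recovery study.

A scaled-down, fully synthetic replication of the segmentation workflow:
three volumes of 128 x 128 x 40 voxels at porosities 0.22, 0.30 and 0.45
(the nominal porosities of the three film compositions), rendered with
shine-through decay depth 3 slices, an x intensity gradient, and noise of
standard deviation 0.05.  Twenty annotated square regions (64 px, across
the three volumes) train a 51-tree forest; six regions each are held out
for validation (postprocessing tuning) and testing.  The study reports the
recovered whole-volume porosities, the pooled and per-volume test mIoU, and
the per-volume global-threshold baseline for comparison.

The problem sizes are chosen so the whole study runs in a few minutes on a
single CPU while preserving the structure of the full workflow; they are
the package's demonstration defaults, not tuned quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import RFConfig
from .metrics import evaluate
from .pipeline import (
    Dataset,
    ExperimentConfig,
    build_synthetic_dataset,
    global_threshold_baseline,
    run_prediction,
    run_training,
    stage_seed,
)
from .postprocess import PostprocessConfig
from .synthetic import SyntheticConfig

__all__ = ["StudyConfig", "StudyResult", "run_study"]

#: nominal porosities of the three film compositions
STUDY_POROSITIES = (0.22, 0.30, 0.45)

#: training regions contributed by each volume (20 in total)
STUDY_TRAIN_COUNTS = (7, 7, 6)


@dataclass(frozen=True)
class StudyConfig:
    """Conditions of the synthetic recovery study."""

    porosities: tuple[float, ...] = STUDY_POROSITIES
    train_counts: tuple[int, ...] = STUDY_TRAIN_COUNTS
    val_count: int = 2  # per volume
    test_count: int = 2  # per volume
    dims: tuple[int, int, int] = (128, 128, 40)
    shine_decay_depth: float = 3.0
    noise_sd: float = 0.05
    correlation_length: float = 4.0
    gradient_slope: float = 0.0008
    region_size: int = 64
    nbhd_size: int = 96
    n_trees: int = 51
    seed: int = 0

    def experiment(self) -> ExperimentConfig:
        return ExperimentConfig(
            rf=RFConfig(n_trees=self.n_trees, n_features_per_tree=30, min_leaf_size=10),
            post=PostprocessConfig(sigma_xy=2.0, threshold=0.5),
            region_size=self.region_size,
            nbhd_size=self.nbhd_size,
            tune_post=True,
            master_seed=self.seed,
        )


@dataclass
class StudyResult:
    """Outcome of one study run."""

    porosity_true: dict[str, float]
    porosity_recovered: dict[str, float]
    test_miou: float
    test_accuracy: float
    test_miou_per_volume: dict[str, float]
    baseline: dict[str, dict[str, float]]
    post_sigma_xy: float
    post_threshold: float
    n_train_regions: int
    datasets: list[Dataset] = field(repr=False, default_factory=list)

    @property
    def porosity_errors(self) -> dict[str, float]:
        return {
            k: self.porosity_recovered[k] - self.porosity_true[k]
            for k in self.porosity_true
        }


def build_study_datasets(cfg: StudyConfig) -> list[Dataset]:
    """The three synthetic volumes with their annotated, split regions."""
    exp = cfg.experiment()
    datasets = []
    for i, (phi, n_train) in enumerate(zip(cfg.porosities, cfg.train_counts)):
        name = f"phi{int(round(phi * 100)):02d}"
        syn = SyntheticConfig(
            dims=cfg.dims,
            target_porosity=phi,
            correlation_length=cfg.correlation_length,
            shine_decay_depth=cfg.shine_decay_depth,
            gradient_slope=cfg.gradient_slope,
            noise_sd=cfg.noise_sd,
            seed=stage_seed(cfg.seed, f"volume:{name}"),
        )
        datasets.append(
            build_synthetic_dataset(
                syn,
                exp,
                name=name,
                split_counts=(n_train, cfg.val_count, cfg.test_count),
            )
        )
    return datasets


def run_study(cfg: StudyConfig | None = None, seed: int | None = None) -> StudyResult:
    """Run the full synthetic recovery study.

    Trains one forest on the pooled training regions of the three volumes,
    tunes postprocessing on the validation regions, evaluates on the test
    regions, segments each whole volume to recover its porosity, and fits
    the per-volume global-threshold baseline.
    """
    cfg = cfg or StudyConfig()
    if seed is not None:
        cfg = StudyConfig(**{**cfg.__dict__, "seed": seed})
    exp = cfg.experiment()
    datasets = build_study_datasets(cfg)
    result = run_training(datasets, exp)

    porosity_true, porosity_rec = {}, {}
    for d in datasets:
        assert d.structure is not None
        porosity_true[d.name] = float((d.structure == 0).mean())
        _mask, phi, _ = run_prediction(result.model, d.volume, exp, post=result.post)
        porosity_rec[d.name] = phi

    per_volume = {}
    for d in datasets:
        scored = [(n, s, l) for n, s, l in result.region_scores["test"] if n == d.name]
        labels = np.concatenate([l.ravel() for _, _, l in scored])
        preds = np.concatenate(
            [(s >= 0.5).astype(np.uint8).ravel() for _, s, _ in scored]
        )
        per_volume[d.name] = evaluate(labels, preds).miou

    baseline = global_threshold_baseline(datasets, exp)
    test_report = result.reports_raw["test"]
    return StudyResult(
        porosity_true=porosity_true,
        porosity_recovered=porosity_rec,
        test_miou=test_report.miou,
        test_accuracy=test_report.accuracy,
        test_miou_per_volume=per_volume,
        baseline=baseline,
        post_sigma_xy=result.post.sigma_xy,
        post_threshold=result.post.threshold,
        n_train_regions=sum(cfg.train_counts),
        datasets=datasets,
    )
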