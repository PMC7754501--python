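"""Random-forest voter over scale-space features.

The forest is an ensemble of CART trees (Gini impurity splits), each trained
on a bootstrap replica of the sample and restricted to its own random subset
of feature columns.  Note the subspace is drawn *per tree*, not per split:
every split inside a tree sees the same candidate features.  Each tree casts
a hard class vote at prediction time and the score is the average vote — an
integer multiple of 1/n_trees interpretable as the probability of the solid
class.  An odd tree count makes thresholding at 0.5 tie-free.

Hyperparameters (features per tree, minimum leaf size, and optionally the
augmentation strengths) are tuned by random search against validation mIoU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix
from .metrics import miou as _miou
from .metrics import accuracy as _accuracy
from .sampling import AugmentationParams, augment_features

__all__ = [
    "RFConfig",
    "SearchSpace",
    "ForestModel",
    "train_forest",
    "predict_scores",
    "random_search",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters.

    Defaults are the best augmented-search configuration: 151 trees, 28
    features per tree, minimum leaf size 14.
    """

    n_trees: int = 151
    n_features_per_tree: int = 28
    min_leaf_size: int = 14
    per_tree_features: bool = True  # False: per-split subsampling instead
    bootstrap: bool = True

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.n_trees % 2 == 0:
            raise ValueError("n_trees must be odd and >= 1 to avoid voting ties")
        if self.n_features_per_tree < 1:
            raise ValueError("n_features_per_tree must be >= 1")
        if self.min_leaf_size < 1:
            raise ValueError("min_leaf_size must be >= 1")


@dataclass(frozen=True)
class SearchSpace:
    """Random-search ranges (inclusive) and priors for hyperparameters.

    Feature counts and leaf sizes are drawn uniformly over their ranges;
    when augmentation is searched, sigma_a and sigma_b are drawn from an
    exponential distribution with the given mean.
    """

    nf_range: tuple[int, int] = (10, 40)
    nmls_range: tuple[int, int] = (10, 50)
    n_trees: int = 151
    sigma_mean: float = 0.01
    budget: int = 1500

    def __post_init__(self) -> None:
        if self.nf_range[0] > self.nf_range[1] or self.nmls_range[0] > self.nmls_range[1]:
            raise ValueError("empty search range")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")


@dataclass
class ForestModel:
    """A trained forest: per-tree estimators, their feature subsets, and the
    feature column map they were trained against."""

    trees: list[DecisionTreeClassifier]
    feature_subsets: list[np.ndarray]
    columns: list[tuple[int, float]]
    config: RFConfig
    seed: int | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def train_forest(
    train: FeatureMatrix, cfg: RFConfig | None = None, seed: int = 0
) -> ForestModel:
    """Train the forest on a labelled feature matrix.

    Each tree gets an independent bootstrap resample of the rows and (in the
    default per-tree mode) its own uniformly drawn subset of feature
    columns without replacement.
    """
    cfg = cfg or RFConfig()
    if train.labels is None:
        raise ValueError("training data must be labelled")
    classes = np.unique(train.labels)
    if classes.size < 2:
        raise ValueError("training data contain a single class")
    n, p = train.values.shape
    if n < 2:
        raise ValueError("need at least two training rows")
    if cfg.n_features_per_tree > p:
        raise ValueError(f"n_features_per_tree={cfg.n_features_per_tree} exceeds {p} features")

    rng = np.random.default_rng(seed)
    trees: list[DecisionTreeClassifier] = []
    subsets: list[np.ndarray] = []
    for _ in range(cfg.n_trees):
        rows = rng.integers(0, n, size=n) if cfg.bootstrap else np.arange(n)
        if cfg.per_tree_features:
            cols = np.sort(rng.choice(p, size=cfg.n_features_per_tree, replace=False))
            max_features = None
        else:
            cols = np.arange(p)
            max_features = cfg.n_features_per_tree
        tree = DecisionTreeClassifier(
            criterion="gini",
            min_samples_leaf=cfg.min_leaf_size,
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(train.values[rows][:, cols], train.labels[rows])
        trees.append(tree)
        subsets.append(cols)
    return ForestModel(trees, subsets, list(train.columns), cfg, seed=seed)


def predict_scores(model: ForestModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Average hard vote per row: the solid-class probability score.

    Every returned score is an integer multiple of 1/n_trees.  When a
    FeatureMatrix is passed, its column map must match the model's.
    """
    if isinstance(features, FeatureMatrix):
        if list(features.columns) != list(model.columns):
            raise ValueError("feature column map does not match the model's")
        values = features.values
    else:
        values = np.asarray(features)
        if values.ndim != 2 or values.shape[1] != len(model.columns):
            raise ValueError(
                f"expected {len(model.columns)} feature columns, got shape {values.shape}"
            )
    votes = np.zeros(values.shape[0], dtype=np.float64)
    for tree, cols in zip(model.trees, model.feature_subsets):
        votes += tree.predict(values[:, cols]).astype(np.float64)
    return votes / model.n_trees


def random_search(
    train: FeatureMatrix,
    val: FeatureMatrix,
    space: SearchSpace | None = None,
    augment: bool = False,
    seed: int = 0,
) -> tuple[RFConfig, AugmentationParams, pd.DataFrame]:
    """Random hyperparameter search maximizing validation-set mIoU.

    Each iteration draws a configuration (uniform integers over the nf and
    nmls ranges; exponential sigma_a, sigma_b when ``augment``), optionally
    augments the training features, trains a forest and scores the
    validation rows at threshold 0.5.  Returns the argmax configuration and
    the full search log.
    """
    space = space or SearchSpace()
    if val.labels is None:
        raise ValueError("validation data must be labelled")
    rng = np.random.default_rng(seed)
    rows = []
    best: tuple[float, RFConfig, AugmentationParams] | None = None
    for it in range(space.budget):
        cfg = RFConfig(
            n_trees=space.n_trees,
            n_features_per_tree=int(rng.integers(space.nf_range[0], space.nf_range[1] + 1)),
            min_leaf_size=int(rng.integers(space.nmls_range[0], space.nmls_range[1] + 1)),
        )
        if augment:
            aug = AugmentationParams(
                sigma_a=float(rng.exponential(space.sigma_mean)),
                sigma_b=float(rng.exponential(space.sigma_mean)),
            )
        else:
            aug = AugmentationParams()
        it_seed = int(rng.integers(0, 2**31 - 1))
        train_it = augment_features(train, aug, seed=it_seed) if augment else train
        model = train_forest(train_it, cfg, seed=it_seed)
        pred = (predict_scores(model, val) >= 0.5).astype(np.uint8)
        val_miou = _miou(val.labels, pred)
        val_acc = _accuracy(val.labels, pred)
        rows.append(
            {
                "iteration": it,
                "nf": cfg.n_features_per_tree,
                "nmls": cfg.min_leaf_size,
                "sigma_a": aug.sigma_a,
                "sigma_b": aug.sigma_b,
                "seed": it_seed,
                "val_miou": val_miou,
                "val_accuracy": val_acc,
            }
        )
        if best is None or val_miou > best[0]:
            best = (val_miou, cfg, aug)
    assert best is not None
    return best[1], best[2], pd.DataFrame(rows)


def save_model(path: str | Path, model: ForestModel) -> None:
    """Persist a trained forest (trees, feature subsets and column map)."""
    joblib.dump(model, Path(path))


def load_model(path: str | Path) -> ForestModel:
    model = joblib.load(Path(path))
    if not isinstance(model, ForestModel):
        raise TypeError(f"{path} does not contain a ForestModel")
    return model
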