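"""Segmentation evaluation: IoU, Dice, accuracy, cross-entropy, porosity.

Classes are encoded 0 = pore, 1 = solid throughout.  Per-class intersection
over union (Jaccard index) and its class mean mIoU are the primary model
selection metrics; Dice and binary cross-entropy are monotonically related
alternatives kept for reporting.  Porosity is the pore-phase volume
fraction; its confidence interval across annotation regions uses a normal
approximation, treating region porosities as independent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MetricsReport",
    "iou",
    "miou",
    "accuracy",
    "dice",
    "bce",
    "porosity",
    "porosity_ci",
    "optimize_global_threshold",
    "evaluate",
]

#: z quantile for the 95% two-sided normal interval
Z_95 = 1.959964

#: score clipping for cross-entropy
BCE_EPS = 1e-12


@dataclass
class MetricsReport:
    """Bundle of segmentation metrics for one evaluation set."""

    iou_pore: float
    iou_solid: float
    miou: float
    accuracy: float
    dsc_pore: float
    dsc_solid: float
    bce: float | None = None
    porosity_manual: float | None = None
    porosity_auto: float | None = None
    n_pixels: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps({k: v for k, v in asdict(self).items() if v is not None}, indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s


def _check_masks(manual: np.ndarray, auto: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    manual, auto = np.asarray(manual), np.asarray(auto)
    if manual.shape != auto.shape:
        raise ValueError(f"shape mismatch: {manual.shape} vs {auto.shape}")
    if not np.isin(manual, (0, 1)).all() or not np.isin(auto, (0, 1)).all():
        raise ValueError("masks must be binary with classes 0 (pore) and 1 (solid)")
    return manual, auto


def iou(manual: np.ndarray, auto: np.ndarray, cls: int = 1) -> float:
    """Intersection over union of one class; 1.0 if the class is absent from both."""
    manual, auto = _check_masks(manual, auto)
    m, a = manual == cls, auto == cls
    union = np.logical_or(m, a).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(m, a).sum() / union)


def miou(manual: np.ndarray, auto: np.ndarray) -> float:
    """Class-symmetric mean of the pore and solid IoU."""
    return 0.5 * (iou(manual, auto, 0) + iou(manual, auto, 1))


def accuracy(manual: np.ndarray, auto: np.ndarray) -> float:
    """Proportion of pixels assigned the correct class."""
    manual, auto = _check_masks(manual, auto)
    return float((manual == auto).mean())


def dice(manual: np.ndarray, auto: np.ndarray, cls: int = 1) -> float:
    """Dice similarity coefficient 2|M n A| / (|M| + |A|); 1.0 if both empty."""
    manual, auto = _check_masks(manual, auto)
    m, a = manual == cls, auto == cls
    denom = m.sum() + a.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(m, a).sum() / denom)


def bce(labels: np.ndarray, scores: np.ndarray) -> float:
    """Binary cross-entropy of solid-probability scores against {0,1} labels.

    Scores are clipped to [eps, 1 - eps] before taking logs; the returned
    value is the conventional non-negative mean negative log-likelihood.
    """
    y = np.asarray(labels, dtype=np.float64).ravel()
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.shape != s.shape:
        raise ValueError("labels and scores must have the same length")
    if (s < 0).any() or (s > 1).any():
        raise ValueError("scores must lie in [0, 1]")
    s = np.clip(s, BCE_EPS, 1.0 - BCE_EPS)
    return float(-np.mean(y * np.log(s) + (1.0 - y) * np.log(1.0 - s)))


def porosity(mask: np.ndarray) -> float:
    """Pore volume fraction of a binary mask (class 0 = pore)."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    return float((mask == 0).mean())


def porosity_ci(
    per_region: np.ndarray | list[float], level: float = 0.95
) -> tuple[float, float, float]:
    """Mean porosity with a normal-approximation confidence interval.

    Treats the per-region porosities as independent observations:
    mean +/- z * sd / sqrt(n), z = 1.959964 at the default 95% level.
    """
    vals = np.asarray(per_region, dtype=np.float64)
    if vals.size < 2:
        raise ValueError("need at least two region porosities for an interval")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    from scipy.stats import norm

    z = Z_95 if level == 0.95 else float(norm.ppf(0.5 + level / 2.0))
    mean = float(vals.mean())
    half = z * float(vals.std(ddof=1)) / np.sqrt(vals.size)
    return mean, mean - half, mean + half


def optimize_global_threshold(
    images: np.ndarray | list[np.ndarray],
    labels: np.ndarray | list[np.ndarray],
    step: float = 1.0 / 1024,
) -> tuple[float, float]:
    """Best single intensity threshold by exhaustive grid search on mIoU.

    Pixels with intensity strictly below the threshold are labelled pore.
    All thresholds k*step for k = 0 .. 1/step are evaluated on the pooled
    input via per-class intensity histograms, and the first maximizer is
    returned together with its mIoU.  This is the no-learning baseline the
    classifier is compared against.
    """
    if isinstance(images, (list, tuple)):
        intens = np.concatenate([np.asarray(a).ravel() for a in images])
        labs = np.concatenate([np.asarray(a).ravel() for a in labels])
    else:
        intens = np.asarray(images).ravel()
        labs = np.asarray(labels).ravel()
    if intens.size == 0:
        raise ValueError("empty input")
    if intens.shape != labs.shape:
        raise ValueError("images and labels must have the same pixel count")
    if (intens < 0).any() or (intens > 1).any():
        raise ValueError("intensities must lie in [0, 1]")

    n_steps = int(round(1.0 / step))
    # bin m = floor(I / step): I < k*step  <=>  m < k, so cumulative
    # histograms give the pore-predicted counts at every threshold at once
    bins = np.minimum((intens / step).astype(np.int64), n_steps)
    hist0 = np.bincount(bins[labs == 0], minlength=n_steps + 1)
    hist1 = np.bincount(bins[labs == 1], minlength=n_steps + 1)
    below0 = np.concatenate([[0], np.cumsum(hist0)])[: n_steps + 1]
    below1 = np.concatenate([[0], np.cumsum(hist1)])[: n_steps + 1]
    n0, n1 = int((labs == 0).sum()), int((labs == 1).sum())

    tp0 = below0  # true pore predicted pore
    fp0 = below1
    fn0 = n0 - below0
    tp1 = (n1 - below1).astype(np.float64)
    fp1 = n0 - below0
    fn1 = below1

    with np.errstate(invalid="ignore", divide="ignore"):
        iou0 = np.where(tp0 + fp0 + fn0 > 0, tp0 / (tp0 + fp0 + fn0), 1.0)
        iou1 = np.where(tp1 + fp1 + fn1 > 0, tp1 / (tp1 + fp1 + fn1), 1.0)
    mious = 0.5 * (iou0 + iou1)
    k = int(np.argmax(mious))
    return k * step, float(mious[k])


def evaluate(
    manual: np.ndarray,
    auto: np.ndarray,
    scores: np.ndarray | None = None,
) -> MetricsReport:
    """Full metrics report for one manual/automatic segmentation pair."""
    report = MetricsReport(
        iou_pore=iou(manual, auto, 0),
        iou_solid=iou(manual, auto, 1),
        miou=miou(manual, auto),
        accuracy=accuracy(manual, auto),
        dsc_pore=dice(manual, auto, 0),
        dsc_solid=dice(manual, auto, 1),
        porosity_manual=porosity(manual),
        porosity_auto=porosity(auto),
        n_pixels=int(np.asarray(manual).size),
    )
    if scores is not None:
        report.bce = bce(np.asarray(manual).ravel(), np.asarray(scores).ravel())
    return report
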