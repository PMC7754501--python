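"""Annotation-region selection, data splitting and pixel sampling.

Manual (or synthetic ground-truth) annotation happens on small square
regions picked at random positions in random slices.  Each square sits at
the centre of a larger neighbourhood that extends three slices in both
directions, so regions are only placed where the full neighbourhood fits
inside the volume.  Regions are split into train/validation/test sets, and
a small class-balanced fraction of their pixels is drawn for learning
(adjacent pixels are strongly correlated, so dense sampling adds little).

Feature-space augmentation: random affine intensity transforms
``I* = a + b I`` with ``a ~ N(0, sigma_a)``, ``b ~ N(1, sigma_b)`` drawn
per sample.  Because feature extraction is linear, the transform is applied
directly to the precomputed feature vectors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .features import FeatureMatrix

__all__ = [
    "RegionSpec",
    "AugmentationParams",
    "PixelSample",
    "select_regions",
    "split_regions",
    "sample_pixels",
    "augment_features",
    "save_regions",
    "load_regions",
]


@dataclass(frozen=True)
class RegionSpec:
    """A square annotation region and its extraction neighbourhood.

    Coordinates are 0-based and half-open: the square covers
    ``[x0, x0+size) x [y0, y0+size)`` in slice ``z``.  The neighbourhood is
    centred on the square, ``nbhd_size`` pixels wide and ``nbhd_depth``
    slices deep (depth 7 = the slice itself plus three on each side).
    """

    x0: int
    y0: int
    z: int
    size: int = 256
    nbhd_size: int = 384
    nbhd_depth: int = 7
    dataset: str = ""
    split: str | None = None  # train / val / test

    def __post_init__(self) -> None:
        if self.size < 1 or self.nbhd_size < self.size:
            raise ValueError("neighbourhood must contain the square region")
        if self.nbhd_depth < 1 or self.nbhd_depth % 2 == 0:
            raise ValueError("neighbourhood depth must be odd and positive")

    @property
    def margin(self) -> int:
        return (self.nbhd_size - self.size) // 2

    @property
    def half_depth(self) -> int:
        return (self.nbhd_depth - 1) // 2

    def pixel_coords(self) -> np.ndarray:
        """(size^2, 3) array of the absolute (x, y, z) of every square pixel."""
        xs, ys = np.meshgrid(
            np.arange(self.x0, self.x0 + self.size),
            np.arange(self.y0, self.y0 + self.size),
            indexing="ij",
        )
        zs = np.full(xs.size, self.z)
        return np.column_stack([xs.ravel(), ys.ravel(), zs])


@dataclass(frozen=True)
class AugmentationParams:
    """Standard deviations of the random affine intensity transform."""

    sigma_a: float = 0.0
    sigma_b: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_a < 0 or self.sigma_b < 0:
            raise ValueError("augmentation standard deviations must be >= 0")


@dataclass
class PixelSample:
    """Sampled pixel coordinates with labels and originating regions."""

    coords: np.ndarray  # (n, 3) int
    labels: np.ndarray  # (n,) in {0, 1}
    region_index: np.ndarray  # (n,) index into the region list


def select_regions(
    shape: tuple[int, int, int],
    n: int,
    seed: int | np.random.Generator,
    size: int = 256,
    nbhd_size: int = 384,
    nbhd_depth: int = 7,
    dataset: str = "",
    exclusive: bool = False,
    max_tries: int = 10000,
) -> list[RegionSpec]:
    """Draw n regions uniformly over all admissible placements.

    A placement is admissible when the full neighbourhood lies inside the
    volume; e.g. with 200 slices and depth-7 neighbourhoods the square's
    slice index ranges over [3, 196].  With ``exclusive=True`` candidate
    placements whose *squares* would share pixels with an already accepted
    region are rejected and redrawn — on small volumes overlapping squares
    would leak labelled pixels between data splits.
    """
    nx, ny, nz = shape
    half_depth = (nbhd_depth - 1) // 2
    margin = (nbhd_size - size) // 2
    if nbhd_size > nx or nbhd_size > ny or nbhd_depth > nz:
        raise ValueError(
            f"volume {shape} cannot host a {nbhd_size}x{nbhd_size}x{nbhd_depth} neighbourhood"
        )
    rng = np.random.default_rng(seed)
    regions: list[RegionSpec] = []
    tries = 0
    while len(regions) < n:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n} non-overlapping {size}x{size} squares "
                f"in volume {shape} after {max_tries} tries"
            )
        tries += 1
        ox = int(rng.integers(0, nx - nbhd_size + 1))
        oy = int(rng.integers(0, ny - nbhd_size + 1))
        z = int(rng.integers(half_depth, nz - half_depth))
        cand = RegionSpec(
            x0=ox + margin,
            y0=oy + margin,
            z=z,
            size=size,
            nbhd_size=nbhd_size,
            nbhd_depth=nbhd_depth,
            dataset=dataset,
        )
        if exclusive and any(
            r.z == cand.z and abs(r.x0 - cand.x0) < size and abs(r.y0 - cand.y0) < size
            for r in regions
        ):
            continue
        regions.append(cand)
    return regions


def split_regions(
    regions: list[RegionSpec],
    counts: tuple[int, int, int] = (60, 20, 20),
    seed: int | np.random.Generator = 0,
) -> list[RegionSpec]:
    """Shuffle regions and tag them train/val/test with the given counts.

    The assignment is a disjoint, exhaustive partition; the seeded shuffle
    both randomizes the split and serves as the region shuffling used to
    spread annotation order effects across the splits.
    """
    if sum(counts) != len(regions):
        raise ValueError(f"split counts {counts} do not sum to {len(regions)} regions")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(regions))
    tags = ["train"] * counts[0] + ["val"] * counts[1] + ["test"] * counts[2]
    out: list[RegionSpec] = [None] * len(regions)  # type: ignore[list-item]
    for tag, idx in zip(tags, order):
        out[idx] = replace(regions[idx], split=tag)
    return out


def sample_pixels(
    regions: list[RegionSpec],
    labels: list[np.ndarray],
    fraction: float = 0.025,
    balanced: bool = True,
    seed: int | np.random.Generator = 0,
) -> PixelSample:
    """Draw a stratified random pixel sample from the square regions.

    The target count is ``fraction`` of all square-region pixels (rounded to
    the nearest even number in balanced mode).  Balanced sampling pools
    pixels of each class across all the regions and draws half the target
    from each class, uniformly without replacement, yielding an exact 50/50
    class balance; unbalanced mode draws uniformly from the pool.

    ``labels`` holds one (size x size) array of {0, 1} per region.
    """
    if len(labels) != len(regions):
        raise ValueError("need one label mask per region")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    for r, lab in zip(regions, labels):
        if lab.shape != (r.size, r.size):
            raise ValueError(f"label mask shape {lab.shape} does not match region size {r.size}")
        if not np.isin(lab, (0, 1)).all():
            raise ValueError("labels must be binary (0 = pore, 1 = solid)")

    coords = np.concatenate([r.pixel_coords() for r in regions], axis=0)
    lab_flat = np.concatenate([np.asarray(lab).ravel() for lab in labels])
    region_idx = np.repeat(np.arange(len(regions)), [r.size**2 for r in regions])
    total = coords.shape[0]
    rng = np.random.default_rng(seed)

    if balanced:
        n = int(round(fraction * total / 2.0) * 2)
        half = n // 2
        picks = []
        for cls in (0, 1):
            pool = np.flatnonzero(lab_flat == cls)
            if pool.size < half:
                raise ValueError(
                    f"class {cls} has only {pool.size} pixels, cannot draw {half} without replacement"
                )
            picks.append(rng.choice(pool, size=half, replace=False))
        chosen = np.concatenate(picks)
    else:
        n = int(round(fraction * total))
        chosen = rng.choice(total, size=n, replace=False)

    return PixelSample(
        coords=coords[chosen], labels=lab_flat[chosen], region_index=region_idx[chosen]
    )


def augment_features(
    fm: FeatureMatrix,
    params: AugmentationParams,
    seed: int | np.random.Generator = 0,
) -> FeatureMatrix:
    """Apply a per-sample random affine intensity transform in feature space.

    For each row, draw ``a ~ N(0, sigma_a)`` and ``b ~ N(1, sigma_b)`` and
    map every feature f to ``a + b f``.  Labels are unchanged.  Valid only
    because all features are unit-sum linear filters of the image, so this
    equals transforming the image first and re-extracting features.
    """
    rng = np.random.default_rng(seed)
    n = fm.n_samples
    a = rng.normal(0.0, params.sigma_a, size=n) if params.sigma_a > 0 else np.zeros(n)
    b = rng.normal(1.0, params.sigma_b, size=n) if params.sigma_b > 0 else np.ones(n)
    values = a[:, None] + b[:, None] * fm.values
    labels = None if fm.labels is None else fm.labels.copy()
    return FeatureMatrix(values, list(fm.columns), labels=labels)


def save_regions(path: str | Path, regions: list[RegionSpec]) -> None:
    """Serialize a region list as JSON (0-based, half-open coordinates)."""
    Path(path).write_text(json.dumps([asdict(r) for r in regions], indent=1))


def load_regions(path: str | Path) -> list[RegionSpec]:
    return [RegionSpec(**d) for d in json.loads(Path(path).read_text())]
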