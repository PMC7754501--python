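"""Linear scale-space feature extraction.

Each pixel is described by the raw intensity plus Gaussian-smoothed
intensities at a geometric ladder of scales, evaluated in its own slice and
in the five adjacent slices on either side.  With the default nine scales
(sigma = 0, 1, 2, ..., 128 pixels, sigma = 0 being the raw data) and eleven
slices this gives 99 features per pixel.

Smoothing is strictly 2D within each slice: the shine-through effect makes
slices "2.5D", so between-slice context is supplied by sampling neighbouring
slices rather than by 3D filtering.  Kernels are truncated sampled Gaussians
of odd full width 4*sigma + 1 (2*sigma + 1 at the largest scale, to limit
edge effects), renormalized to sum exactly to one so that constant images
are fixed points and the features are affine-equivariant:
``features(a + b*I) == a + b*features(I)``.  That linearity is what lets
intensity augmentation act directly on precomputed feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import ImageVolume

__all__ = [
    "ScaleSpaceConfig",
    "FeatureMatrix",
    "gaussian_kernel",
    "gaussian_scale_space",
    "mirror_index",
    "assemble_features",
    "slice_features",
]

DEFAULT_SIGMAS = (0, 1, 2, 4, 8, 16, 32, 64, 128)
DEFAULT_OFFSETS = tuple(range(-5, 6))


@dataclass(frozen=True)
class ScaleSpaceConfig:
    """Scales, slice context and boundary handling for feature extraction.

    Parameters
    ----------
    sigmas
        Gaussian standard deviations in pixels, ascending, starting at 0
        (the raw image).
    slice_offsets
        Relative slice indices sampled around each pixel.
    boundary
        Out-of-range handling for both in-slice filtering and z sampling:
        ``"mirror"`` reflects without repeating the edge sample (slice -1 is
        slice 1), ``"reflect"`` repeats it (slice -1 is slice 0).
    """

    sigmas: tuple[float, ...] = DEFAULT_SIGMAS
    slice_offsets: tuple[int, ...] = DEFAULT_OFFSETS
    boundary: str = "mirror"

    def __post_init__(self) -> None:
        if len(self.sigmas) == 0:
            raise ValueError("need at least one scale")
        if any(s < 0 for s in self.sigmas):
            raise ValueError("scales must be non-negative")
        if list(self.sigmas) != sorted(self.sigmas):
            raise ValueError("scales must be ascending")
        if self.boundary not in ("mirror", "reflect"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")

    @property
    def n_features(self) -> int:
        return len(self.sigmas) * len(self.slice_offsets)

    def half_width(self, sigma: float) -> int:
        """Kernel half-width: 2*sigma, except sigma at the largest scale."""
        if sigma == 0:
            return 0
        if sigma == max(self.sigmas):
            return int(round(sigma))
        return int(round(2 * sigma))

    def columns(self) -> list[tuple[int, float]]:
        """Fixed column order: slice offset major, then sigma ascending."""
        return [(off, sig) for off in self.slice_offsets for sig in self.sigmas]

    def column_index(self) -> dict[tuple[int, float], int]:
        return {key: i for i, key in enumerate(self.columns())}


@dataclass
class FeatureMatrix:
    """Per-pixel feature vectors with their column map and optional labels."""

    values: np.ndarray  # (n_samples, n_features)
    columns: list[tuple[int, float]]  # (slice_offset, sigma) per column
    labels: np.ndarray | None = None  # 0 = pore, 1 = solid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2D (samples x features)")
        if self.values.shape[1] != len(self.columns):
            raise ValueError(
                f"{self.values.shape[1]} feature columns but {len(self.columns)} column keys"
            )
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("column map is not a bijection")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.values.shape[0],):
                raise ValueError("labels must be one per row")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def gaussian_kernel(sigma: float, half_width: int) -> np.ndarray:
    """Sampled Gaussian on [-half_width, half_width], renormalized to sum 1."""
    if sigma <= 0:
        return np.ones(1)
    x = np.arange(-half_width, half_width + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_scale_space(
    vol: ImageVolume | np.ndarray, cfg: ScaleSpaceConfig | None = None
) -> list[np.ndarray]:
    """Filter every slice of the volume at each scale.

    Returns one array of the volume's shape per sigma, in the order of
    ``cfg.sigmas``.  Filtering is separable 2D within slices (axes x and y);
    nothing mixes across z.  sigma = 0 returns a copy of the input.
    """
    cfg = cfg or ScaleSpaceConfig()
    data = vol.data if isinstance(vol, ImageVolume) else np.asarray(vol, dtype=np.float64)
    out: list[np.ndarray] = []
    for sigma in cfg.sigmas:
        if sigma == 0:
            out.append(data.copy())
            continue
        k = gaussian_kernel(sigma, cfg.half_width(sigma))
        f = ndimage.correlate1d(data, k, axis=0, mode=cfg.boundary)
        f = ndimage.correlate1d(f, k, axis=1, mode=cfg.boundary)
        out.append(f)
    return out


def mirror_index(i: int | np.ndarray, n: int, boundary: str = "mirror") -> int | np.ndarray:
    """Map an out-of-range index into [0, n) by reflection.

    ``"mirror"`` reflects about the edge samples (period 2(n-1); index -1
    maps to 1), ``"reflect"`` reflects about the boundary between samples
    (period 2n; index -1 maps to 0).
    """
    i = np.asarray(i)
    if n == 1:
        return np.zeros_like(i) if i.ndim else 0
    if boundary == "mirror":
        period = 2 * (n - 1)
        j = np.abs(i) % period
        j = np.where(j >= n, period - j, j)
    elif boundary == "reflect":
        period = 2 * n
        j = i % period
        j = np.where(j >= n, period - 1 - j, j)
    else:
        raise ValueError(f"unknown boundary mode {boundary!r}")
    return j if j.ndim else int(j)


def assemble_features(
    filtered: list[np.ndarray],
    pixels: np.ndarray,
    cfg: ScaleSpaceConfig | None = None,
    labels: np.ndarray | None = None,
) -> FeatureMatrix:
    """Gather the feature vector of each listed pixel.

    ``pixels`` is an integer array of shape (n, 3) holding (x, y, z).  The
    row for pixel p holds, for every (slice offset, sigma) column, the
    sigma-filtered value at ``(x_p, y_p, z_p + offset)``; z indices outside
    the stack are obtained by reflecting the filtered volumes.
    """
    cfg = cfg or ScaleSpaceConfig()
    pixels = np.asarray(pixels)
    if pixels.ndim != 2 or pixels.shape[1] != 3:
        raise ValueError("pixels must be an (n, 3) array of (x, y, z)")
    nx, ny, nz = filtered[0].shape
    x, y, z = pixels[:, 0], pixels[:, 1], pixels[:, 2]
    if (x < 0).any() or (x >= nx).any() or (y < 0).any() or (y >= ny).any():
        raise IndexError("pixel x/y coordinates out of bounds")
    if (z < 0).any() or (z >= nz).any():
        raise IndexError("pixel z coordinates out of bounds")

    n_sig = len(cfg.sigmas)
    values = np.empty((pixels.shape[0], cfg.n_features))
    for oi, off in enumerate(cfg.slice_offsets):
        zi = mirror_index(z + off, nz, cfg.boundary)
        for si in range(n_sig):
            values[:, oi * n_sig + si] = filtered[si][x, y, zi]
    return FeatureMatrix(values, cfg.columns(), labels=labels)


def slice_features(
    filtered: list[np.ndarray], z: int, cfg: ScaleSpaceConfig | None = None
) -> np.ndarray:
    """Feature matrix for every pixel of slice z, in C (row-major x, y) order.

    Vectorized equivalent of :func:`assemble_features` on the full slice;
    used for whole-volume prediction.
    """
    cfg = cfg or ScaleSpaceConfig()
    nx, ny, nz = filtered[0].shape
    n_sig = len(cfg.sigmas)
    values = np.empty((nx * ny, cfg.n_features))
    for oi, off in enumerate(cfg.slice_offsets):
        zi = int(mirror_index(z + off, nz, cfg.boundary))
        for si in range(n_sig):
            values[:, oi * n_sig + si] = filtered[si][:, :, zi].ravel()
    return values
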