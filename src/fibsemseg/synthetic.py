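"""Ground-truthed synthetic FIB-SEM volumes of two-phase porous media.

The generator produces a binary pore/solid microstructure (a thresholded
Gaussian random field, emulating a phase-separated polymer film after
leaching) and renders it the way a FIB-SEM cross-section series sees it:

* **shine-through** — a pore pixel is not dark if solid material sits
  behind it along the milling direction; its brightness decays
  exponentially with the depth of the first solid voxel behind it, so the
  pore and solid intensity histograms overlap, which is precisely what
  makes global thresholding fail on real data;
* a near-linear **intensity gradient** along the in-slice x axis;
* additive Gaussian **noise**.

Because the phase map is known exactly, every segmentation metric has an
unambiguous reference, making the whole pipeline testable end to end.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .preprocess import ImageVolume

__all__ = ["SyntheticConfig", "generate_structure", "render_fibsem", "simulate"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic microstructure and its rendering.

    Parameters
    ----------
    dims
        Volume shape (nx, ny, nz); z is the slice/milling axis.
    target_porosity
        Pore volume fraction; hit exactly (to one voxel) by quantile
        thresholding of the random field.
    correlation_length
        Gaussian smoothing scale of the random field, in pixels; sets the
        characteristic pore/strut size.
    shine_decay_depth
        e-folding depth (in slices) of the subsurface-solid brightness seen
        through a pore; 0 disables shine-through.
    solid_level, pore_floor
        Rendered intensity of solid voxels and of pores with no solid
        behind them.
    gradient_slope
        Linear intensity ramp per pixel along x.
    noise_sd
        Standard deviation of additive Gaussian noise.
    """

    dims: tuple[int, int, int] = (128, 128, 40)
    target_porosity: float = 0.30
    correlation_length: float = 4.0
    shine_decay_depth: float = 3.0
    solid_level: float = 0.75
    pore_floor: float = 0.15
    gradient_slope: float = 0.0008
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_porosity < 1:
            raise ValueError("target_porosity must be in (0, 1)")
        if self.shine_decay_depth < 0 or self.noise_sd < 0:
            raise ValueError("shine_decay_depth and noise_sd must be >= 0")
        if not (0 <= self.pore_floor <= 1 and 0 <= self.solid_level <= 1):
            raise ValueError("intensity levels must lie in [0, 1]")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")


def generate_structure(cfg: SyntheticConfig) -> np.ndarray:
    """Binary phase map (0 = pore, 1 = solid) with exact porosity control.

    White noise is smoothed by a periodic 3D Gaussian of the correlation
    length and thresholded at the empirical quantile of the target porosity,
    so the realized pore fraction matches to within one voxel.
    """
    nx, ny, nz = cfg.dims
    if min(cfg.dims) < 8:
        raise ValueError(f"dims {cfg.dims} too small; need at least 8 along every axis")
    rng = np.random.default_rng(cfg.seed)
    field = rng.standard_normal(cfg.dims)
    field = ndimage.gaussian_filter(field, cfg.correlation_length, mode="wrap")
    thr = np.quantile(field, cfg.target_porosity)
    return (field > thr).astype(np.uint8)


def _depth_to_backing_solid(structure: np.ndarray) -> np.ndarray:
    """Per-voxel distance (in slices, >= 1) to the nearest solid voxel at
    strictly greater z on the same (x, y) ray; +inf where none exists."""
    nx, ny, nz = structure.shape
    depth = np.full(structure.shape, np.inf)
    ahead = np.full((nx, ny), np.inf)  # distance from slice z to solid at z' > z
    for z in range(nz - 1, -1, -1):
        depth[:, :, z] = ahead
        ahead = np.where(structure[:, :, z] == 1, 1.0, ahead + 1.0)
    return depth


def render_fibsem(
    structure: np.ndarray, cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> ImageVolume:
    """Render the phase map as a FIB-SEM-like intensity volume.

    Solid voxels render at ``solid_level``.  A pore voxel renders at
    ``pore_floor + (solid_level - pore_floor) * exp(-(d - 1) / lambda)``
    where ``d >= 1`` is the slice distance to the first solid voxel behind
    it (greater z, the not-yet-milled material) and lambda is the shine
    decay depth; pores with no solid behind them get the floor.  The decay
    is anchored at ``d = 1``: a pore with solid on the very next slice is
    indistinguishable from solid in that cross-section, so the pore and
    solid intensity histograms genuinely overlap and single-slice
    thresholding cannot separate the phases — the central difficulty of
    segmenting porous FIB-SEM data.  The x gradient and Gaussian noise are
    then added and the result clipped to [0, 1].
    """
    structure = np.asarray(structure)
    if not np.isin(structure, (0, 1)).all():
        raise ValueError("structure must be binary (0 = pore, 1 = solid)")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)

    img = np.full(structure.shape, cfg.solid_level, dtype=np.float64)
    pore = structure == 0
    if cfg.shine_decay_depth > 0:
        d = _depth_to_backing_solid(structure)
        shine = np.zeros_like(img)
        finite = np.isfinite(d)
        shine[finite] = (cfg.solid_level - cfg.pore_floor) * np.exp(
            -(d[finite] - 1.0) / cfg.shine_decay_depth
        )
        img[pore] = cfg.pore_floor + shine[pore]
    else:
        img[pore] = cfg.pore_floor

    nx = structure.shape[0]
    img += cfg.gradient_slope * np.arange(nx)[:, None, None]
    if cfg.noise_sd > 0:
        img += rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return ImageVolume(np.clip(img, 0.0, 1.0))


def simulate(cfg: SyntheticConfig) -> tuple[np.ndarray, ImageVolume]:
    """Generate a structure and its rendered image in one call."""
    structure = generate_structure(cfg)
    return structure, render_fibsem(structure, cfg)


def save_manifest(path: str | Path, cfg: SyntheticConfig) -> None:
    """Write the generating configuration as a JSON manifest."""
    Path(path).write_text(json.dumps(asdict(cfg), indent=1))
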