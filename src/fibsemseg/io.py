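"""TIFF stack input/output.

Stacks are stored page-per-slice (multipage TIFF, or one numbered file per
slice read in lexicographic order).  On disk each page is a 2D image indexed
``(x, y)``; in memory slices are stacked along the last axis, giving the
``(nx, ny, nz)`` convention used throughout the package.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .preprocess import ImageVolume

__all__ = ["read_stack", "write_stack", "write_label_stack", "read_label_stack"]


def _to_volume_axes(pages: np.ndarray) -> np.ndarray:
    # tifffile yields (nz, nx, ny); move the slice axis last
    return np.moveaxis(pages, 0, -1)


def read_stack(path: str | Path) -> np.ndarray:
    """Read a grayscale stack from a multipage TIFF or a directory of slices.

    Returns the raw array with shape ``(nx, ny, nz)`` and the on-disk dtype
    (typically uint16 for raw data, float32 for corrected volumes).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF slices found in {path}")
        pages = np.stack([tifffile.imread(f) for f in files], axis=0)
    else:
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"expected a stack of 2D pages, got shape {pages.shape}")
    return _to_volume_axes(pages)


def write_stack(path: str | Path, vol: ImageVolume | np.ndarray) -> None:
    """Write a float volume as a 32-bit float multipage TIFF."""
    data = vol.data if isinstance(vol, ImageVolume) else np.asarray(vol)
    pages = np.moveaxis(data.astype(np.float32), -1, 0)
    tifffile.imwrite(Path(path), pages, photometric="minisblack")


def write_label_stack(path: str | Path, labels: np.ndarray) -> None:
    """Write a binary segmentation as 8-bit TIFF, 0 = pore, 255 = solid."""
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("label volume must be binary (0 = pore, 1 = solid)")
    pages = np.moveaxis((labels * 255).astype(np.uint8), -1, 0)
    tifffile.imwrite(Path(path), pages, photometric="minisblack")


def read_label_stack(path: str | Path) -> np.ndarray:
    """Read an 8-bit label stack back to a {0, 1} volume (255 -> solid)."""
    raw = read_stack(path)
    return (raw > 127).astype(np.uint8)
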