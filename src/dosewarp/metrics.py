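"""Segmentation-overlap and surface-distance metrics.

DSC is the Dice similarity coefficient ``2|A∩B| / (|A|+|B|)``.  The Hausdorff
family is computed on boundary voxel centres in millimetres: ``hd`` is the
classic symmetric maximum of directed nearest-point distances, while ``hd95``
and ``hdmean`` are, by default, the 95th percentile and mean of the *pooled*
nearest-point distances from both directions, which keeps them symmetric in
their arguments (a directed variant is available by flag).  Percentiles use
linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .grids import Mask3D


def dsc(a: Mask3D | np.ndarray, b: Mask3D | np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks on one grid."""
    aa = (a.data if isinstance(a, Mask3D) else np.asarray(a)).astype(bool)
    bb = (b.data if isinstance(b, Mask3D) else np.asarray(b)).astype(bool)
    if aa.shape != bb.shape:
        raise ValueError("masks must share a grid")
    denom = int(aa.sum()) + int(bb.sum())
    if denom == 0:
        raise ValueError("DSC undefined: both masks are empty")
    return 2.0 * int(np.logical_and(aa, bb).sum()) / denom


@dataclass
class SurfacePointSet:
    """Boundary voxel centres in mm."""

    points: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.points) == 0:
            raise ValueError("surface point set must be nonempty")


def extract_surface(mask: Mask3D) -> SurfacePointSet:
    """Mask voxels with a 6-neighbour outside the mask (grid border counts)."""
    m = mask.data
    if not m.any():
        raise ValueError("cannot extract the surface of an empty mask")
    interior = np.ones_like(m)
    # a voxel is interior only if all six face neighbours are inside
    for axis in range(3):
        lo = np.ones_like(m)
        hi = np.ones_like(m)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(1, None)
        sl_hi[axis] = slice(None, -1)
        lo[tuple(sl_lo)] = np.take(m, range(m.shape[axis] - 1), axis=axis)
        hi[tuple(sl_hi)] = np.take(m, range(1, m.shape[axis]), axis=axis)
        # border voxels get a virtual outside neighbour
        sl_first = [slice(None)] * 3
        sl_first[axis] = 0
        lo[tuple(sl_first)] = False
        sl_last = [slice(None)] * 3
        sl_last[axis] = m.shape[axis] - 1
        hi[tuple(sl_last)] = False
        interior &= lo & hi
    surface = m & ~interior
    idx = np.argwhere(surface).astype(np.float64)
    idx *= np.asarray(mask.spacing)
    return SurfacePointSet(idx)


def _nearest_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return np.asarray(d, dtype=np.float64)


def hausdorff(
    a: SurfacePointSet | np.ndarray,
    b: SurfacePointSet | np.ndarray,
    pooled: bool = True,
) -> tuple[float, float, float]:
    """(hd, hd95, hdmean) in mm between two boundary point sets.

    ``pooled=True`` (default) computes hd95/hdmean over the concatenated
    nearest-distance samples of both directions; ``pooled=False`` returns the
    maximum of the two directed statistics instead.
    """
    pa = a.points if isinstance(a, SurfacePointSet) else np.asarray(a, dtype=np.float64)
    pb = b.points if isinstance(b, SurfacePointSet) else np.asarray(b, dtype=np.float64)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("hausdorff undefined for empty point sets")
    d_ab = _nearest_distances(pa, pb)
    d_ba = _nearest_distances(pb, pa)
    hd = max(d_ab.max(), d_ba.max())
    if pooled:
        pool = np.concatenate([d_ab, d_ba])
        hd95 = float(np.percentile(pool, 95))
        hdmean = float(pool.mean())
    else:
        hd95 = max(float(np.percentile(d_ab, 95)), float(np.percentile(d_ba, 95)))
        hdmean = max(float(d_ab.mean()), float(d_ba.mean()))
    return float(hd), hd95, hdmean


def mask_distances(a: Mask3D, b: Mask3D, pooled: bool = True) -> tuple[float, float, float]:
    """Hausdorff family straight from two masks."""
    return hausdorff(extract_surface(a), extract_surface(b), pooled=pooled)
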