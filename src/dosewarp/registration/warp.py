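"""Backward (pull) warping of volumes through displacement fields.

The sampling convention follows the pull-warp definition used throughout the
package: ``out(p) = in(p + u(p) / spacing)`` where ``u`` is in millimetres and
the division converts to (fractional) voxel offsets per axis.  Out-of-bounds
sample positions are clamped to the border voxel (clamp-to-border).

``warp_with_grad`` additionally returns the Jacobian-vector product of the
output with respect to the displacement field, which is what unsupervised
registration training differentiates through.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from ..grids import DisplacementField, Volume3D


def _sample_coords(shape, u, spacing):
    """Fractional sampling coordinates per axis, clamped to the volume."""
    coords = []
    inside = []
    for a in range(3):
        idx = np.arange(shape[a], dtype=np.float64).reshape(
            [-1 if i == a else 1 for i in range(3)]
        )
        x = idx + u[..., a] / spacing[a]
        ins = (x >= 0.0) & (x <= shape[a] - 1.0)
        coords.append(np.clip(x, 0.0, shape[a] - 1.0))
        inside.append(ins)
    return coords, inside


def _corner_setup(coords, shape):
    i0, frac = [], []
    for a in range(3):
        base = np.minimum(np.floor(coords[a]), shape[a] - 2).astype(np.intp)
        base = np.maximum(base, 0)
        i0.append(base)
        frac.append(coords[a] - base)
    return i0, frac


def warp_array(
    data: np.ndarray,
    u: np.ndarray,
    spacing,
    mode: str = "linear",
) -> np.ndarray:
    """Warp a 3D array through a displacement field (mm).

    mode="linear" uses trilinear interpolation; mode="nearest" rounds the
    sampling coordinate half away from zero (suitable for masks).
    """
    data = np.asarray(data)
    shape = data.shape
    if u.shape != (*shape, 3):
        raise ValueError(f"field shape {u.shape} does not match volume {shape}")
    coords, _ = _sample_coords(shape, u, spacing)
    if mode == "nearest":
        idx = []
        for a in range(3):
            x = coords[a]
            r = np.sign(x) * np.floor(np.abs(x) + 0.5)  # round half away from zero
            idx.append(np.clip(r, 0, shape[a] - 1).astype(np.intp))
        return data[idx[0], idx[1], idx[2]]
    if mode != "linear":
        raise ValueError(f"unknown mode {mode!r}")
    i0, t = _corner_setup(coords, shape)
    out = np.zeros(shape, dtype=np.float64)
    for dx in (0, 1):
        wx = t[0] if dx else 1.0 - t[0]
        for dy in (0, 1):
            wy = t[1] if dy else 1.0 - t[1]
            for dz in (0, 1):
                wz = t[2] if dz else 1.0 - t[2]
                c = data[i0[0] + dx, i0[1] + dy, i0[2] + dz]
                out += c * wx * wy * wz
    return out


def warp_with_grad(
    data: np.ndarray, u: np.ndarray, spacing
) -> tuple[np.ndarray, Callable[[np.ndarray], np.ndarray]]:
    """Trilinear warp returning (output, backward).

    ``backward(g_out)`` maps a gradient w.r.t. the warped volume to a gradient
    w.r.t. the displacement field (same shape as ``u``).  Positions whose
    unclamped sampling coordinate falls outside the volume get zero gradient
    along that axis (the clamped sample does not move with the field there).
    """
    data = np.asarray(data, dtype=np.float64)
    shape = data.shape
    coords, inside = _sample_coords(shape, u, spacing)
    i0, t = _corner_setup(coords, shape)

    corners = {}
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                corners[dx, dy, dz] = data[i0[0] + dx, i0[1] + dy, i0[2] + dz]

    w = [(1.0 - t[a], t[a]) for a in range(3)]
    out = np.zeros(shape, dtype=np.float64)
    for (dx, dy, dz), c in corners.items():
        out += c * w[0][dx] * w[1][dy] * w[2][dz]

    def backward(g_out: np.ndarray) -> np.ndarray:
        g_u = np.zeros((*shape, 3), dtype=np.float64)
        # d out / d t_a : difference of corner pairs along axis a, weighted by
        # the other two axes' interpolation weights.
        for a in range(3):
            d = np.zeros(shape, dtype=np.float64)
            for db in (0, 1):
                for dc in (0, 1):
                    sel = [None, None, None]
                    sel[a] = None
                    others = [i for i in range(3) if i != a]
                    key_hi = [0, 0, 0]
                    key_lo = [0, 0, 0]
                    key_hi[a] = 1
                    key_hi[others[0]] = db
                    key_hi[others[1]] = dc
                    key_lo[others[0]] = db
                    key_lo[others[1]] = dc
                    diff = corners[tuple(key_hi)] - corners[tuple(key_lo)]
                    d += diff * w[others[0]][db] * w[others[1]][dc]
            g_u[..., a] = g_out * d * inside[a] / spacing[a]
        return g_u

    return out, backward


def warp_volume(vol: Volume3D, field: DisplacementField, mode: str = "linear") -> Volume3D:
    if vol.shape != field.grid_shape:
        raise ValueError(
            f"volume grid {vol.shape} does not match field grid {field.grid_shape}"
        )
    out = warp_array(vol.data, field.u, vol.spacing, mode=mode)
    return Volume3D(out, vol.spacing, role="moving")
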