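"""Core in-memory containers for volumetric radiotherapy data.

All grids live on a regular axis-aligned lattice indexed ``(x, y, z)`` with an
anisotropic voxel spacing in millimetres.  World coordinates are
``index * spacing`` (no direction cosines or origin offsets in v1; see the
methods note).  Displacement fields are stored in millimetres on the fixed
image's grid and follow the pull/backward-warp convention: a field ``u`` maps
a fixed-grid position ``p`` to the moving-image sampling position
``p + u(p)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

Spacing = tuple[float, float, float]


def _as_spacing(spacing: Sequence[float]) -> Spacing:
    s = tuple(float(v) for v in spacing)
    if len(s) != 3 or any(v <= 0 for v in s):
        raise ValueError(f"spacing must be 3 positive floats, got {spacing!r}")
    return s  # type: ignore[return-value]


@dataclass
class Volume3D:
    """Scalar image volume (arbitrary intensity units)."""

    data: np.ndarray
    spacing: Spacing
    role: str = "unspecified"  # "fixed" | "moving" | "unspecified"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D needs a 3D array, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume3D data must be finite")
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "Volume3D":
        return replace(self, data=self.data.copy())


@dataclass
class Mask3D:
    """Binary organ segmentation on the same lattice conventions."""

    data: np.ndarray
    spacing: Spacing
    organ: str = "organ"

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"Mask3D needs a 3D array, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("Mask3D values must be 0/1")
        self.data = arr.astype(bool)
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def volume_cc(self) -> float:
        return float(self.data.sum()) * self.voxel_volume_cc


@dataclass
class DoseGrid:
    """Absorbed-dose grid in Gy.

    ``kind`` distinguishes a physical per-fraction dose from an accumulated
    EQD2 dose; ``n_fractions`` records how many identical fractions the grid
    stands for (relevant for the per-fraction kind).
    """

    data: np.ndarray
    spacing: Spacing
    kind: str = "physical_per_fraction"  # or "eqd2_total"
    n_fractions: int = 1

    _KINDS = ("physical_per_fraction", "eqd2_total")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"DoseGrid needs a 3D array, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("DoseGrid data must be finite")
        if np.any(self.data < 0):
            raise ValueError("DoseGrid data must be nonnegative")
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class DisplacementField:
    """Dense displacement field u(p) in mm on the fixed grid, shape (nx,ny,nz,3)."""

    u: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError(
                f"DisplacementField needs shape (nx,ny,nz,3), got {self.u.shape}"
            )
        if not np.all(np.isfinite(self.u)):
            raise ValueError("DisplacementField must be finite")
        self.spacing = _as_spacing(self.spacing)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.u.shape[:3]  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.u**2).sum(axis=-1))

    @classmethod
    def zeros(cls, shape: Sequence[int], spacing: Sequence[float]) -> "DisplacementField":
        return cls(np.zeros((*shape, 3)), _as_spacing(spacing))


@dataclass
class Frame:
    """One imaging/treatment time point of a course."""

    role: str  # "ebrt" or "icbt"
    image: Volume3D
    masks: dict[str, Mask3D]
    dose: DoseGrid | None = None
    n_fractions: int = 1
    is_fixed: bool = False
    # pull field from this frame's grid into the base-phantom frame (synthetic
    # courses only; None for real data)
    deformation: DisplacementField | None = None


@dataclass
class Course:
    """An EBRT plan plus an ordered series of ICBT fractions for one patient."""

    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_fixed = sum(f.is_fixed for f in self.frames)
        if self.frames and n_fixed != 1:
            raise ValueError(f"exactly one frame must be fixed, got {n_fixed}")

    @property
    def fixed_index(self) -> int:
        return next(i for i, f in enumerate(self.frames) if f.is_fixed)

    @property
    def fixed_frame(self) -> Frame:
        return self.frames[self.fixed_index]

    @property
    def moving_indices(self) -> list[int]:
        return [i for i, f in enumerate(self.frames) if not f.is_fixed]


def check_same_grid(*grids, what: str = "grids") -> None:
    shapes = {g.data.shape if hasattr(g, "data") else g.u.shape[:3] for g in grids}
    spacings = {tuple(g.spacing) for g in grids}
    if len(shapes) > 1 or len(spacings) > 1:
        raise ValueError(
            f"{what} must share one grid; shapes={shapes}, spacings={spacings}"
        )
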