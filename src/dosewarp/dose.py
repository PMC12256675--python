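"""EQD2 conversion, deformation-based dose accumulation and DVH extraction.

Per-fraction physical doses are first rescaled voxelwise to the equivalent
dose in 2 Gy fractions using the linear-quadratic model,

    EQD2(p) = N * d(p) * (d(p) + α/β) / (2 + α/β),

with ``d(p)`` the per-fraction voxel dose, ``N`` the number of identical
fractions and α/β = 3 Gy for late-responding normal tissue.  EQD2 grids from
the moving frames are then pull-warped into the reference (last-ICBT) frame
with the registration fields and summed; DVH parameters (D2cc, D1cc, D0.1cc,
V50) are read off the cumulative grid inside the reference-frame organ
masks.  Dose is treated as a point quantity: warping uses plain trilinear
interpolation without Jacobian weighting.

Three addition strategies are provided: DA (direct DVH-parameter summation,
the worst-case convention), and deformation-based addition driven by either
the mix-transformer model (MA) or the CNN baseline (VoA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Course, DisplacementField, DoseGrid, Mask3D, check_same_grid
from .registration.training import RegistrationModel
from .registration.warp import warp_array


@dataclass
class AlphaBeta:
    """α/β ratio in Gy (3 Gy default: late normal-tissue endpoint)."""

    value: float = 3.0

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("alpha/beta must be > 0")


@dataclass
class DVHParams:
    organ: str
    d2cc: float
    d1cc: float
    d01cc: float
    v50: float | None  # percent, None when undefined for the method

    def __post_init__(self) -> None:
        if not (self.d01cc >= self.d1cc >= self.d2cc >= 0):
            raise ValueError("DVH D-metrics must satisfy d01cc >= d1cc >= d2cc >= 0")
        if self.v50 is not None and not (0 <= self.v50 <= 100):
            raise ValueError("v50 must be a percentage")


def to_eqd2(dose: DoseGrid, ab: AlphaBeta | float = AlphaBeta()) -> DoseGrid:
    """Voxelwise LQ conversion of a per-fraction dose grid to total EQD2."""
    abv = ab.value if isinstance(ab, AlphaBeta) else float(ab)
    if abv <= 0:
        raise ValueError("alpha/beta must be > 0")
    if dose.kind != "physical_per_fraction":
        raise ValueError(f"to_eqd2 expects a physical_per_fraction grid, got {dose.kind}")
    d = dose.data
    eqd2 = dose.n_fractions * d * (d + abv) / (2.0 + abv)
    return DoseGrid(eqd2, dose.spacing, kind="eqd2_total", n_fractions=dose.n_fractions)


def warp_dose(dose: DoseGrid, field: DisplacementField) -> DoseGrid:
    """Pull-warp an EQD2 grid into the fixed frame (trilinear, point-dose)."""
    if dose.kind != "eqd2_total":
        raise ValueError("warp doses after EQD2 conversion, not before")
    if dose.shape != field.grid_shape:
        raise ValueError(
            f"dose grid {dose.shape} does not match field grid {field.grid_shape}"
        )
    out = warp_array(dose.data, field.u, dose.spacing)
    return DoseGrid(
        np.maximum(out, 0.0), dose.spacing, kind="eqd2_total", n_fractions=dose.n_fractions
    )


def accumulate(doses: list[DoseGrid]) -> DoseGrid:
    """Voxelwise sum of EQD2 grids on a common grid."""
    if not doses:
        raise ValueError("nothing to accumulate")
    kinds = {d.kind for d in doses}
    if kinds != {"eqd2_total"}:
        raise ValueError(f"can only accumulate eqd2_total grids, got kinds {kinds}")
    check_same_grid(*doses, what="dose grids")
    total = np.zeros_like(doses[0].data)
    n = 0
    for d in doses:
        total += d.data
        n += d.n_fractions
    return DoseGrid(total, doses[0].spacing, kind="eqd2_total", n_fractions=n)


def dvh_dcc(
    dose: DoseGrid, mask: Mask3D, cc: float, interpolate: bool = True
) -> float:
    """Minimum dose received by the hottest ``cc`` cm³ of the organ.

    In-mask voxel doses are sorted descending and voxel volumes accumulated;
    the returned dose is read at the point where the cumulative volume
    reaches ``cc``, linearly interpolated between the straddling sorted
    voxels (``interpolate=False`` returns the straddling voxel's dose).
    """
    check_same_grid(dose, mask, what="dose and mask")
    if cc <= 0:
        raise ValueError("cc must be > 0")
    vox_cc = mask.voxel_volume_cc
    vals = np.sort(dose.data[mask.data])[::-1]
    total_cc = len(vals) * vox_cc
    if total_cc < cc:
        raise ValueError(
            f"mask volume {total_cc:.3f} cc is smaller than the requested {cc} cc"
        )
    # cumulative volume after voxel j (1-based) is j * vox_cc
    j = cc / vox_cc  # fractional voxel count
    hi = int(np.ceil(j))
    if not interpolate or hi <= 1:
        return float(vals[hi - 1])
    lo = hi - 1  # cumulative volume lo*vox_cc < cc <= hi*vox_cc
    frac = j - lo  # in (0, 1]
    return float(vals[lo - 1] + (vals[hi - 1] - vals[lo - 1]) * frac)


def dvh_v(dose: DoseGrid, mask: Mask3D, threshold: float = 50.0) -> float:
    """Percent of the organ volume receiving at least ``threshold`` Gy."""
    check_same_grid(dose, mask, what="dose and mask")
    n = int(mask.data.sum())
    if n == 0:
        raise ValueError("V-metric undefined on an empty mask")
    return 100.0 * float((dose.data[mask.data] >= threshold).sum()) / n


def dvh_params(dose: DoseGrid, mask: Mask3D, v_threshold: float = 50.0) -> DVHParams:
    return DVHParams(
        organ=mask.organ,
        d2cc=dvh_dcc(dose, mask, 2.0),
        d1cc=dvh_dcc(dose, mask, 1.0),
        d01cc=dvh_dcc(dose, mask, 0.1),
        v50=dvh_v(dose, mask, v_threshold),
    )


def direct_addition(per_plan_params: list[DVHParams]) -> DVHParams:
    """DA: component-wise sum of per-plan D-metrics (worst-case convention).

    V50 is not defined by simple parameter addition across frames; it is
    reported as None here.  Use ``direct_addition_course`` when all plans
    share one frame, which computes V50 from the unwarped voxel sum.
    """
    if not per_plan_params:
        raise ValueError("empty parameter list")
    organs = {p.organ for p in per_plan_params}
    if len(organs) > 1:
        raise ValueError(f"mixed organs in direct addition: {organs}")
    if len(per_plan_params) == 1:
        return per_plan_params[0]
    return DVHParams(
        organ=per_plan_params[0].organ,
        d2cc=sum(p.d2cc for p in per_plan_params),
        d1cc=sum(p.d1cc for p in per_plan_params),
        d01cc=sum(p.d01cc for p in per_plan_params),
        v50=None,
    )


def course_eqd2_grids(course: Course, ab: AlphaBeta | float = AlphaBeta()) -> list[DoseGrid]:
    grids = []
    for frame in course.frames:
        if frame.dose is None:
            raise ValueError(f"frame with role {frame.role!r} has no dose grid")
        grids.append(to_eqd2(frame.dose, ab))
    return grids


def direct_addition_course(
    course: Course, organs: list[str], ab: AlphaBeta | float = AlphaBeta()
) -> dict[str, DVHParams]:
    """DA on a course: per-frame DVH parameters on each frame's own masks,
    summed; V50 from the unwarped voxel sum on the fixed frame (all synthetic
    frames share one grid)."""
    eqd2 = course_eqd2_grids(course, ab)
    out = {}
    unwarped_sum = accumulate(eqd2)
    for organ in organs:
        per_plan = [
            dvh_params(g, frame.masks[organ])
            for g, frame in zip(eqd2, course.frames)
        ]
        params = direct_addition(per_plan)
        params.v50 = dvh_v(unwarped_sum, course.fixed_frame.masks[organ])
        out[organ] = params
    return out


def dir_addition(
    course: Course,
    model: RegistrationModel | None = None,
    fields: dict[int, DisplacementField] | None = None,
    organs: list[str] | None = None,
    ab: AlphaBeta | float = AlphaBeta(),
) -> dict[str, DVHParams]:
    """Deformation-based dose addition onto the fixed (last-ICBT) frame.

    Every moving frame's EQD2 grid is pull-warped into the fixed frame with
    its registration field (star topology: each session registered directly
    to the last session), the fixed frame's own EQD2 is added unwarped, and
    DVH parameters are computed on the fixed frame's organ masks.  Fields may
    come from a trained model or be supplied directly.
    """
    if (model is None) == (fields is None):
        raise ValueError("provide exactly one of model or fields")
    fixed = course.fixed_frame
    if organs is None:
        organs = sorted(fixed.masks)
    for organ in organs:
        if organ not in fixed.masks:
            raise ValueError(f"fixed frame lacks a mask for organ {organ!r}")
    eqd2 = course_eqd2_grids(course, ab)
    warped = []
    for idx, frame in enumerate(course.frames):
        if frame.is_fixed:
            warped.append(eqd2[idx])
            continue
        if fields is not None:
            field = fields[idx]
        else:
            field = model.predict_field(fixed.image, frame.image)
        warped.append(warp_dose(eqd2[idx], field))
    total = accumulate(warped)
    return {organ: dvh_params(total, fixed.masks[organ]) for organ in organs}
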