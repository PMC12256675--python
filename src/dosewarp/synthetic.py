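"""Synthetic pelvic phantoms, deformations, dose grids and treatment courses.

This module generates the study material the rest of the package is exercised
on: CT-like volumes containing an ellipsoidal bladder and a cylindrical
rectum, smooth random inter-fraction deformations with known ground truth,
an EBRT-like plateau dose (many small fractions), an ICBT-like inverse-square
dose around a line applicator (few large fractions), and complete courses of
one EBRT frame plus several ICBT frames.

Conventions
-----------
* World coordinates are ``index * spacing`` in mm.
* A stored truth field follows the pull/backward convention: the *fixed*
  image of a pair is the base phantom resampled through the field, so
  ``warp(moving, truth) == fixed`` up to interpolation error.  The base
  phantom itself is the moving image.
* All randomness is seeded; identical (spec, seed) gives bit-identical
  output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import (
    Course,
    DisplacementField,
    DoseGrid,
    Frame,
    Mask3D,
    Volume3D,
)
from .registration.warp import warp_array


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (48, 48, 32)
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)
    bladder_semiaxes: tuple[float, float, float] = (20.0, 15.0, 15.0)
    rectum_radius: float = 8.0
    rectum_length: float = 60.0
    texture_sigma: float = 15.0
    intensity_levels: tuple[float, float, float] = (100.0, 30.0, 160.0)
    # organ centres as fractions of the physical grid extent
    bladder_centre_frac: tuple[float, float, float] = (0.5, 0.38, 0.5)
    rectum_centre_frac: tuple[float, float, float] = (0.5, 0.74, 0.5)
    texture_smooth_voxels: float = 1.5

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid too small for a phantom")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.texture_sigma < 0:
            raise ValueError("texture_sigma must be >= 0")
        if min(self.bladder_semiaxes) <= 0 or self.rectum_radius <= 0:
            raise ValueError("organ dimensions must be positive")


@dataclass
class DeformSpec:
    amplitude: float = 4.0  # mm, max displacement magnitude
    smoothness_sigma: float = 12.0  # mm, Gaussian smoothing scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.smoothness_sigma <= 0:
            raise ValueError("smoothness_sigma must be > 0")


@dataclass
class CourseSpec:
    """Fractionation mirroring the dominant clinical schedules (50.4 Gy / 28
    fractions EBRT at 1.8 Gy per fraction; 6 Gy per ICBT fraction)."""

    n_icbt: int = 5
    ebrt_total_dose: float = 50.4
    ebrt_fractions: int = 28
    icbt_dose_per_fraction: float = 6.0
    icbt_fractions_per_session: int = 1
    source_path: np.ndarray | None = None  # (k, 3) polyline in mm
    prescription_distance_mm: float = 10.0
    ebrt_target_radius_mm: float = 35.0
    ebrt_penumbra_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.ebrt_total_dose < 0 or self.icbt_dose_per_fraction < 0:
            raise ValueError("doses must be >= 0")
        if self.ebrt_fractions < 1 or self.icbt_fractions_per_session < 1:
            raise ValueError("fraction counts must be >= 1")


@dataclass
class PairSample:
    """A registration pair with its ground-truth pull field."""

    fixed: Volume3D
    moving: Volume3D
    fixed_masks: dict[str, Mask3D]
    moving_masks: dict[str, Mask3D]
    truth: DisplacementField


def _world_axes(shape, spacing):
    return [np.arange(n) * s for n, s in zip(shape, spacing)]


def _world_grid(shape, spacing):
    ax = _world_axes(shape, spacing)
    return np.meshgrid(*ax, indexing="ij")


def generate_phantom(
    spec: PhantomSpec, seed: int
) -> tuple[Volume3D, Mask3D, Mask3D]:
    """Textured CT-like volume with bladder and rectum masks."""
    shape, spacing = spec.grid_shape, spec.spacing
    extent = [(n - 1) * s for n, s in zip(shape, spacing)]
    x, y, z = _world_grid(shape, spacing)

    bc = [f * e for f, e in zip(spec.bladder_centre_frac, extent)]
    a, b, c = spec.bladder_semiaxes
    for centre, semi, ext in zip(bc, spec.bladder_semiaxes, extent):
        if centre - semi < 0 or centre + semi > ext:
            raise ValueError(
                f"bladder (centre {centre:.1f} mm, semiaxis {semi:.1f} mm) does "
                f"not fit in the {ext:.1f} mm grid extent"
            )
    bladder = ((x - bc[0]) / a) ** 2 + ((y - bc[1]) / b) ** 2 + (
        (z - bc[2]) / c
    ) ** 2 <= 1.0

    rc = [f * e for f, e in zip(spec.rectum_centre_frac, extent)]
    r, half_l = spec.rectum_radius, spec.rectum_length / 2.0
    if (
        rc[0] - r < 0
        or rc[0] + r > extent[0]
        or rc[1] - r < 0
        or rc[1] + r > extent[1]
        or rc[2] - half_l < 0
        or rc[2] + half_l > extent[2]
    ):
        raise ValueError("rectum cylinder does not fit in the grid")
    rectum = ((x - rc[0]) ** 2 + (y - rc[1]) ** 2 <= r**2) & (
        np.abs(z - rc[2]) <= half_l
    )

    if np.any(bladder & rectum):
        raise ValueError("bladder and rectum overlap; adjust centres or sizes")

    bg, lvl_bladder, lvl_rectum = spec.intensity_levels
    img = np.full(shape, bg, dtype=np.float64)
    img[bladder] = lvl_bladder
    img[rectum] = lvl_rectum
    if spec.texture_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = gaussian_filter(
            rng.standard_normal(shape), sigma=spec.texture_smooth_voxels
        )
        noise *= spec.texture_sigma / noise.std()
        img += noise

    vol = Volume3D(img, spacing)
    return (
        vol,
        Mask3D(bladder, spacing, organ="bladder"),
        Mask3D(rectum, spacing, organ="rectum"),
    )


def generate_displacement(spec: DeformSpec, shape, spacing) -> DisplacementField:
    """Smooth random field, zero on all boundary faces, max |u| == amplitude.

    Built by Gaussian-smoothing per-axis white noise at the requested
    smoothness scale, tapering to zero over a boundary margin, and rescaling
    the maximum magnitude to ``amplitude``.
    """
    shape = tuple(int(n) for n in shape)
    if spec.amplitude == 0:
        return DisplacementField.zeros(shape, spacing)
    rng = np.random.default_rng(spec.seed)
    sigma_vox = [spec.smoothness_sigma / s for s in spacing]
    u = np.stack(
        [gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox) for _ in range(3)],
        axis=-1,
    )
    # taper: linear ramp from the faces over roughly one smoothness scale
    for axis, (n, s) in enumerate(zip(shape, spacing)):
        margin = max(2, int(round(spec.smoothness_sigma / s)))
        margin = min(margin, (n - 1) // 2)
        i = np.arange(n, dtype=np.float64)
        ramp = np.minimum(1.0, np.minimum(i, n - 1 - i) / margin)
        u *= ramp.reshape([-1 if a == axis else 1 for a in range(3)] + [1])
    mag = np.sqrt((u**2).sum(axis=-1)).max()
    if mag > 0:
        u *= spec.amplitude / mag
    return DisplacementField(u, spacing)


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """det(I + ∇u) per voxel (central differences, world units)."""
    u = field.u
    jac = np.empty((*u.shape[:3], 3, 3))
    for comp in range(3):
        for axis in range(3):
            jac[..., comp, axis] = np.gradient(
                u[..., comp], field.spacing[axis], axis=axis
            )
        jac[..., comp, comp] += 1.0
    return np.linalg.det(jac)


def make_pair(
    phantom: tuple[Volume3D, Mask3D, Mask3D], field: DisplacementField
) -> PairSample:
    """Turn a phantom and a truth field into a (fixed, moving) training pair.

    The phantom is the moving image; the fixed image is the phantom resampled
    through the field, so the stored truth is exactly the pull field a perfect
    registration should recover.
    """
    vol, bladder, rectum = phantom
    if field.grid_shape != vol.shape:
        raise ValueError(
            f"field grid {field.grid_shape} does not match phantom grid {vol.shape}"
        )
    spacing = vol.spacing
    fixed = Volume3D(warp_array(vol.data, field.u, spacing), spacing, role="fixed")
    moving = Volume3D(vol.data.copy(), spacing, role="moving")
    fixed_masks, moving_masks = {}, {}
    for mask in (bladder, rectum):
        warped = warp_array(mask.data.astype(np.float64), field.u, spacing, mode="nearest")
        fixed_masks[mask.organ] = Mask3D(warped > 0.5, spacing, organ=mask.organ)
        moving_masks[mask.organ] = Mask3D(mask.data.copy(), spacing, organ=mask.organ)
    return PairSample(fixed, moving, fixed_masks, moving_masks, field)


def generate_pairs(
    n_pairs: int,
    phantom_spec: PhantomSpec,
    deform_spec: DeformSpec,
    seed: int,
) -> list[PairSample]:
    """Independent registration pairs sharing one base phantom family."""
    master = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_pairs):
        phantom_seed = int(master.integers(2**31))
        field_seed = int(master.integers(2**31))
        phantom = generate_phantom(phantom_spec, phantom_seed)
        spec = DeformSpec(
            amplitude=deform_spec.amplitude,
            smoothness_sigma=deform_spec.smoothness_sigma,
            seed=field_seed,
        )
        field = generate_displacement(spec, phantom_spec.grid_shape, phantom_spec.spacing)
        pairs.append(make_pair(phantom, field))
    return pairs


def generate_ebrt_dose(shape, spacing, course: CourseSpec) -> DoseGrid:
    """Per-fraction EBRT-like dose: plateau at total/fractions inside a
    central target with a smooth sigmoidal penumbra."""
    d0 = course.ebrt_total_dose / course.ebrt_fractions
    x, y, z = _world_grid(shape, spacing)
    centre = [(n - 1) * s / 2.0 for n, s in zip(shape, spacing)]
    r = np.sqrt((x - centre[0]) ** 2 + (y - centre[1]) ** 2 + (z - centre[2]) ** 2)
    dose = d0 / (1.0 + np.exp((r - course.ebrt_target_radius_mm) / course.ebrt_penumbra_mm))
    return DoseGrid(dose, spacing, kind="physical_per_fraction", n_fractions=course.ebrt_fractions)


def default_source_path(shape, spacing) -> np.ndarray:
    """Applicator axis: a vertical line between bladder and rectum."""
    extent = [(n - 1) * s for n, s in zip(shape, spacing)]
    x0, y0 = 0.5 * extent[0], 0.55 * extent[1]
    z_lo, z_hi = 0.3 * extent[2], 0.7 * extent[2]
    n_pts = max(2, int((z_hi - z_lo) / 2.0))
    z = np.linspace(z_lo, z_hi, n_pts)
    return np.stack([np.full_like(z, x0), np.full_like(z, y0), z], axis=1)


def icbt_kernel(points_mm: np.ndarray, source: np.ndarray, r_min: float) -> np.ndarray:
    """Sum of inverse-square contributions of the source points, r clamped."""
    d2 = ((points_mm[:, None, :] - source[None, :, :]) ** 2).sum(axis=-1)
    d2 = np.maximum(d2, r_min**2)
    return (1.0 / d2).sum(axis=1)


def generate_icbt_dose(shape, spacing, course: CourseSpec) -> DoseGrid:
    """Per-fraction ICBT-like dose: inverse-square falloff around the source
    polyline, scaled so the prescription distance receives the prescribed
    dose per fraction."""
    source = course.source_path
    if source is None:
        source = default_source_path(shape, spacing)
    source = np.atleast_2d(np.asarray(source, dtype=np.float64))
    extent = [(n - 1) * s for n, s in zip(shape, spacing)]
    if np.any(source < -1e-9) or np.any(source > np.asarray(extent) + 1e-9):
        raise ValueError("source_path must lie inside the grid")
    r_min = min(spacing)
    mid = source.mean(axis=0)
    ref = mid + np.array([course.prescription_distance_mm, 0.0, 0.0])
    k_ref = icbt_kernel(ref[None, :], source, r_min)[0]
    scale = course.icbt_dose_per_fraction / k_ref
    pts = np.stack(_world_grid(shape, spacing), axis=-1).reshape(-1, 3)
    dose = scale * icbt_kernel(pts, source, r_min)
    return DoseGrid(
        dose.reshape(shape),
        spacing,
        kind="physical_per_fraction",
        n_fractions=course.icbt_fractions_per_session,
    )


def generate_course(
    spec: CourseSpec,
    phantom_spec: PhantomSpec,
    deform_spec: DeformSpec,
    seed: int,
) -> Course:
    """One EBRT frame plus ``n_icbt`` ICBT frames on a shared base anatomy.

    Every frame is the base phantom resampled through an independent smooth
    deformation; the last ICBT frame is flagged as the fixed/reference frame.
    Each frame carries its per-fraction planned dose.
    """
    if spec.n_icbt < 2:
        raise ValueError("a course needs at least 2 ICBT fractions")
    shape, spacing = phantom_spec.grid_shape, phantom_spec.spacing
    master = np.random.default_rng(seed)
    phantom = generate_phantom(phantom_spec, int(master.integers(2**31)))
    vol, bladder, rectum = phantom

    frames: list[Frame] = []
    roles = ["ebrt"] + ["icbt"] * spec.n_icbt
    for idx, role in enumerate(roles):
        dspec = DeformSpec(
            amplitude=deform_spec.amplitude,
            smoothness_sigma=deform_spec.smoothness_sigma,
            seed=int(master.integers(2**31)),
        )
        w = generate_displacement(dspec, shape, spacing)
        image = Volume3D(warp_array(vol.data, w.u, spacing), spacing)
        masks = {}
        for mask in (bladder, rectum):
            warped = warp_array(
                mask.data.astype(np.float64), w.u, spacing, mode="nearest"
            )
            masks[mask.organ] = Mask3D(warped > 0.5, spacing, organ=mask.organ)
        if role == "ebrt":
            dose = generate_ebrt_dose(shape, spacing, spec)
            n_fractions = spec.ebrt_fractions
        else:
            dose = generate_icbt_dose(shape, spacing, spec)
            n_fractions = spec.icbt_fractions_per_session
        frames.append(
            Frame(
                role=role,
                image=image,
                masks=masks,
                dose=dose,
                n_fractions=n_fractions,
                is_fixed=(idx == len(roles) - 1),
                deformation=w,
            )
        )
    return Course(frames)


def true_field_to_fixed(course: Course, frame_index: int, n_iter: int = 5) -> DisplacementField:
    """Approximate truth field pulling ``frame_index`` onto the fixed frame.

    Solves ``v(p) = w_F(p) - w_k(p + v(p))`` by fixed-point iteration, where
    ``w_F`` and ``w_k`` are the stored base-phantom deformations of the fixed
    and moving frames.  Exact to first order in the field amplitude.
    """
    fixed = course.fixed_frame
    moving = course.frames[frame_index]
    if fixed.deformation is None or moving.deformation is None:
        raise ValueError("course frames carry no stored deformations")
    w_f, w_k = fixed.deformation.u, moving.deformation.u
    spacing = fixed.deformation.spacing
    v = w_f.copy()
    for _ in range(n_iter):
        sampled = np.stack(
            [warp_array(w_k[..., c], v, spacing) for c in range(3)], axis=-1
        )
        v = w_f - sampled
    return DisplacementField(v, spacing)
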