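"""Phantom, deformation, pair and course generation."""

import numpy as np
import pytest
from scipy.ndimage import label

from dosewarp.grids import DisplacementField
from dosewarp.metrics import dsc
from dosewarp.registration.warp import warp_array
from dosewarp.synthetic import (
    CourseSpec,
    DeformSpec,
    PhantomSpec,
    generate_course,
    generate_displacement,
    generate_ebrt_dose,
    generate_icbt_dose,
    generate_phantom,
    jacobian_determinant,
    make_pair,
    true_field_to_fixed,
)


class TestPhantom:
    def test_deterministic_for_fixed_seed(self, phantom_spec):
        v1, b1, r1 = generate_phantom(phantom_spec, seed=11)
        v2, b2, r2 = generate_phantom(phantom_spec, seed=11)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(b1.data, b2.data)
        assert np.array_equal(r1.data, r2.data)

    def test_different_seed_changes_texture(self, phantom_spec):
        v1, *_ = generate_phantom(phantom_spec, seed=1)
        v2, *_ = generate_phantom(phantom_spec, seed=2)
        assert not np.array_equal(v1.data, v2.data)

    def test_bladder_volume_matches_analytic_ellipsoid(self):
        spec = PhantomSpec(bladder_semiaxes=(20.0, 15.0, 15.0), spacing=(2.0, 2.0, 2.0),
                           grid_shape=(48, 48, 48))
        _, bladder, _ = generate_phantom(spec, seed=0)
        analytic_mm3 = 4.0 / 3.0 * np.pi * 20 * 15 * 15
        voxel_mm3 = 8.0
        assert bladder.data.sum() == pytest.approx(analytic_mm3 / voxel_mm3, rel=0.10)

    def test_zero_texture_background_constant(self, phantom_spec):
        spec = PhantomSpec(texture_sigma=0.0)
        vol, bladder, rectum = generate_phantom(spec, seed=0)
        background = vol.data[~(bladder.data | rectum.data)]
        assert np.all(background == background.flat[0])

    def test_organ_contrast_exceeds_twice_texture_sigma(self, phantom_spec, phantom):
        vol, bladder, rectum = phantom
        bg_mask = ~(bladder.data | rectum.data)
        bg = vol.data[bg_mask].mean()
        for mask in (bladder, rectum):
            contrast = abs(vol.data[mask.data].mean() - bg)
            assert contrast >= 2 * phantom_spec.texture_sigma

    def test_masks_are_single_6connected_components(self, phantom):
        _, bladder, rectum = phantom
        structure = np.zeros((3, 3, 3), bool)
        structure[1, 1, :] = structure[1, :, 1] = structure[:, 1, 1] = True
        for mask in (bladder, rectum):
            _, n = label(mask.data, structure=structure)
            assert n == 1

    def test_oversized_organ_rejected(self):
        spec = PhantomSpec(bladder_semiaxes=(200.0, 15.0, 15.0))
        with pytest.raises(ValueError, match="does not fit"):
            generate_phantom(spec, seed=0)


class TestDisplacement:
    def test_zero_amplitude_gives_zero_field(self, phantom_spec):
        f = generate_displacement(DeformSpec(amplitude=0.0, seed=1),
                                  phantom_spec.grid_shape, phantom_spec.spacing)
        assert np.all(f.u == 0)

    def test_max_magnitude_equals_amplitude(self, phantom_spec):
        f = generate_displacement(DeformSpec(amplitude=4.0, seed=1),
                                  phantom_spec.grid_shape, phantom_spec.spacing)
        mag = f.magnitude()
        assert 0 < mag.max() <= 4.0 + 1e-12

    def test_zero_on_boundary_faces(self, phantom_spec):
        f = generate_displacement(DeformSpec(amplitude=4.0, seed=2),
                                  phantom_spec.grid_shape, phantom_spec.spacing)
        for axis in range(3):
            for face in (0, -1):
                sl = [slice(None)] * 3
                sl[axis] = face
                assert np.all(f.u[tuple(sl)] == 0)

    def test_jacobian_positive_for_small_amplitude(self, phantom_spec):
        f = generate_displacement(DeformSpec(amplitude=3.0, smoothness_sigma=12.0, seed=5),
                                  phantom_spec.grid_shape, phantom_spec.spacing)
        assert jacobian_determinant(f).min() > 0

    def test_deterministic(self, phantom_spec):
        a = generate_displacement(DeformSpec(amplitude=4.0, seed=9),
                                  phantom_spec.grid_shape, phantom_spec.spacing)
        b = generate_displacement(DeformSpec(amplitude=4.0, seed=9),
                                  phantom_spec.grid_shape, phantom_spec.spacing)
        assert np.array_equal(a.u, b.u)


class TestMakePair:
    def test_zero_field_pair_identical(self, phantom, phantom_spec):
        zero = DisplacementField.zeros(phantom_spec.grid_shape, phantom_spec.spacing)
        p = make_pair(phantom, zero)
        np.testing.assert_allclose(p.fixed.data, p.moving.data, atol=1e-6)

    def test_truth_warp_recovers_fixed_masks(self, pair):
        for organ, fmask in pair.fixed_masks.items():
            warped = warp_array(
                pair.moving_masks[organ].data.astype(float),
                pair.truth.u,
                pair.moving.spacing,
                mode="nearest",
            ) > 0.5
            assert dsc(fmask.data, warped) >= 0.95

    def test_truth_warp_recovers_fixed_image(self, pair, phantom_spec):
        recovered = warp_array(pair.moving.data, pair.truth.u, pair.moving.spacing)
        err = np.abs(recovered - pair.fixed.data)
        interior = err[2:-2, 2:-2, 2:-2]
        assert interior.mean() < 3 * phantom_spec.texture_sigma

    def test_dsc_decreases_with_amplitude(self, phantom_spec, phantom):
        mean_dsc = {}
        for amplitude in (2.0, 6.0):
            vals = []
            for seed in range(10):
                f = generate_displacement(
                    DeformSpec(amplitude=amplitude, smoothness_sigma=12.0, seed=seed),
                    phantom_spec.grid_shape, phantom_spec.spacing)
                p = make_pair(phantom, f)
                vals.append(dsc(p.fixed_masks["bladder"], p.moving_masks["bladder"]))
            mean_dsc[amplitude] = np.mean(vals)
        assert mean_dsc[6.0] < mean_dsc[2.0]

    def test_grid_mismatch_rejected(self, phantom):
        bad = DisplacementField.zeros((8, 8, 8), (2.0, 2.0, 4.0))
        with pytest.raises(ValueError, match="grid"):
            make_pair(phantom, bad)

    def test_mask_volume_conserved_under_small_deformation(self, phantom, phantom_spec):
        f = generate_displacement(DeformSpec(amplitude=3.0, smoothness_sigma=12.0, seed=4),
                                  phantom_spec.grid_shape, phantom_spec.spacing)
        p = make_pair(phantom, f)
        for organ in p.fixed_masks:
            v0 = p.moving_masks[organ].data.sum()
            v1 = p.fixed_masks[organ].data.sum()
            assert abs(v1 - v0) / v0 < 0.15


class TestDoses:
    def test_ebrt_central_dose_is_per_fraction_prescription(self, phantom_spec):
        course = CourseSpec(ebrt_total_dose=50.4, ebrt_fractions=28)
        dose = generate_ebrt_dose(phantom_spec.grid_shape, phantom_spec.spacing, course)
        centre = tuple(n // 2 for n in phantom_spec.grid_shape)
        assert dose.data[centre] == pytest.approx(1.8, rel=0.01)
        assert dose.n_fractions == 28

    def test_ebrt_nonnegative_and_monotone_along_ray(self, phantom_spec):
        dose = generate_ebrt_dose(phantom_spec.grid_shape, phantom_spec.spacing, CourseSpec())
        assert np.all(dose.data >= 0)
        cx, cy, cz = (n // 2 for n in phantom_spec.grid_shape)
        ray = dose.data[cx:, cy, cz]
        assert np.all(np.diff(ray) <= 1e-12)

    def test_icbt_inverse_square_from_point_source(self):
        shape, spacing = (40, 40, 20), (2.0, 2.0, 2.0)
        src_idx = (20, 20, 10)  # a voxel centre
        src_mm = [i * s for i, s in zip(src_idx, spacing)]
        course = CourseSpec(source_path=np.array([src_mm]), icbt_dose_per_fraction=6.0)
        dose = generate_icbt_dose(shape, spacing, course)
        near = dose.data[src_idx[0] + 5, src_idx[1], src_idx[2]]   # 10 mm
        far = dose.data[src_idx[0] + 10, src_idx[1], src_idx[2]]   # 20 mm
        assert near / far == pytest.approx(4.0, rel=0.02)

    def test_icbt_prescription_point_and_finiteness(self):
        shape, spacing = (40, 40, 20), (2.0, 2.0, 2.0)
        src_idx = (20, 20, 10)
        src_mm = [i * s for i, s in zip(src_idx, spacing)]
        course = CourseSpec(source_path=np.array([src_mm]), icbt_dose_per_fraction=6.0,
                            prescription_distance_mm=10.0)
        dose = generate_icbt_dose(shape, spacing, course)
        assert np.all(np.isfinite(dose.data))
        at_rx = dose.data[src_idx[0] + 5, src_idx[1], src_idx[2]]
        assert at_rx == pytest.approx(6.0, rel=0.02)

    def test_source_outside_grid_rejected(self, phantom_spec):
        course = CourseSpec(source_path=np.array([[1e4, 0.0, 0.0]]))
        with pytest.raises(ValueError, match="inside the grid"):
            generate_icbt_dose(phantom_spec.grid_shape, phantom_spec.spacing, course)


@pytest.fixture(scope="module")
def course(phantom_spec):
    return generate_course(CourseSpec(n_icbt=5), phantom_spec,
                           DeformSpec(amplitude=4.0, smoothness_sigma=12.0), seed=42)


class TestCourse:
    def test_frame_count_and_fixed_flag(self, course):
        assert len(course.frames) == 6
        assert course.fixed_index == 5
        assert course.frames[0].role == "ebrt"
        assert all(f.role == "icbt" for f in course.frames[1:])

    def test_reproducible(self, phantom_spec, course):
        again = generate_course(CourseSpec(n_icbt=5), phantom_spec,
                                DeformSpec(amplitude=4.0, smoothness_sigma=12.0), seed=42)
        for f1, f2 in zip(course.frames, again.frames):
            assert np.array_equal(f1.image.data, f2.image.data)
            assert np.array_equal(f1.dose.data, f2.dose.data)

    def test_frames_differ_pairwise(self, course):
        for i in range(len(course.frames)):
            for j in range(i + 1, len(course.frames)):
                d = dsc(course.frames[i].masks["bladder"], course.frames[j].masks["bladder"])
                assert d < 1.0

    def test_too_few_icbt_rejected(self, phantom_spec):
        with pytest.raises(ValueError, match="at least 2"):
            generate_course(CourseSpec(n_icbt=1), phantom_spec, DeformSpec(), seed=0)

    def test_true_field_composition_improves_alignment(self, course):
        fixed = course.fixed_frame
        frame_idx = 1
        moving = course.frames[frame_idx]
        v = true_field_to_fixed(course, frame_idx)
        warped = warp_array(moving.masks["bladder"].data.astype(float), v.u,
                            fixed.image.spacing, mode="nearest") > 0.5
        before = dsc(fixed.masks["bladder"], moving.masks["bladder"])
        after = dsc(fixed.masks["bladder"], warped)
        assert after > before
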