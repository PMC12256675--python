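"""EQD2 conversion, dose warping/accumulation and DVH parameters."""

import numpy as np
import pytest

from dosewarp.grids import DisplacementField, DoseGrid, Mask3D
from dosewarp.dose import (
    AlphaBeta,
    DVHParams,
    accumulate,
    direct_addition,
    dvh_dcc,
    dvh_params,
    dvh_v,
    to_eqd2,
    warp_dose,
)

SPACING = (2.0, 2.0, 2.0)  # 8 mm^3 voxels


def grid(data, kind="physical_per_fraction", n_fractions=1, spacing=SPACING):
    return DoseGrid(np.asarray(data, dtype=float), spacing, kind=kind, n_fractions=n_fractions)


class TestEQD2:
    def test_two_gray_per_fraction_is_fixed_point(self):
        for n in (1, 5, 28):
            d = grid(np.full((4, 4, 4), 2.0), n_fractions=n)
            out = to_eqd2(d, AlphaBeta(3.0))
            np.testing.assert_allclose(out.data, 2.0 * n, atol=1e-12)

    def test_zero_dose_maps_to_zero(self):
        out = to_eqd2(grid(np.zeros((3, 3, 3))))
        assert np.all(out.data == 0)

    def test_six_gray_single_fraction_closed_form(self):
        out = to_eqd2(grid(np.full((3, 3, 3), 6.0)), AlphaBeta(3.0))
        np.testing.assert_allclose(out.data, 10.8, atol=1e-12)

    def test_monotone_in_dose(self, rng):
        a = rng.uniform(0, 8, (5, 5, 5))
        hi = to_eqd2(grid(a + 0.5)).data
        lo = to_eqd2(grid(a)).data
        assert np.all(hi > lo)

    def test_rejects_already_converted_grid(self):
        with pytest.raises(ValueError, match="physical_per_fraction"):
            to_eqd2(grid(np.ones((3, 3, 3)), kind="eqd2_total"))


class TestWarpDose:
    def test_zero_field_unchanged(self, rng):
        d = grid(rng.uniform(0, 10, (6, 6, 6)), kind="eqd2_total")
        f = DisplacementField.zeros((6, 6, 6), SPACING)
        np.testing.assert_allclose(warp_dose(d, f).data, d.data, atol=1e-6)

    def test_one_voxel_translation_shifts_grid(self, rng):
        d = grid(rng.uniform(0, 10, (6, 6, 6)), kind="eqd2_total")
        u = np.zeros((6, 6, 6, 3))
        u[..., 0] = SPACING[0]
        out = warp_dose(d, DisplacementField(u, SPACING))
        np.testing.assert_allclose(out.data[:-1], d.data[1:], atol=1e-12)

    def test_uniform_dose_stays_uniform(self):
        d = grid(np.full((6, 6, 6), 7.5), kind="eqd2_total")
        u = np.random.default_rng(0).normal(0, 1.5, (6, 6, 6, 3))
        out = warp_dose(d, DisplacementField(u, SPACING))
        np.testing.assert_allclose(out.data, 7.5, atol=1e-9)

    def test_requires_eqd2_kind(self):
        d = grid(np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="EQD2"):
            warp_dose(d, DisplacementField.zeros((4, 4, 4), SPACING))


class TestAccumulate:
    def test_twice_same_grid_doubles(self, rng):
        a = grid(rng.uniform(0, 5, (4, 4, 4)), kind="eqd2_total")
        out = accumulate([a, a])
        np.testing.assert_array_equal(out.data, 2 * a.data)

    def test_order_invariant(self, rng):
        grids = [grid(rng.uniform(0, 5, (4, 4, 4)), kind="eqd2_total") for _ in range(3)]
        out1 = accumulate(grids)
        out2 = accumulate(grids[::-1])
        np.testing.assert_allclose(out1.data, out2.data, rtol=1e-14)

    def test_single_grid_unchanged(self, rng):
        a = grid(rng.uniform(0, 5, (4, 4, 4)), kind="eqd2_total")
        np.testing.assert_array_equal(accumulate([a]).data, a.data)

    def test_mixed_kinds_rejected(self, rng):
        a = grid(rng.uniform(0, 5, (4, 4, 4)), kind="eqd2_total")
        b = grid(rng.uniform(0, 5, (4, 4, 4)))
        with pytest.raises(ValueError, match="kind"):
            accumulate([a, b])


def full_mask(shape, spacing=SPACING, organ="bladder"):
    return Mask3D(np.ones(shape, bool), spacing, organ=organ)


class TestDcc:
    def test_uniform_dose_returns_that_dose(self):
        d = grid(np.full((6, 6, 6), 4.2), kind="eqd2_total")
        m = full_mask((6, 6, 6))
        for cc in (0.1, 1.0, (6**3) * 0.008):
            assert dvh_dcc(d, m, cc) == pytest.approx(4.2)

    def test_toy_descending_grid_interpolation(self):
        """8 mm^3 voxels with doses 10, 9, 8, ...; the 0.016 cc level sits at
        the second-hottest voxel boundary, between 9 and 10 Gy."""
        data = np.arange(27, 0, -1, dtype=float).reshape(3, 3, 3)
        d = grid(data + 0.0, kind="eqd2_total")
        m = full_mask((3, 3, 3))
        val = dvh_dcc(d, m, 0.016)
        # brute-force: sorted doses 27, 26, ...; cumulative volume per voxel 0.008
        assert 26.0 <= val <= 27.0
        assert val == pytest.approx(26.0)

    def test_d_metrics_monotone_in_cc(self, rng):
        for _ in range(20):
            d = grid(rng.uniform(0, 80, (8, 8, 8)), kind="eqd2_total")
            m = full_mask((8, 8, 8))
            p = dvh_params(d, m)
            assert p.d01cc >= p.d1cc >= p.d2cc >= 0

    def test_mask_smaller_than_cc_rejected(self):
        d = grid(np.ones((3, 3, 3)), kind="eqd2_total")
        small = Mask3D(np.zeros((3, 3, 3), bool), SPACING)
        small.data[0, 0, 0] = True
        with pytest.raises(ValueError, match="smaller"):
            dvh_dcc(d, small, 2.0)

    def test_integer_voxel_fallback(self):
        data = np.arange(27, 0, -1, dtype=float).reshape(3, 3, 3)
        d = grid(data, kind="eqd2_total")
        m = full_mask((3, 3, 3))
        assert dvh_dcc(d, m, 0.012, interpolate=False) == 26.0


class TestV:
    def test_uniform_above_threshold_is_100(self):
        d = grid(np.full((5, 5, 5), 60.0), kind="eqd2_total")
        assert dvh_v(d, full_mask((5, 5, 5)), 50.0) == 100.0

    def test_uniform_below_threshold_is_0(self):
        d = grid(np.full((5, 5, 5), 40.0), kind="eqd2_total")
        assert dvh_v(d, full_mask((5, 5, 5)), 50.0) == 0.0

    def test_half_half_split(self):
        data = np.full((4, 4, 4), 40.0)
        data[:2] = 60.0
        d = grid(data, kind="eqd2_total")
        assert dvh_v(d, full_mask((4, 4, 4)), 50.0) == 50.0

    def test_monotone_in_threshold(self, rng):
        d = grid(rng.uniform(0, 100, (6, 6, 6)), kind="eqd2_total")
        m = full_mask((6, 6, 6))
        vals = [dvh_v(d, m, t) for t in (20, 40, 60, 80)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_empty_mask_rejected(self):
        d = grid(np.ones((3, 3, 3)), kind="eqd2_total")
        with pytest.raises(ValueError, match="empty"):
            dvh_v(d, Mask3D(np.zeros((3, 3, 3), bool), SPACING), 50.0)


class TestDirectAddition:
    def test_single_plan_unchanged(self):
        p = DVHParams("bladder", d2cc=30.0, d1cc=32.0, d01cc=40.0, v50=10.0)
        assert direct_addition([p]) is p

    def test_two_plans_sum(self):
        a = DVHParams("bladder", 30.0, 32.0, 40.0, 10.0)
        b = DVHParams("bladder", 36.0, 40.0, 52.0, 20.0)
        out = direct_addition([a, b])
        assert out.d2cc == 66.0 and out.d1cc == 72.0 and out.d01cc == 92.0
        assert out.v50 is None

    def test_mixed_organs_rejected(self):
        a = DVHParams("bladder", 1.0, 1.0, 1.0, 0.0)
        b = DVHParams("rectum", 1.0, 1.0, 1.0, 0.0)
        with pytest.raises(ValueError, match="organ"):
            direct_addition([a, b])


def test_positive_homogeneity_of_d_metrics(rng):
    """Scaling every dose by c scales all D-metrics by c."""
    d = grid(rng.uniform(0, 40, (8, 8, 8)), kind="eqd2_total")
    m = full_mask((8, 8, 8))
    c = 2.5
    scaled = grid(c * d.data, kind="eqd2_total")
    for cc in (0.1, 1.0, 2.0):
        assert dvh_dcc(scaled, m, cc) == pytest.approx(c * dvh_dcc(d, m, cc), rel=1e-12)
    # V at a scaled threshold matches the unscaled V
    assert dvh_v(scaled, m, c * 30.0) == dvh_v(d, m, 30.0)
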