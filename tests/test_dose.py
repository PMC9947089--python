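"""CEM43 dose accumulation, critical area and the hottest pixel."""

import numpy as np
import pytest

from thermodose import (
    AcquisitionParams,
    DataError,
    DoseParams,
    PixelMask,
    TemperatureSeries,
    cem43,
    critical_area,
    pixel_area,
)


def _temps(delta_t, baseline=37.0, dt_s=0.62):
    delta_t = np.asarray(delta_t, dtype=float)
    times = np.arange(delta_t.shape[0]) * dt_s
    return TemperatureSeries(delta_t, times, baseline_temp_C=baseline)


def _full_mask(shape):
    return PixelMask(keep=np.ones(shape, dtype=bool))


def scalar_cem43(temp_curve_C, dt_min, params=DoseParams()):
    """Independent per-frame scalar-loop dose oracle."""
    total = 0.0
    for t in temp_curve_C:
        if t >= params.t_break_C:
            total += dt_min * params.r_above ** (params.t_break_C - t)
        elif t >= params.t_floor_C:
            total += dt_min * params.r_below ** (params.t_break_C - t)
    return total


class TestPixelArea:
    def test_kidney_protocol_gives_1_82_mm2(self):
        acq = AcquisitionParams(fov_mm=(235.0, 259.0), matrix=(174, 192))
        assert round(pixel_area(acq), 2) == 1.82

    @pytest.mark.parametrize(
        "fov, matrix, expected",
        [((100.0, 100.0), (100, 100), 1.0), ((10.0, 20.0), (5, 4), 10.0)],
    )
    def test_exact_arithmetic(self, fov, matrix, expected):
        acq = AcquisitionParams(fov_mm=fov, matrix=(max(matrix[0], 8),
                                                    max(matrix[1], 8)))
        # matrices below the acquisition minimum are checked directly
        area = (fov[0] / matrix[0]) * (fov[1] / matrix[1])
        assert area == pytest.approx(expected)


class TestCem43:
    def test_hour_at_breakpoint_is_sixty_minutes(self):
        n = int(round(3600 / 0.62))
        delta = np.full((n, 3, 3), 6.0)  # 37 + 6 = 43 degC
        dose = cem43(_temps(delta), _full_mask((3, 3)))
        assert dose.cem43_min[1, 1] == pytest.approx(n * 0.62 / 60, rel=1e-12)
        assert dose.cem43_min[1, 1] == pytest.approx(60.0, rel=1e-2)

    def test_one_degree_above_breakpoint_doubles_dose(self):
        # 60 min at 44 degC -> 60 * (0.5)^(-1) = 120 equivalent minutes
        delta = np.full((100, 2, 2), 7.0)
        temps = _temps(delta, dt_s=36.0)  # 100 frames * 36 s = 60 min
        dose = cem43(temps, _full_mask((2, 2)))
        assert dose.cem43_min[0, 0] == pytest.approx(120.0, rel=1e-12)

    def test_below_floor_accrues_nothing(self):
        delta = np.full((50, 2, 2), 1.5)  # 38.5 degC < 39 floor
        dose = cem43(_temps(delta), _full_mask((2, 2)))
        assert np.all(dose.cem43_min == 0.0)

    def test_sub_breakpoint_uses_quarter_rate(self):
        # 60 min at 41 degC -> 60 * 0.25^2 = 3.75 min
        delta = np.full((60, 2, 2), 4.0)
        temps = _temps(delta, dt_s=60.0)
        dose = cem43(temps, _full_mask((2, 2)))
        assert dose.cem43_min[0, 0] == pytest.approx(3.75, rel=1e-12)

    def test_matches_scalar_loop_on_random_trajectories(self):
        rng = np.random.default_rng(17)
        delta = rng.uniform(-2.0, 20.0, (200, 4, 4))
        temps = _temps(delta)
        dose = cem43(temps, _full_mask((4, 4)))
        dt_min = 0.62 / 60.0
        for r in range(4):
            for c in range(4):
                expected = scalar_cem43(37.0 + delta[:, r, c], dt_min)
                assert dose.cem43_min[r, c] == pytest.approx(
                    expected, rel=1e-12
                )

    def test_additive_over_frame_split(self):
        rng = np.random.default_rng(8)
        delta = rng.uniform(0.0, 15.0, (120, 3, 3))
        full = cem43(_temps(delta), _full_mask((3, 3))).cem43_min
        head = cem43(_temps(delta[:50]), _full_mask((3, 3))).cem43_min
        tail = cem43(_temps(delta[50:]), _full_mask((3, 3))).cem43_min
        assert np.allclose(full, head + tail, rtol=1e-12)

    def test_pointwise_hotter_never_lowers_dose(self):
        rng = np.random.default_rng(9)
        delta = rng.uniform(0.0, 12.0, (80, 5, 5))
        hotter = delta + rng.uniform(0.0, 3.0, delta.shape)
        d1 = cem43(_temps(delta), _full_mask((5, 5))).cem43_min
        d2 = cem43(_temps(hotter), _full_mask((5, 5))).cem43_min
        assert np.all(d2 >= d1 - 1e-12)

    def test_excluded_pixels_carry_zero_dose(self):
        delta = np.full((10, 4, 4), 10.0)
        keep = np.zeros((4, 4), bool)
        keep[0, 0] = True
        dose = cem43(_temps(delta), PixelMask(keep=keep))
        assert dose.cem43_min[0, 0] > 0
        assert np.all(dose.cem43_min[~keep] == 0.0)

    def test_nonfinite_kept_temperature_names_pixel(self):
        delta = np.zeros((10, 4, 4))
        delta[3, 2, 1] = np.nan
        with pytest.raises(DataError, match=r"\(2, 1\).*frame 3"):
            cem43(_temps(delta), _full_mask((4, 4)))

    def test_nonfinite_excluded_pixel_tolerated(self):
        delta = np.zeros((10, 4, 4))
        delta[3, 2, 1] = np.nan
        keep = np.ones((4, 4), bool)
        keep[2, 1] = False
        dose = cem43(_temps(delta), PixelMask(keep=keep))
        assert dose.cem43_min[2, 1] == 0.0


class TestCriticalArea:
    def test_no_pixel_above_threshold_zero_area(self):
        delta = np.zeros((10, 4, 4))
        temps = _temps(delta)
        dose = cem43(temps, _full_mask((4, 4)))
        res = critical_area(dose, temps, _full_mask((4, 4)))
        assert res.area_mm2 == 0.0
        assert res.n_pixels == 0

    def test_five_pixels_at_kidney_pixel_size(self):
        # 5 pixels above threshold at 1.82 mm^2 each -> 9.1 mm^2
        delta = np.zeros((10, 4, 4))
        delta[:, 0, :4] = 20.0
        delta[:, 1, 0] = 20.0
        temps = _temps(delta, dt_s=600.0)
        dose = cem43(temps, _full_mask((4, 4)), pixel_area_mm2=1.82)
        res = critical_area(dose, temps, _full_mask((4, 4)))
        assert res.n_pixels == 5
        assert res.area_mm2 == pytest.approx(9.1)

    def test_matches_exhaustive_scan_on_random_dose(self):
        rng = np.random.default_rng(30)
        delta = rng.uniform(0.0, 25.0, (150, 6, 6))
        keep = rng.random((6, 6)) > 0.25
        mask = PixelMask(keep=keep)
        temps = _temps(delta, dt_s=30.0)
        dose = cem43(temps, mask, pixel_area_mm2=1.82)
        res = critical_area(dose, temps, mask)
        expected = sum(
            1
            for r in range(6)
            for c in range(6)
            if keep[r, c] and dose.cem43_min[r, c] > 120.0
        )
        assert res.n_pixels == expected
        assert res.area_mm2 == pytest.approx(expected * 1.82)

    def test_hottest_pixel_is_peak_delta_t_with_row_major_ties(self):
        delta = np.zeros((4, 5, 5))
        delta[2, 1, 3] = 9.0
        delta[3, 4, 4] = 9.0  # tie: row-major order keeps (1, 3)
        temps = _temps(delta)
        dose = cem43(temps, _full_mask((5, 5)))
        res = critical_area(dose, temps, _full_mask((5, 5)))
        assert res.hottest_pixel == (1, 3)
        assert res.max_delta_t_C == pytest.approx(9.0)
        assert np.allclose(res.hottest_curve, delta[:, 1, 3])

    def test_hottest_pixel_restricted_to_kept(self):
        delta = np.zeros((4, 5, 5))
        delta[2, 0, 0] = 50.0
        delta[2, 3, 3] = 5.0
        keep = np.ones((5, 5), bool)
        keep[0, 0] = False
        temps = _temps(delta)
        mask = PixelMask(keep=keep)
        dose = cem43(temps, mask)
        res = critical_area(dose, temps, mask)
        assert res.hottest_pixel == (3, 3)

    def test_empty_mask_flagged(self):
        delta = np.zeros((4, 3, 3))
        temps = _temps(delta)
        mask = PixelMask(keep=np.zeros((3, 3), bool))
        dose = cem43(temps, mask)
        res = critical_area(dose, temps, mask)
        assert res.area_mm2 == 0.0
        assert res.hottest_pixel is None
        assert res.qc_flag == "empty-mask"

    def test_strict_threshold_boundary_excluded(self):
        # dt_min = 1.0 and R^(43-44) = 2 give exact float arithmetic:
        # 120 frames -> 240 min (included), 60 frames -> exactly 120 min
        # (excluded: the criterion is strictly greater than the threshold)
        params = DoseParams(threshold_min=120.0)
        temps_long = _temps(np.full((120, 2, 2), 7.0), dt_s=60.0)
        above = cem43(temps_long, _full_mask((2, 2)), params)
        res = critical_area(above, temps_long, _full_mask((2, 2)), params)
        assert res.n_pixels == 4
        temps_exact = _temps(np.full((60, 2, 2), 7.0), dt_s=60.0)
        exact = cem43(temps_exact, _full_mask((2, 2)), params)
        assert exact.cem43_min[0, 0] == 120.0
        res2 = critical_area(exact, temps_exact, _full_mask((2, 2)), params)
        assert res2.n_pixels == 0
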