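"""Coregistration, refined Lee filtering, calibration, temporal mean."""

from datetime import date

import numpy as np
import pytest
from scipy.ndimage import uniform_filter

from sarwheat import (
    BackscatterStack,
    SARScene,
    apply_shift,
    calibrate,
    coregister_shift,
    refined_lee,
    temporal_mean,
)

from conftest import make_raster


def ncc_oracle(ref, mov, dr, dc):
    """Independent NCC of ref against mov translated by (dr, dc)."""
    n_rows, n_cols = ref.shape
    r0, r1 = max(0, dr), min(n_rows, n_rows + dr)
    c0, c1 = max(0, dc), min(n_cols, n_cols + dc)
    a = ref[r0:r1, c0:c1].ravel()
    b = mov[r0 - dr : r1 - dr, c0 - dc : c1 - dc].ravel()
    if a.std() == 0 or b.std() == 0:
        return -np.inf
    return float(np.corrcoef(a, b)[0, 1])


def brute_force_shift(ref, mov, max_shift):
    best, best_key = None, None
    for dr in range(-max_shift, max_shift + 1):
        for dc in range(-max_shift, max_shift + 1):
            key = (-ncc_oracle(ref, mov, dr, dc), dr * dr + dc * dc, (dr, dc))
            if best_key is None or key < best_key:
                best_key, best = key, (dr, dc)
    return best


class TestCoregister:
    def test_identity(self):
        rng = np.random.default_rng(0)
        r = make_raster(rng.normal(size=(16, 16)))
        assert coregister_shift(r, r, 3) == (0, 0)

    def test_recovers_injected_shift(self):
        rng = np.random.default_rng(1)
        ref = make_raster(rng.normal(size=(32, 32)))
        moving = apply_shift(ref, (-3, 2))  # content moved up 3, right 2
        # the correction that re-aligns moving with ref is the inverse
        assert coregister_shift(ref, moving, 5) == (3, -2)

    def test_matches_exhaustive_oracle_on_noise(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            ref = make_raster(rng.normal(size=(24, 24)))
            mov = make_raster(rng.normal(size=(24, 24)))
            got = coregister_shift(ref, mov, 3)
            assert got == brute_force_shift(ref.values, mov.values, 3)

    def test_correction_maximizes_correlation(self):
        rng = np.random.default_rng(3)
        ref = make_raster(rng.normal(size=(32, 32)))
        mov = apply_shift(ref, (2, -1))
        s = coregister_shift(ref, mov, 4)
        realigned = apply_shift(mov, s)
        ok = realigned.valid_mask & ref.valid_mask
        c_best = np.corrcoef(ref.values[ok], realigned.values[ok])[0, 1]
        assert c_best > 0.999

    def test_constant_image_raises(self):
        rng = np.random.default_rng(4)
        ref = make_raster(rng.normal(size=(8, 8)))
        flat = make_raster(np.ones((8, 8)))
        with pytest.raises(ValueError, match="degenerate correlation"):
            coregister_shift(ref, flat, 2)


class TestApplyShift:
    def test_zero_shift_identity(self):
        r = make_raster(np.arange(9.0).reshape(3, 3))
        np.testing.assert_array_equal(apply_shift(r, (0, 0)).values, r.values)

    def test_down_shift_exposes_nodata_row(self):
        r = make_raster(np.arange(9.0).reshape(3, 3))
        out = apply_shift(r, (1, 0))
        assert (out.values[0] == r.meta.nodata_value).all()
        np.testing.assert_array_equal(out.values[1:], r.values[:2])

    def test_too_large_shift_raises(self):
        r = make_raster(np.ones((3, 3)))
        with pytest.raises(ValueError):
            apply_shift(r, (4, 0))


class TestRefinedLee:
    def test_constant_image_unchanged(self):
        r = make_raster(np.full((20, 20), 3.5))
        out = refined_lee(r, window=7, enl=4.0)
        np.testing.assert_allclose(out.values, 3.5)

    def test_variance_reduced_mean_preserved_on_speckle(self):
        rng = np.random.default_rng(10)
        field = 5.0 * rng.gamma(4.0, 1 / 4.0, size=(100, 100))
        r = make_raster(field)
        out = refined_lee(r, window=7, enl=4.0)
        assert out.values.var() < field.var()
        assert abs(out.values.mean() - field.mean()) / field.mean() < 0.02

    def test_beats_boxcar_on_step_edges(self):
        # periodic vertical step edges: edge preservation is the point of
        # the directional windows
        rng = np.random.default_rng(11)
        cols = np.arange(100)
        clean = np.where((cols[None, :] // 10) % 2 == 0, 2.0, 10.0) * np.ones((100, 100))
        speckled = clean * rng.gamma(4.0, 1 / 4.0, size=clean.shape)
        filtered = refined_lee(make_raster(speckled), window=7, enl=4.0)
        boxcar = uniform_filter(speckled, size=7)
        mae_refined = np.abs(filtered.values - clean).mean()
        mae_boxcar = np.abs(boxcar - clean).mean()
        assert mae_refined < mae_boxcar

    def test_output_within_window_range(self):
        rng = np.random.default_rng(12)
        vals = rng.gamma(4.0, 2.0, size=(30, 30))
        out = refined_lee(make_raster(vals), window=7, enl=4.0)
        lo = -np.inf * np.ones_like(vals)
        hi = np.inf * np.ones_like(vals)
        # window bounds via min/max filters
        from scipy.ndimage import maximum_filter, minimum_filter

        lo = minimum_filter(vals, size=7)
        hi = maximum_filter(vals, size=7)
        assert (out.values >= lo - 1e-12).all()
        assert (out.values <= hi + 1e-12).all()

    def test_nodata_excluded_and_preserved(self):
        vals = np.full((20, 20), 4.0)
        vals[5, 5] = -9999.0
        out = refined_lee(make_raster(vals), window=7, enl=4.0)
        assert out.values[5, 5] == -9999.0
        np.testing.assert_allclose(out.values[out.values != -9999.0], 4.0)

    @pytest.mark.parametrize("window,enl", [(6, 4.0), (7, 0.0), (3, 4.0)])
    def test_invalid_parameters_raise(self, window, enl):
        r = make_raster(np.ones((10, 10)))
        with pytest.raises(ValueError):
            refined_lee(r, window=window, enl=enl)


def make_scene(dn, calib_A=1000.0, pol="VH", day=7):
    return SARScene(
        raster=make_raster(dn, units="DN"),
        polarization=pol,
        date=date(2022, 3, day),
        calib_A=calib_A,
    )


class TestCalibrate:
    def test_dn_equal_A_gives_zero_db(self):
        out = calibrate(make_scene(np.full((2, 2), 1000.0)))
        np.testing.assert_allclose(out.values, 0.0)
        assert out.units == "dB"

    def test_closed_form_minus_10_db(self):
        dn = np.full((2, 2), 1000.0 / np.sqrt(10.0))
        out = calibrate(make_scene(dn))
        np.testing.assert_allclose(out.values, -10.0)

    def test_zero_dn_becomes_nodata(self):
        dn = np.array([[0.0, 1000.0]])
        out = calibrate(make_scene(dn))
        assert out.values[0, 0] == out.meta.nodata_value
        assert out.values[0, 1] == 0.0

    def test_negative_dn_raises(self):
        with pytest.raises(ValueError):
            make_scene(np.array([[-1.0, 2.0]]))

    def test_monotone_and_invertible(self):
        rng = np.random.default_rng(5)
        dn = np.sort(rng.uniform(1, 5000, size=(1, 64)))
        out = calibrate(make_scene(dn))
        assert (np.diff(out.values[0]) > 0).all()
        back = 1000.0 * 10 ** (out.values / 20.0)
        np.testing.assert_allclose(back, dn, rtol=1e-9)


class TestTemporalMean:
    def _stack(self, arrays, days=None):
        days = days or list(range(1, len(arrays) + 1))
        return BackscatterStack(
            polarization="VH",
            dates=[date(2022, 3, d) for d in days],
            scenes=[make_raster(a, units="dB") for a in arrays],
        )

    def test_idempotent_on_identical(self):
        a = np.arange(4.0).reshape(2, 2)
        out = temporal_mean(self._stack([a] * 9))
        np.testing.assert_allclose(out.values, a)

    def test_arithmetic_mean(self):
        out = temporal_mean(
            self._stack([np.full((1, 1), -10.0), np.full((1, 1), -20.0)])
        )
        assert out.values[0, 0] == -15.0

    def test_nodata_skipped(self):
        a = np.array([[-9999.0]])
        b = np.array([[-12.0]])
        out = temporal_mean(self._stack([a, b]))
        assert out.values[0, 0] == -12.0

    def test_all_nodata_stays_nodata(self):
        a = np.array([[-9999.0]])
        out = temporal_mean(self._stack([a, a]))
        assert out.values[0, 0] == -9999.0

    def test_permutation_invariant(self):
        rng = np.random.default_rng(6)
        arrays = [rng.normal(-15, 2, size=(4, 4)) for _ in range(5)]
        a = temporal_mean(self._stack(arrays))
        b = temporal_mean(self._stack(arrays[::-1]))
        np.testing.assert_allclose(a.values, b.values)

    def test_misaligned_raises(self):
        with pytest.raises(ValueError):
            BackscatterStack(
                polarization="VH",
                dates=[date(2022, 3, 1), date(2022, 3, 13)],
                scenes=[
                    make_raster(np.ones((2, 2))),
                    make_raster(np.ones((2, 2)), origin=(50.0, 20.0)),
                ],
            )
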