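"""Measurement math: closed-form YII, calibration identities, pixel
counting oracles for region sampling, finite-difference red edge."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phytoprobe import measurements as meas
from phytoprobe.measurements import (
    FluorometerReading, MeasurementError, RegionShape, SpectralCube,
    ThermalImage, calibrate_reflectance, compute_yii, export_records,
    import_records, red_edge_derivative, sample_region_spectrum,
    sample_region_temperature,
)


class TestYII:
    def test_zero_when_f_equals_fm(self):
        assert compute_yii(0.8, 0.8) == 0.0

    def test_one_when_f_zero(self):
        assert compute_yii(0.0, 0.8) == 1.0

    def test_printed_formula(self):
        assert compute_yii(0.4, 0.8) == pytest.approx(0.5)

    def test_invalid_fm(self):
        with pytest.raises(MeasurementError):
            compute_yii(0.1, 0.0)

    def test_negative_f(self):
        with pytest.raises(MeasurementError):
            compute_yii(-0.1, 0.5)

    def test_f_above_fm_warns_returns_negative(self):
        with pytest.warns(UserWarning):
            val = compute_yii(1.0, 0.8)
        assert val < 0

    @given(f=st.floats(0.0, 1.0), fm=st.floats(0.01, 1.0))
    def test_bounds_property(self, f, fm):
        if f <= fm:
            assert 0.0 <= compute_yii(f, fm) <= 1.0

    def test_strictly_decreasing_in_f(self):
        fm = 0.9
        vals = [compute_yii(f, fm) for f in np.linspace(0, fm, 20)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_reading_carries_yii_and_flag(self):
        r = FluorometerReading(F=0.4, F_M_prime=0.8, site=(1, 2, 3),
                               site_index=1)
        assert r.YII == pytest.approx(0.5)
        assert r.saturated_ok


class TestCalibration:
    def test_raw_equals_white_gives_one(self):
        raw = np.full((4, 5, 3), 2.0)
        cube = calibrate_reflectance(raw, white=np.full(3, 2.0),
                                     dark=np.zeros(3))
        assert np.allclose(cube.data, 1.0)

    def test_raw_equals_dark_gives_zero(self):
        raw = np.full((4, 5, 3), 0.5)
        cube = calibrate_reflectance(raw, white=np.full(3, 2.0),
                                     dark=np.full(3, 0.5))
        assert np.allclose(cube.data, 0.0)

    def test_midpoint_gives_half(self):
        white, dark = np.full(3, 3.0), np.full(3, 1.0)
        raw = np.full((2, 2, 3), 2.0)
        cube = calibrate_reflectance(raw, white, dark)
        assert np.allclose(cube.data, 0.5)

    def test_white_equal_dark_names_band(self):
        white = np.array([2.0, 1.0, 2.0])
        dark = np.array([0.0, 1.0, 0.0])
        with pytest.raises(MeasurementError, match=r"\[1\]"):
            calibrate_reflectance(np.zeros((2, 2, 3)), white, dark)

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(0, 1, (3, 4, 5))
        once = calibrate_reflectance(raw, np.ones(5), np.zeros(5))
        assert np.allclose(once.data, raw)


class TestRegionSampling:
    def test_uniform_cube_constant(self):
        cube = SpectralCube(bands=np.arange(5, dtype=float),
                            data=np.full((20, 20, 5), 0.3))
        shape = RegionShape(kind="circle", center=(10, 10), radius=4)
        spec, n = sample_region_spectrum(cube, shape)
        assert np.allclose(spec, 0.3)
        assert n > 0

    def test_circle_pixel_count_oracle(self):
        cube = SpectralCube(bands=np.arange(2, dtype=float),
                            data=np.zeros((30, 30, 2)))
        shape = RegionShape(kind="circle", center=(15, 15), radius=5.5)
        _, n = sample_region_spectrum(cube, shape)
        # brute-force pixel-center membership oracle
        count = sum(
            1 for r in range(30) for c in range(30)
            if (r - 15) ** 2 + (c - 15) ** 2 <= 5.5 ** 2)
        assert n == count

    def test_half_over_two_values(self):
        data = np.zeros((20, 21, 1))
        data[:, :10] = 0.4    # left of the centerline
        data[:, 11:] = 0.2    # right of it
        data[:, 10] = 0.3     # centerline itself averages to 0.3 too
        cube = SpectralCube(bands=np.array([500.0]), data=data)
        shape = RegionShape(kind="circle", center=(10, 10), radius=4.5)
        spec, n = sample_region_spectrum(cube, shape)
        assert spec[0] == pytest.approx(0.3)

    def test_line_region_mean(self):
        img = ThermalImage(data=np.full((10, 10), 25.0))
        shape = RegionShape(kind="line", endpoints=((1, 1), (8, 8)),
                            thickness=2.0)
        temp, n = sample_region_temperature(img, shape)
        assert temp == 25.0
        assert n > 0

    def test_boundary_straddling_temperature(self):
        data = np.full((20, 20), 20.0)
        data[:, 10:] = 30.0
        img = ThermalImage(data=data)
        # symmetric line region across the boundary: equal pixels each side
        shape = RegionShape(kind="line", endpoints=((5, 9.5), (14, 9.5)),
                            thickness=3.0)
        temp, n = sample_region_temperature(img, shape)
        assert n % 2 == 0
        assert temp == pytest.approx(25.0)

    def test_empty_intersection_errors(self):
        img = ThermalImage(data=np.zeros((5, 5)))
        shape = RegionShape(kind="circle", center=(100, 100), radius=2)
        with pytest.raises(MeasurementError):
            sample_region_temperature(img, shape)

    def test_sampling_linearity(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 1, (15, 15, 4))
        b = rng.uniform(0, 1, (15, 15, 4))
        bands = np.arange(4, dtype=float)
        shape = RegionShape(kind="circle", center=(7, 7), radius=3)
        sa, _ = sample_region_spectrum(SpectralCube(bands=bands, data=a), shape)
        sb, _ = sample_region_spectrum(SpectralCube(bands=bands, data=b), shape)
        sab, _ = sample_region_spectrum(
            SpectralCube(bands=bands, data=a + b), shape)
        assert np.allclose(sab, sa + sb)

    def test_invalid_shapes_rejected(self):
        with pytest.raises(MeasurementError):
            RegionShape(kind="circle", center=(1, 1), radius=0)
        with pytest.raises(MeasurementError):
            RegionShape(kind="line", endpoints=((1, 1), (1, 1)))
        with pytest.raises(MeasurementError):
            RegionShape(kind="blob")


class TestRedEdge:
    bands = np.linspace(400.0, 900.0, 56)

    def test_flat_spectrum_zero_everywhere_tie_to_first(self):
        wl, d = red_edge_derivative(self.bands, np.zeros(56),
                                    window=(680, 740))
        assert d == 0.0
        first_in_window = self.bands[self.bands >= 680][0]
        assert wl == pytest.approx(first_in_window)

    def test_constant_spectrum_derivative_negligible(self):
        _, d = red_edge_derivative(self.bands, np.full(56, 0.5),
                                   window=(680, 740))
        assert d == pytest.approx(0.0, abs=1e-15)

    def test_linear_ramp_slope(self):
        spec = 0.002 * self.bands
        wl, d = red_edge_derivative(self.bands, spec, window=(680, 740))
        assert d == pytest.approx(0.002, rel=1e-9)

    def test_logistic_step_located(self):
        spec = 0.4 / (1.0 + np.exp(-(self.bands - 710.0) / 5.0))
        wl, _ = red_edge_derivative(self.bands, spec, window=(680, 740))
        spacing = self.bands[1] - self.bands[0]
        assert abs(wl - 710.0) <= spacing

    def test_window_outside_bands_errors(self):
        with pytest.raises(MeasurementError):
            red_edge_derivative(self.bands, np.zeros(56), window=(300, 500))

    def test_too_few_bands_in_window(self):
        with pytest.raises(MeasurementError):
            red_edge_derivative(self.bands, np.zeros(56),
                                window=(700.0, 705.0))


class TestExport:
    def readings(self):
        return [
            FluorometerReading(F=0.4, F_M_prime=0.8,
                               site=(0.1, 0.2, 0.3), site_index=1),
            FluorometerReading(F=0.2, F_M_prime=0.8,
                               site=(0.15, 0.25, 0.35), site_index=2),
        ]

    def test_csv_columns(self, tmp_path):
        path = export_records(self.readings(), tmp_path / "y.csv", "csv")
        df = import_records(path)
        assert list(df.columns) == ["site_index", "x", "y", "z", "YII"]
        assert df["YII"].tolist() == pytest.approx([0.5, 0.75])

    def test_json_roundtrip(self, tmp_path):
        path = export_records(self.readings(), tmp_path / "y.json", "json")
        df = import_records(path)
        assert len(df) == 2
        assert df.loc[0, "YII"] == pytest.approx(0.5)
        assert df.loc[1, "x"] == pytest.approx(0.15)

    def test_empty_records_error(self, tmp_path):
        with pytest.raises(MeasurementError):
            export_records([], tmp_path / "y.csv", "csv")

    def test_unknown_format_error(self, tmp_path):
        with pytest.raises(MeasurementError):
            export_records(self.readings(), tmp_path / "y.xml", "xml")

    def test_png_renders(self, tmp_path):
        img = np.zeros((50, 50))
        shapes = [RegionShape(kind="circle", center=(25, 25), radius=10)]
        path = export_records(self.readings(), tmp_path / "y.png", "png",
                              image=img, shapes=shapes)
        assert path.exists() and path.stat().st_size > 0
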