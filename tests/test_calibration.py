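import math

import numpy as np
import pytest

from vogkit.calibration import (
    CalibrationError,
    EyeModel,
    aggregate_fixation,
    apply_calibration,
    estimate_radius,
    fit_eye_model,
    fit_regression,
    load_calibration,
    model_pixels_to_degrees,
    read_target_schedule,
    save_calibration,
)
from vogkit.core.types import Ellipse, EyeDatum, Eye, Glint, Point


class TestFitEyeModel:
    def test_median_center_from_jittered_fixation(self, rng):
        true = np.array([180.0, 135.0])
        samples = [Point(*(true + rng.normal(0, 0.2, 2))) for _ in range(100)]
        model = fit_eye_model(samples, radius_px=260.0)
        assert abs(model.center_ref.x - 180.0) < 0.1
        assert abs(model.center_ref.y - 135.0) < 0.1

    def test_radius_closed_form(self):
        # two fixations 10 deg apart, 45 px apart: r = 45 / sin(10 deg)
        r = estimate_radius(45.0, 10.0)
        assert r == pytest.approx(45.0 / math.sin(math.radians(10.0)), abs=1e-9)
        assert r == pytest.approx(259.1, abs=0.1)

    def test_empty_samples_rejected(self):
        with pytest.raises(CalibrationError):
            fit_eye_model([], radius_px=260.0)

    def test_unstable_fixation_rejected(self, rng):
        samples = [Point(*rng.normal(0, 20.0, 2)) for _ in range(50)]
        with pytest.raises(CalibrationError, match="unstable"):
            fit_eye_model(samples, radius_px=260.0)


class TestModelPixelsToDegrees:
    model = EyeModel(Point(180.0, 135.0), 259.1)

    def test_zero_offset(self):
        s = model_pixels_to_degrees(self.model, Point(180.0, 135.0))
        assert s.h_deg == pytest.approx(0.0, abs=1e-12)
        assert s.v_deg == pytest.approx(0.0, abs=1e-12)

    def test_half_radius_is_30_degrees(self):
        s = model_pixels_to_degrees(self.model, Point(180.0 + 259.1 / 2, 135.0))
        assert s.h_deg == pytest.approx(30.0, abs=1e-9)

    def test_vertical_sign_convention(self):
        dy = -259.1 * math.sin(math.radians(10.0))  # upward in image
        s = model_pixels_to_degrees(self.model, Point(180.0, 135.0 + dy))
        assert s.v_deg == pytest.approx(10.0, abs=1e-9)

    def test_out_of_range_flagged(self):
        s = model_pixels_to_degrees(self.model, Point(180.0 + 300.0, 135.0))
        assert not s.valid
        assert math.isnan(s.h_deg)


class TestFitRegression:
    @staticmethod
    def grid_features(gain=0.1, intercept=-20.0):
        # synthetic linear device: h = gain*x + intercept, v = gain*y
        targets, feats = [], []
        for h in (-10.0, 0.0, 10.0):
            for v in (-10.0, 0.0, 10.0):
                x = (h - intercept) / gain
                y = v / gain
                feats.append((x, y))
                targets.append((h, v))
        return feats, targets

    def test_exact_linear_recovery(self):
        feats, targets = self.grid_features()
        cal = fit_regression(feats, targets)
        assert cal.coef_h[1] == pytest.approx(0.1, abs=1e-9)
        assert cal.coef_h[0] == pytest.approx(-20.0, abs=1e-6)
        assert cal.residual_rms[0] == pytest.approx(0.0, abs=1e-9)
        assert cal.residual_rms[1] == pytest.approx(0.0, abs=1e-9)

    def test_collinear_targets_rejected(self):
        feats = [(0.0, 50.0), (10.0, 50.0), (20.0, 50.0)]
        targets = [(-5.0, 0.0), (0.0, 0.0), (5.0, 0.0)]
        with pytest.raises(CalibrationError, match="collinear|rank"):
            fit_regression(feats, targets)

    def test_noise_residual_scale(self, rng):
        # gain 0.1 deg/px, pixel noise sigma=0.5 px -> residual ~0.05 deg
        feats, targets = self.grid_features()
        noisy = [(x + rng.normal(0, 0.5), y + rng.normal(0, 0.5))
                 for x, y in feats]
        cal = fit_regression(noisy, targets)
        for r in cal.residual_rms:
            assert 0.025 < r < 0.075  # 0.05 deg +/- 50%

    def test_too_few_targets(self):
        with pytest.raises(CalibrationError):
            fit_regression([(0, 0), (1, 1)], [(0, 0), (1, 1)])


class TestApplyCalibration:
    @staticmethod
    def datum_with_pupil(x, y, torsion=None):
        pupil = Ellipse(Point(x, y), 40.0, 40.0, 0.0)
        return EyeDatum(0, 0.0, Eye.LEFT, pupil=pupil, torsion_deg=torsion)

    def test_interpolation_at_node(self):
        feats, targets = TestFitRegression.grid_features()
        cal = fit_regression(feats, targets)
        x, y = feats[4]
        s = apply_calibration(cal, self.datum_with_pupil(x, y))
        assert s.h_deg == pytest.approx(targets[4][0], abs=1e-6)
        assert s.v_deg == pytest.approx(targets[4][1], abs=1e-6)

    def test_missing_pupil_flagged(self):
        feats, targets = TestFitRegression.grid_features()
        cal = fit_regression(feats, targets)
        s = apply_calibration(cal, EyeDatum(0, 0.0, Eye.LEFT))
        assert not s.valid and math.isnan(s.h_deg)

    def test_identity_calibration(self):
        feats = [(-1.0, -1.0), (0.0, 0.0), (1.0, 1.0), (1.0, -1.0), (-1.0, 1.0)]
        cal = fit_regression(feats, feats)
        s = apply_calibration(cal, self.datum_with_pupil(0.37, -0.21))
        assert s.h_deg == pytest.approx(0.37, abs=1e-9)
        assert s.v_deg == pytest.approx(-0.21, abs=1e-9)

    def test_torsion_rezeroed(self):
        feats, targets = TestFitRegression.grid_features()
        cal = fit_regression(feats, targets)
        cal.torsion_ref_deg = 1.5
        s = apply_calibration(cal, self.datum_with_pupil(0.0, 0.0, torsion=2.0))
        assert s.torsion_deg == pytest.approx(0.5)

    def test_pupil_cr_feature(self):
        feats, targets = TestFitRegression.grid_features()
        cal = fit_regression(feats, targets, feature="pupil_cr")
        x, y = feats[0]
        datum = self.datum_with_pupil(x + 50.0, y + 60.0)
        datum.glints = [Glint(Point(50.0, 60.0), 4, 250.0)]
        s = apply_calibration(cal, datum)
        assert s.h_deg == pytest.approx(targets[0][0], abs=1e-6)


class TestModelRegressionAgreement:
    def test_small_angle_agreement(self):
        model = EyeModel(Point(200.0, 150.0), 259.1)
        feats, targets = [], []
        for h in (-5.0, 0.0, 5.0):
            for v in (-5.0, 0.0, 5.0):
                x = 200.0 + 259.1 * math.sin(math.radians(h))
                y = 150.0 - 259.1 * math.sin(math.radians(v))
                feats.append((x, y))
                targets.append((h, v))
        cal = fit_regression(feats, targets)
        for h in np.linspace(-5, 5, 11):
            x = 200.0 + 259.1 * math.sin(math.radians(h))
            m = model_pixels_to_degrees(model, Point(x, 150.0))
            r = cal.predict(Point(x, 150.0))
            assert abs(m.h_deg - r[0]) < 0.1

    def test_regression_recovers_model_gain_at_center(self):
        # local gain d(deg)/d(px) at center = 1 / (r * pi/180)
        r_px = 259.1
        feats, targets = [], []
        for h in (-5.0, 0.0, 5.0):
            for v in (-5.0, 0.0, 5.0):
                feats.append((r_px * math.sin(math.radians(h)),
                              -r_px * math.sin(math.radians(v))))
                targets.append((h, v))
        cal = fit_regression(feats, targets)
        expected_gain = 1.0 / (r_px * math.pi / 180.0)
        assert cal.coef_h[1] == pytest.approx(expected_gain, rel=0.02)
        assert -cal.coef_v[2] == pytest.approx(expected_gain, rel=0.02)


class TestFilesAndSchedules:
    def test_calibration_file_roundtrip(self, tmp_path):
        feats, targets = TestFitRegression.grid_features()
        cal = fit_regression(feats, targets)
        cal.torsion_ref_deg = 0.25
        path = tmp_path / "cal.txt"
        save_calibration(cal, path)
        back = load_calibration(path)
        np.testing.assert_allclose(back.coef_h, cal.coef_h)
        np.testing.assert_allclose(back.coef_v, cal.coef_v)
        assert back.feature == cal.feature
        assert back.torsion_ref_deg == 0.25

    def test_target_schedule_parsing(self, tmp_path):
        path = tmp_path / "targets.txt"
        path.write_text("# schedule\n0.0 1.0 -10.0 0.0\n1.0 2.0 0.0 5.0\n")
        dwells = read_target_schedule(path)
        assert len(dwells) == 2
        assert dwells[0].h_deg == -10.0
        assert dwells[1].v_deg == 5.0

    def test_aggregate_fixation_middle_half_median(self):
        from vogkit.calibration import TargetDwell

        times = np.linspace(0.0, 1.0, 101)
        feats = np.tile([[5.0, 7.0]], (101, 1))
        feats[:20] = 99.0  # settle-in transient outside the middle window
        agg = aggregate_fixation(times, feats, TargetDwell(0.0, 1.0, 0, 0))
        assert agg == (5.0, 7.0)
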