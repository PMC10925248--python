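import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from vogkit.core.types import Point
from vogkit.pupil import (
    PupilMethod,
    binarize_dark,
    find_pupil_component,
    fit_ellipse,
    pupil_centroid,
    pupil_convex_hull,
    track_pupil,
)
from vogkit.synthetic import render_frame

from conftest import make_disk


class TestBinarize:
    def test_uniform_above_threshold_all_false(self):
        img = np.full((10, 10), 200, np.uint8)
        assert not binarize_dark(img, 100).any()

    def test_disk_recovered(self):
        img = make_disk((100, 100), (50, 40), 12)
        mask = binarize_dark(img, 100)
        np.testing.assert_array_equal(mask, img < 100)
        assert mask.sum() > 0

    def test_threshold_zero_strict_inequality(self):
        img = np.zeros((5, 5), np.uint8)
        assert not binarize_dark(img, 0).any()

    @given(threshold_lo=st.integers(0, 254), delta=st.integers(1, 255))
    @hsettings(max_examples=50, deadline=None)
    def test_monotone_in_threshold(self, threshold_lo, delta):
        rng = np.random.default_rng(threshold_lo * 1000 + delta)
        img = rng.integers(0, 256, (20, 20), dtype=np.uint8)
        lo = binarize_dark(img, threshold_lo)
        hi = binarize_dark(img, min(255, threshold_lo + delta))
        assert (lo <= hi).all()  # raising threshold never shrinks the mask


class TestFindComponent:
    def test_largest_in_range_selected(self):
        mask = np.zeros((100, 200), bool)
        ys, xs = np.mgrid[0:100, 0:200]
        small = (xs - 40) ** 2 + (ys - 50) ** 2 <= 9.5 ** 2   # ~300 px
        large = (xs - 150) ** 2 + (ys - 50) ** 2 <= 17 ** 2   # ~900 px
        mask |= small | large
        comp = find_pupil_component(mask, 500, 2000)
        assert comp is not None
        assert abs(comp.centroid.x - 150) < 1

    def test_none_in_range(self):
        mask = np.zeros((50, 50), bool)
        mask[10:12, 10:12] = True  # area 4
        assert find_pupil_component(mask, 100, 1000) is None

    def test_equal_area_tiebreak_prefers_center(self):
        # two identical 5x5 squares, one nearer the image center
        mask = np.zeros((40, 100), bool)
        mask[18:23, 5:10] = True     # far from center (x~7)
        mask[18:23, 45:50] = True    # near center (x~47, center x=49.5)
        comp = find_pupil_component(mask, 1, 100)
        assert comp.centroid.x == pytest.approx(47.0)

    def test_8_connectivity(self):
        mask = np.zeros((10, 10), bool)
        mask[2, 2] = mask[3, 3] = mask[4, 4] = True  # diagonal chain
        comp = find_pupil_component(mask, 3, 10)
        assert comp is not None and comp.area_px2 == 3


class TestCentroid:
    def test_symmetric_disk(self):
        img = make_disk((100, 100), (50, 40), 15)
        comp = find_pupil_component(binarize_dark(img, 100), 10, 10000)
        c = pupil_centroid(comp)
        assert c.x == pytest.approx(50.0, abs=1e-9)
        assert c.y == pytest.approx(40.0, abs=1e-9)

    def test_2x2_square(self):
        mask = np.zeros((5, 5), bool)
        mask[0:2, 0:2] = True
        comp = find_pupil_component(mask, 1, 10)
        c = pupil_centroid(comp)
        assert (c.x, c.y) == (0.5, 0.5)

    def test_l_shape_matches_bruteforce(self):
        mask = np.zeros((30, 30), bool)
        mask[5:20, 5:9] = True
        mask[16:20, 5:25] = True
        comp = find_pupil_component(mask, 1, 10000)
        # independent oracle: exhaustive enumeration of member pixels
        pix = [(x, y) for y in range(30) for x in range(30) if mask[y, x]]
        ex = sum(p[0] for p in pix) / len(pix)
        ey = sum(p[1] for p in pix) / len(pix)
        c = pupil_centroid(comp)
        assert c.x == pytest.approx(ex, abs=1e-12)
        assert c.y == pytest.approx(ey, abs=1e-12)


class TestFitEllipse:
    @staticmethod
    def ellipse_points(cx, cy, a, b, angle_deg, n=36):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        phi = math.radians(angle_deg)
        x = cx + a * np.cos(t) * np.cos(phi) - b * np.sin(t) * np.sin(phi)
        y = cy + a * np.cos(t) * np.sin(phi) + b * np.sin(t) * np.cos(phi)
        return np.column_stack([x, y])

    def test_exact_recovery(self):
        pts = self.ellipse_points(100.0, 80.0, 20.0, 12.5, 30.0)
        e = fit_ellipse(pts)
        assert e.center.x == pytest.approx(100.0, abs=1e-6)
        assert e.center.y == pytest.approx(80.0, abs=1e-6)
        assert e.major_axis == pytest.approx(40.0, abs=1e-6)
        assert e.minor_axis == pytest.approx(25.0, abs=1e-6)
        assert e.angle_deg == pytest.approx(30.0, abs=1e-6)

    def test_circle_any_angle(self):
        pts = self.ellipse_points(0.0, 0.0, 10.0, 10.0, 0.0)
        e = fit_ellipse(pts)
        assert e.center.x == pytest.approx(0.0, abs=1e-6)
        assert e.major_axis == pytest.approx(20.0, abs=1e-6)
        assert e.minor_axis == pytest.approx(20.0, abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_ellipse(np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float))

    def test_collinear_points(self):
        pts = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(ValueError):
            fit_ellipse(pts)

    def test_angle_normalized(self):
        pts = self.ellipse_points(0, 0, 20, 10, 120.0)
        e = fit_ellipse(pts)
        assert 0 <= e.angle_deg < 180
        assert e.angle_deg == pytest.approx(120.0, abs=1e-5)


class TestConvexHull:
    def test_convex_disk_hull_center_matches_centroid(self):
        img = make_disk((120, 120), (60, 55), 20)
        comp = find_pupil_component(binarize_dark(img, 100), 10, 10000)
        centroid = pupil_centroid(comp)
        _, result = pupil_convex_hull(comp)
        assert result.found
        assert abs(result.ellipse.center.x - centroid.x) < 0.5
        assert abs(result.ellipse.center.y - centroid.y) < 0.5

    def test_hull_contains_all_pixels(self):
        img = make_disk((120, 120), (60, 55), 20)
        comp = find_pupil_component(binarize_dark(img, 100), 10, 10000)
        vertices, result = pupil_convex_hull(comp)
        assert result.found
        # every member pixel is inside (or on) the hull polygon
        from scipy.spatial import Delaunay

        hull = Delaunay(vertices)
        assert (hull.find_simplex(comp.pixel_coords()) >= 0).all()

    def test_notched_disk_hull_beats_centroid(self):
        # dark disk with its top sector occluded (bright), center known
        img = make_disk((150, 150), (75, 70), 30)
        img[:52, :] = 200  # notch: removes the cap above y=52
        comp = find_pupil_component(binarize_dark(img, 100), 10, 10000)
        centroid_err = math.hypot(*(np.array(pupil_centroid(comp)) - (75, 70)))
        _, result = pupil_convex_hull(comp)
        hull_err = math.hypot(result.ellipse.center.x - 75,
                              result.ellipse.center.y - 70)
        assert hull_err < centroid_err

    def test_collinear_pixels_not_found(self):
        mask = np.zeros((10, 10), bool)
        mask[5, 2:5] = True  # 3 collinear pixels
        comp = find_pupil_component(mask, 1, 10)
        _, result = pupil_convex_hull(comp)
        assert not result.found


class TestTrackPupil:
    def test_synthetic_frame_ellipse_method(self, scene, settings):
        img, truth = render_frame(scene)
        r = track_pupil(img, settings, PupilMethod.ELLIPSE_FIT)
        assert r.found
        err = math.hypot(r.ellipse.center.x - truth.pupil_x,
                         r.ellipse.center.y - truth.pupil_y)
        assert err < 0.5

    def test_blink_frame_not_found(self, settings):
        img = np.full((100, 100), 210, np.uint8)  # all bright: closed eye
        r = track_pupil(img, settings)
        assert not r.found and r.ellipse is None

    def test_method_agreement_on_clean_pupil(self, scene, settings):
        img, truth = render_frame(scene)
        centers = {}
        for m in PupilMethod:
            r = track_pupil(img, settings, m)
            assert r.found
            centers[m] = r.ellipse.center
        for m in (PupilMethod.CENTROID, PupilMethod.CONVEX_HULL):
            d = math.hypot(centers[m].x - centers[PupilMethod.ELLIPSE_FIT].x,
                           centers[m].y - centers[PupilMethod.ELLIPSE_FIT].y)
            assert d < 1.0

    def test_centroid_method_reports_equivalent_circle(self, settings):
        img = make_disk((100, 100), (50, 50), 15)
        r = track_pupil(img, settings, PupilMethod.CENTROID)
        assert r.found
        assert r.ellipse.major_axis == r.ellipse.minor_axis
        # diameter of the equal-area circle ~ 2*radius
        assert r.ellipse.major_axis == pytest.approx(30.0, rel=0.05)

    def test_translation_equivariance(self, scene, settings):
        img, _ = render_frame(scene)
        dx, dy = 7, -3
        shifted = np.roll(np.roll(img, dy, axis=0), dx, axis=1)
        r0 = track_pupil(img, settings, PupilMethod.ELLIPSE_FIT)
        r1 = track_pupil(shifted, settings, PupilMethod.ELLIPSE_FIT)
        assert r1.ellipse.center.x - r0.ellipse.center.x == pytest.approx(dx, abs=0.05)
        assert r1.ellipse.center.y - r0.ellipse.center.y == pytest.approx(dy, abs=0.05)

    def test_rotation_90_consistency(self, scene, settings):
        img, _ = render_frame(dataclasses.replace(scene, gaze_h_deg=8.0))
        rot = np.rot90(img).copy()  # (x, y) -> (y, W-1-x)
        r0 = track_pupil(img, settings, PupilMethod.ELLIPSE_FIT)
        r1 = track_pupil(rot, settings, PupilMethod.ELLIPSE_FIT)
        w = img.shape[1]
        assert r1.ellipse.center.x == pytest.approx(r0.ellipse.center.y, abs=0.1)
        assert r1.ellipse.center.y == pytest.approx(w - 1 - r0.ellipse.center.x, abs=0.1)
        assert r1.ellipse.major_axis == pytest.approx(r0.ellipse.major_axis, rel=0.01)

    def test_roi_restricts_search(self, settings):
        img = make_disk((100, 200), (40, 50), 12)   # pupil at x=40
        img = np.minimum(img, make_disk((100, 200), (150, 50), 12))
        settings.roi = "100,0,200,100"
        r = track_pupil(img, settings)
        assert r.found
        assert r.ellipse.center.x == pytest.approx(150, abs=1.0)
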