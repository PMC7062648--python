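"""Landmark -> geometry extraction: orientations, heights, Cobb, apex."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import scoliosim as ss
from scoliosim.frames import LEVELS
from scoliosim.geometry import (
    InvalidLandmarkError,
    NoCurveError,
    compute_cobb,
    read_landmarks_csv,
    write_landmarks_csv,
)

from conftest import make_rect_landmarks


def rotate_plane(points, angle_deg, center):
    a = math.radians(angle_deg)
    R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    return {k: center + R @ (v - center) for k, v in points.items()}


class TestExtractOrientation:
    def test_axis_aligned_vertebra_has_zero_rotations(self):
        lm = make_rect_landmarks()
        assert ss.extract_orientation(lm) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_equal_upper_and_lower_slopes_force_the_mean(self):
        lm = make_rect_landmarks()
        c = np.array([0.0, 100.0])
        lm.sagittal = rotate_plane(lm.sagittal, 10.0, c)
        sag, fro, axi = ss.extract_orientation(lm)
        assert sag == pytest.approx(10.0, abs=1e-9)
        assert fro == pytest.approx(0.0, abs=1e-12)

    def test_sagittal_rotation_is_mean_of_endplate_slopes(self):
        lm = make_rect_landmarks()
        c_up = np.array([0.0, 110.0])
        c_lo = np.array([0.0, 90.0])
        upper = rotate_plane({k: lm.sagittal[k] for k in ("UA", "UP")}, 8.0, c_up)
        lower = rotate_plane({k: lm.sagittal[k] for k in ("LA", "LP")}, 4.0, c_lo)
        lm.sagittal = {**upper, **lower}
        sag, _, _ = ss.extract_orientation(lm)
        assert sag == pytest.approx(6.0, abs=1e-9)

    def test_axial_rotation_from_spinous_offset(self):
        depth = 40.0
        lm = make_rect_landmarks(spinous_dz=depth * math.sin(math.radians(7.0)))
        _, _, axi = ss.extract_orientation(lm, spinous_depth_mm=depth)
        assert axi == pytest.approx(7.0, abs=1e-9)

    def test_coincident_corners_raise(self):
        lm = make_rect_landmarks()
        lm.sagittal["UA"] = lm.sagittal["UP"].copy()
        with pytest.raises(InvalidLandmarkError):
            ss.extract_orientation(lm)


class TestExtractHeight:
    @pytest.mark.parametrize(
        "frontal_deg, h_sag, expected",
        [
            (0.0, 20.0, 20.0),
            (60.0, 10.0, 20.0),
            (25.0, 18.0, 18.0 / math.cos(math.radians(25.0))),
        ],
    )
    def test_projection_correction(self, frontal_deg, h_sag, expected):
        # construct an isolated vertebra whose own endplate centroids span h_sag
        lm = make_rect_landmarks(half_height=h_sag / 2.0)
        got_sag, got_total = ss.extract_height(lm, frontal_rot_deg=frontal_deg)
        assert got_sag == pytest.approx(h_sag, abs=1e-9)
        assert got_total == pytest.approx(expected, abs=1e-9)

    def test_correction_monotone_in_tilt(self):
        h = [ss.extract_height(make_rect_landmarks(), frontal_rot_deg=a)[1] for a in range(0, 89, 4)]
        assert all(b >= a for a, b in zip(h, h[1:]))


class TestCobb:
    def test_straight_spine_reports_zero_with_extreme_ends(self):
        cobb, upper, lower = compute_cobb([0.0] * 17)
        assert cobb == 0.0 and (upper, lower) == ("T1", "L5")

    def test_linear_ramp_gives_end_to_end_difference(self):
        f = [0.0] * 17
        idx6, idx12 = LEVELS.index("T6"), LEVELS.index("T12")
        for k, i in enumerate(range(idx6, idx12 + 1)):
            f[i] = 12.0 - 24.0 * k / (idx12 - idx6)
        cobb, upper, lower = compute_cobb(f)
        assert cobb == pytest.approx(24.0)
        assert (upper, lower) == ("T6", "T12")

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-40, 40), min_size=17, max_size=17))
    def test_matches_exhaustive_pairwise_search(self, f):
        cobb, upper, lower = compute_cobb(f)
        brute = max(
            abs(f[i] - f[j]) for i in range(17) for j in range(i + 1, 17)
        )
        assert cobb == pytest.approx(brute)

    def test_round_trip_with_generator(self):
        geom = ss.generate_curve(apex="T9", cobb_target=22.0, convexity="left")
        assert geom.cobb_deg == pytest.approx(22.0, abs=0.5)


class TestApex:
    def test_straight_spine_has_no_apex(self):
        geom = ss.generate_curve(cobb_target=0.0)
        with pytest.raises(NoCurveError):
            ss.find_apex(geom)

    @pytest.mark.parametrize("convexity", ["left", "right"])
    def test_single_curve_apex_and_side(self, convexity):
        geom = ss.generate_curve(apex="T8", cobb_target=24.0, convexity=convexity)
        apex, side = ss.find_apex(geom)
        assert apex == "T8"
        assert side == convexity

    def test_mirror_flips_convexity_keeps_cobb(self, subject_geometry):
        mirrored = subject_geometry.mirrored()
        assert mirrored.cobb_deg == pytest.approx(subject_geometry.cobb_deg)
        apex, side = ss.find_apex(mirrored)
        assert apex == subject_geometry.apex_level
        assert side == "left"  # original is right-convex


class TestRoundTrip:
    @pytest.mark.parametrize("apex,convexity,cobb", [("T8", "right", 24.0), ("T11", "left", 15.0)])
    def test_zero_noise_recovers_geometry_exactly(self, apex, convexity, cobb):
        geom = ss.generate_curve(apex=apex, cobb_target=cobb, convexity=convexity)
        lms = ss.landmarks_from_geometry(geom, noise_sd=0.0)
        back = ss.extract_geometry(lms)
        for p, q in zip(geom.poses, back.poses):
            assert q.sagittal_rot == pytest.approx(p.sagittal_rot, abs=1e-6)
            assert q.frontal_rot == pytest.approx(p.frontal_rot, abs=1e-6)
            assert q.axial_rot == pytest.approx(p.axial_rot, abs=1e-6)
            assert q.h_sagittal == pytest.approx(p.h_sagittal, abs=1e-6)
            assert q.h_total == pytest.approx(p.h_total, abs=1e-6)
            assert np.allclose(q.center, p.center, atol=1e-6)
        assert back.apex_level == apex and back.convexity == convexity

    @settings(max_examples=10, deadline=None)
    @given(
        apex=st.sampled_from(["T7", "T8", "T9", "T10", "T12"]),
        cobb=st.floats(6.0, 34.0),
        kyph=st.floats(18.0, 42.0),
    )
    def test_orientation_round_trip_over_curve_space(self, apex, cobb, kyph):
        geom = ss.generate_curve(apex=apex, cobb_target=cobb, kyphosis_deg=kyph)
        back = ss.extract_geometry(ss.landmarks_from_geometry(geom, noise_sd=0.0))
        for p, q in zip(geom.poses, back.poses):
            assert abs(q.frontal_rot - p.frontal_rot) < 1e-6
            assert abs(q.sagittal_rot - p.sagittal_rot) < 1e-6


class TestLandmarkIO:
    def test_csv_round_trip(self, tmp_path, subject_geometry):
        lms = ss.landmarks_from_geometry(subject_geometry, noise_sd=0.0)
        path = tmp_path / "lm.csv"
        write_landmarks_csv(path, "S01", lms)
        loaded = read_landmarks_csv(path)
        assert set(loaded) == {"S01"}
        for a, b in zip(lms, loaded["S01"]):
            assert a.level == b.level
            assert np.allclose(a.spinous, b.spinous)
            for role in a.sagittal:
                assert np.allclose(a.sagittal[role], b.sagittal[role])

    def test_missing_points_rejected(self, tmp_path, subject_geometry):
        lms = ss.landmarks_from_geometry(subject_geometry, noise_sd=0.0)
        path = tmp_path / "lm.csv"
        write_landmarks_csv(path, "S01", lms)
        df = __import__("pandas").read_csv(path)
        df.drop(index=[0]).to_csv(path, index=False)
        with pytest.raises(InvalidLandmarkError):
            read_landmarks_csv(path)
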