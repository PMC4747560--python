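"""Face-model geometry: centre construction, ellipse radii, placement."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from facemark.geometry import (
    MARKER_IDS,
    EyePair,
    FaceGeometry,
    GeometryError,
    MarkerPlacement,
    PlacementProfile,
    compute_center,
    default_profile,
    ellipse_radius_at,
    marker_distance,
    mirror_markers,
    place_marker,
    place_markers,
)


class TestComputeCenter:
    @pytest.mark.parametrize(
        "eyes,emd,expected",
        [
            (((40, 50), (80, 50)), 40, (60, 70)),
            (((100, 120), (160, 120)), 70, (130, 155)),
        ],
    )
    def test_midpoint_plus_half_offset(self, eyes, emd, expected):
        assert compute_center(EyePair(*eyes), emd) == pytest.approx(expected)

    def test_degenerate_eye_mouth_distance(self):
        with pytest.raises(GeometryError):
            compute_center(EyePair((0, 0), (10, 0)), 0)

    def test_eye_order_enforced(self):
        with pytest.raises(GeometryError):
            EyePair((10, 0), (0, 0))


class TestEllipseRadius:
    def test_circle_is_angle_independent(self):
        g = FaceGeometry((0, 0), 50, 50)
        for ang in (0, 30, 45, 77, 90, 130):
            assert ellipse_radius_at(g, ang) == pytest.approx(50.0)

    def test_axis_cases(self):
        g = FaceGeometry((0, 0), 80, 60)
        assert ellipse_radius_at(g, 0) == pytest.approx(80.0)
        assert ellipse_radius_at(g, 90) == pytest.approx(60.0)
        assert ellipse_radius_at(g, 45) == pytest.approx(67.88, abs=0.005)

    @given(
        a=st.floats(20, 200),
        b=st.floats(20, 200),
        angle=st.floats(0, 180),
    )
    def test_matches_parametric_ray_intersection(self, a, b, angle):
        """r(theta) equals a brute-force intersection of the ray with the
        parametric ellipse boundary."""
        g = FaceGeometry((0, 0), a, b)
        th = math.radians(angle)
        # brute force: scale the unit ray direction until it satisfies the
        # implicit ellipse equation
        cx, sx = math.cos(th), math.sin(th)
        r_ref = 1.0 / math.sqrt((cx / a) ** 2 + (sx / b) ** 2)
        assert ellipse_radius_at(g, angle) == pytest.approx(r_ref, rel=1e-9)


class TestPlacement:
    def test_eyebrow_marker_on_circle(self):
        g = FaceGeometry((100, 100), 90, 90)
        p = MarkerPlacement(45.0, 6.5 / 9, "upper", "left")
        x, y = place_marker(g, p)
        assert (x, y) == pytest.approx((54.04, 54.04), abs=0.005)
        assert marker_distance((100, 100), (x, y)) == pytest.approx(65.0)

    def test_zero_ratio_collapses_to_center(self, ellipse_geom):
        prof = PlacementProfile(
            {mid: MarkerPlacement(p.angle_deg, 0.0, p.hemisphere, p.side)
             for mid, p in default_profile().placements.items()}
        )
        ms = place_markers(ellipse_geom, prof)
        for xy in ms.markers.values():
            assert xy == pytest.approx(ellipse_geom.center)

    def test_hemispheres(self, ellipse_geom):
        ms = place_markers(ellipse_geom)
        yc = ellipse_geom.center[1]
        for mid in ("p_e1", "p_e2", "p_e3", "p_e4"):
            assert ms.markers[mid][1] < yc, f"{mid} must be above the centre"
        for mid in ("p_m1", "p_m2", "p_m3", "p_m4"):
            assert ms.markers[mid][1] > yc, f"{mid} must be below the centre"

    def test_midline_markers_on_vertical_axis(self, ellipse_geom):
        ms = place_markers(ellipse_geom)
        for mid in ("p_m3", "p_m4"):
            assert ms.markers[mid][0] == ellipse_geom.center[0]

    def test_symmetric_profile_is_mirror_symmetric(self, circle_geom):
        pairs = [("p_e1", "p_e2"), ("p_e3", "p_e4"), ("p_m1", "p_m2")]
        base = default_profile().placements
        sym = dict(base)
        for left, right in pairs:
            pl = base[left]
            sym[right] = MarkerPlacement(
                pl.angle_deg, pl.ratio, pl.hemisphere, "right"
            )
        ms = place_markers(circle_geom, PlacementProfile(sym))
        xc = circle_geom.center[0]
        for left, right in pairs:
            lx, ly = ms.markers[left]
            rx, ry = ms.markers[right]
            assert abs(lx - xc) == pytest.approx(abs(rx - xc))
            assert ly == pytest.approx(ry)

    def test_out_of_image_warning_and_clamp(self, ellipse_geom):
        with pytest.warns(UserWarning):
            ms = place_markers(ellipse_geom, image_shape=(130, 300), clamp=True)
        for x, y in ms.markers.values():
            assert 0 <= x <= 299 and 0 <= y <= 129

    @given(
        ex=st.floats(60, 120), ey=st.floats(40, 120),
        axis=st.floats(-50, 250),
    )
    def test_reflecting_eyes_reflects_marker_set(self, ex, ey, axis):
        """With a left/right-symmetric profile, mirroring the eye pair
        mirrors every placed marker (identities swapping sides)."""
        from facemark.geometry import geometry_from_eyes

        base = default_profile().placements
        sym = dict(base)
        for left, right in (("p_e1", "p_e2"), ("p_e3", "p_e4"),
                            ("p_m1", "p_m2")):
            pl = base[left]
            sym[right] = MarkerPlacement(pl.angle_deg, pl.ratio,
                                         pl.hemisphere, "right")
        prof = PlacementProfile(sym)
        eyes = EyePair((ex, ey), (ex + 50, ey))
        ms = place_markers(geometry_from_eyes(eyes), prof)
        ms_ref = place_markers(geometry_from_eyes(eyes.mirrored(axis)), prof)
        expected = mirror_markers(ms, axis)
        for mid in MARKER_IDS:
            assert ms_ref.markers[mid] == pytest.approx(
                expected.markers[mid], abs=1e-9
            )


class TestMarkerDistance:
    def test_pythagorean_triple(self):
        assert marker_distance((0, 0), (3, 4)) == 5.0

    def test_identity_and_symmetry(self):
        assert marker_distance((7, 2), (7, 2)) == 0.0
        assert marker_distance((1, 2), (5, -1)) == marker_distance((5, -1), (1, 2))

    @given(
        angle=st.floats(1, 89), ratio=st.floats(0.05, 1.4),
        a=st.floats(30, 150), b=st.floats(30, 150),
    )
    def test_distance_equals_ratio_times_radius(self, angle, ratio, a, b):
        g = FaceGeometry((200, 200), a, b)
        p = MarkerPlacement(angle, ratio, "upper", "right")
        xy = place_marker(g, p)
        assert marker_distance(g.center, xy) == pytest.approx(
            ratio * ellipse_radius_at(g, angle), rel=1e-12
        )


class TestProfileSerialization:
    def test_yaml_round_trip(self, tmp_path):
        prof = default_profile()
        path = tmp_path / "profile.yaml"
        prof.save(path)
        loaded = PlacementProfile.load(path)
        assert loaded == prof

    def test_profile_requires_all_markers(self):
        with pytest.raises(GeometryError):
            PlacementProfile({"p_e1": MarkerPlacement(45, 0.7, "upper", "left")})


def test_default_profile_rounds_to_prose_values():
    """The calibrated defaults agree with the coarse published readings:
    eyebrow angles ~45 and ~65 deg, mouth corners ~130, midline ~90;
    ratios ~0.72, ~0.55, ~0.73 and ~0.33."""
    prof = default_profile()
    assert round(prof["p_e1"].angle_deg) == 45
    assert round(prof["p_e2"].angle_deg) == 45
    assert round(prof["p_e3"].angle_deg) == 65
    assert round(prof["p_e4"].angle_deg) == 65
    assert round(prof["p_m1"].angle_deg) == 130
    assert round(prof["p_m2"].angle_deg) == 130
    assert round(prof["p_m3"].angle_deg) == 90
    assert round(prof["p_m4"].angle_deg) == 90
    assert prof["p_e1"].ratio == pytest.approx(0.72, abs=0.0051)
    assert prof["p_e2"].ratio == pytest.approx(0.55, abs=0.0051)
    assert prof["p_m1"].ratio == pytest.approx(0.73, abs=0.0051)
    assert prof["p_m3"].ratio == pytest.approx(0.33, abs=0.0051)
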