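"""Centerline resampling, plane slicing, area profiles, constriction metrics."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from airwayloss import geometry
from airwayloss.errors import EmptySectionError, InvalidInputError


def gaussian_profile(A0=117.0, c=0.825, x0=0.0, sigma=12.5, span=80.0, n=400):
    x = np.linspace(x0 - span, x0 + span, n)
    A = A0 * (1.0 - c * np.exp(-((x - x0) ** 2) / (2 * sigma**2)))
    return geometry.AreaProfile(x=x, A=A)


class TestResampleCenterline:
    def test_straight_segment_unit_spacing(self):
        pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 10.0]])
        cl = geometry.resample_centerline(pts, spacing=1.0)
        assert len(cl.points) == 11
        assert np.allclose(cl.arclength, np.arange(11.0))
        assert np.allclose(cl.points[0], pts[0]) and np.allclose(cl.points[-1], pts[1])

    def test_quarter_circle_arclength_converges(self):
        # quarter circle of radius 10 has arclength 5*pi
        theta = np.linspace(0, np.pi / 2, 2000)
        pts = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta), 0 * theta])
        cl = geometry.resample_centerline(pts, spacing=0.05)
        assert cl.total_length == pytest.approx(5 * np.pi, rel=1e-5)

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(InvalidInputError):
            geometry.resample_centerline(np.zeros((3, 3)), spacing=1.0)
        with pytest.raises(InvalidInputError):
            geometry.resample_centerline(np.array([[0, 0, 0], [0, 0, 1.0]]), spacing=-1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.integers(3, 12),
        spacing=st.floats(0.1, 3.0),
        seed=st.integers(0, 1000),
    )
    def test_uniform_spacing_and_endpoints(self, n, spacing, seed):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.uniform(0.2, 4.0, size=(n, 3)), axis=0)
        cl = geometry.resample_centerline(pts, spacing)
        steps = np.diff(cl.arclength)
        assert np.all(np.abs(steps - steps[0]) < 1e-6)
        assert np.allclose(cl.points[0], pts[0], atol=1e-9)
        assert np.allclose(cl.points[-1], pts[-1], atol=1e-9)


class TestFramesAlong:
    def test_straight_axial_line(self):
        cl = geometry.resample_centerline(
            np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 20.0]]), 2.0
        )
        for _, n in geometry.frames_along(cl):
            assert np.allclose(n, [0, 0, 1])

    def test_two_point_line_uses_chord(self):
        cl = geometry.Centerline(
            points=np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]]),
            arclength=np.array([0.0, 5.0]),
        )
        frames = geometry.frames_along(cl)
        assert len(frames) == 2
        for _, n in frames:
            assert np.allclose(n, [0.6, 0.8, 0.0])

    def test_circular_arc_tangents(self):
        theta = np.linspace(0, np.pi / 2, 200)
        r = 30.0
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), 0 * theta])
        s = np.concatenate([[0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        frames = geometry.frames_along(geometry.Centerline(pts, s))
        for (_, n), t in zip(frames[1:-1], theta[1:-1]):
            analytic = np.array([-np.sin(t), np.cos(t), 0.0])
            assert abs(np.linalg.norm(n) - 1.0) < 1e-12
            assert abs(abs(n @ analytic) - 1.0) < 1e-4


class TestSliceArea:
    def test_cylinder_circle_area(self):
        mesh = trimesh.creation.cylinder(radius=10.0, height=40.0, sections=128)
        sec = geometry.slice_area(mesh, [0, 0, 0], [0, 0, 1], [0, 0, 0])
        assert sec.area == pytest.approx(100 * np.pi, rel=2e-3)
        assert sec.hydraulic_diameter == pytest.approx(20.0, rel=2e-3)
        assert sec.perimeter == pytest.approx(20 * np.pi, rel=2e-3)

    def test_oblique_slice_is_ellipse(self):
        mesh = trimesh.creation.cylinder(radius=10.0, height=60.0, sections=128)
        ang = np.pi / 6
        normal = [0.0, np.sin(ang), np.cos(ang)]
        sec = geometry.slice_area(mesh, [0, 0, 0], normal, [0, 0, 0])
        assert sec.area == pytest.approx(100 * np.pi / np.cos(ang), rel=5e-3)

    def test_plane_outside_mesh_raises(self):
        mesh = trimesh.creation.cylinder(radius=5.0, height=10.0, sections=32)
        with pytest.raises(EmptySectionError):
            geometry.slice_area(mesh, [0, 0, 100.0], [0, 0, 1], [0, 0, 100.0])

    def test_nearest_loop_selected(self):
        # two parallel tubes; near_point picks out the right lumen
        a = trimesh.creation.cylinder(radius=3.0, height=20.0, sections=64)
        b = a.copy()
        b.apply_translation([20.0, 0.0, 0.0])
        mesh = trimesh.util.concatenate([a, b])
        sec = geometry.slice_area(mesh, [0, 0, 0], [0, 0, 1], [20.0, 0.0, 0.0])
        c = sec.loops[0].mean(axis=0)
        assert np.linalg.norm(c[:2] - [20.0, 0.0]) < 1.0


class TestAreaProfile:
    def test_uniform_tube_constant(self):
        mesh = trimesh.creation.cylinder(radius=8.0, height=50.0, sections=96)
        mesh.apply_translation([0, 0, 25.0])
        pts = np.array([[0.0, 0.0, 2.0], [0.0, 0.0, 48.0]])
        cl = geometry.resample_centerline(pts, 2.0)
        prof = geometry.area_profile(mesh, cl)
        assert np.ptp(prof.A) / prof.A.mean() < 1e-6
        assert prof.A[0] == pytest.approx(64 * np.pi, rel=5e-3)
        # carina_offset 0 keeps raw arclength stations
        assert np.allclose(prof.x, cl.arclength)

    def test_carina_alignment_sign_convention(self, airway, default_shape):
        mesh, centerline, _ = airway
        cl = geometry.resample_centerline(centerline.points, 10.0)
        keep = (cl.arclength >= 5) & (cl.arclength <= default_shape.total_length - 5)
        cl = geometry.Centerline(cl.points[keep], cl.arclength[keep])
        prof = geometry.area_profile(mesh, cl, carina_offset=default_shape.total_length)
        assert np.all(prof.x < 0)  # everything superior to the carina


class TestLocalMinima:
    def test_three_dips_found_at_planted_stations(self):
        x = np.linspace(-260.0, 0.0, 1301)
        A = 120.0 * np.ones_like(x)
        for x0, depth, sig in [(-200.0, 0.5, 6.0), (-135.0, 0.4, 5.0), (-85.0, 0.8, 9.0)]:
            A -= 120.0 * depth * np.exp(-((x - x0) ** 2) / (2 * sig**2))
        stations, areas = geometry.local_minima(geometry.AreaProfile(x, A), k=3)
        assert np.allclose(stations, [-200.0, -135.0, -85.0], atol=0.5)
        assert np.all(np.diff(areas) != 0)

    def test_monotone_profile_has_none(self):
        prof = geometry.AreaProfile(np.arange(10.0), np.linspace(50, 20, 10))
        stations, areas = geometry.local_minima(prof, k=2)
        assert len(stations) == 0 and len(areas) == 0

    def test_flat_bottom_reports_midpoint(self):
        x = np.arange(11.0)
        A = np.array([50, 40, 30, 20, 20, 20, 20, 30, 40, 50, 60.0])
        stations, areas = geometry.local_minima(geometry.AreaProfile(x, A), k=1)
        assert stations[0] == pytest.approx(4.5)  # midpoint of the flat run 3..6
        assert areas[0] == 20.0


class TestConstrictionMetrics:
    def test_printed_severity_values(self):
        # first-ring vs minimum areas of the most and less constricted scans
        assert geometry.constriction_ratio(117.0, 20.5) == pytest.approx(0.825, abs=5e-4)
        assert geometry.constriction_ratio(148.0, 35.2) == pytest.approx(0.762, abs=5e-4)

    def test_constant_profile_no_constriction(self):
        prof = geometry.AreaProfile(np.arange(20.0), np.full(20, 80.0))
        cm = geometry.constriction_metrics(prof, ref_station=2.0)
        assert cm.ratio == 0.0 and cm.length == 0.0 and not cm.widened

    def test_gaussian_dip_length_closed_form(self):
        c, sigma, thr = 0.825, 12.5, 0.35
        prof = gaussian_profile(c=c, sigma=sigma, n=4000)
        cm = geometry.constriction_metrics(prof, ref_station=prof.x[0], threshold=thr)
        expected = 2 * sigma * np.sqrt(2 * np.log(c / thr))
        assert cm.length == pytest.approx(expected, rel=1e-3)
        assert cm.ratio == pytest.approx(c, rel=1e-3)

    def test_length_vanishes_as_threshold_approaches_depth(self):
        c, sigma = 0.825, 12.5
        prof = gaussian_profile(c=c, sigma=sigma, n=8000)
        for t in (0.35, 0.6, 0.8, 0.8245):
            cm = geometry.constriction_metrics(prof, prof.x[0], threshold=t)
            expected = 2 * sigma * np.sqrt(2 * np.log(c / t))
            assert cm.length == pytest.approx(expected, rel=0.02)
        # just above the dip depth nothing clears the threshold any more
        assert geometry.constriction_metrics(prof, prof.x[0], threshold=0.9).length == 0.0

    def test_widened_lumen_flagged_not_rejected(self):
        # post-operative lumen everywhere larger than an externally measured reference
        x = np.arange(10.0)
        A = np.linspace(100, 150, 10)
        cm = geometry.constriction_metrics(
            geometry.AreaProfile(x, A), ref_station=0.0, A_ref=90.0
        )
        assert cm.widened and cm.ratio < 0.0 and cm.length == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(offset=st.floats(-500, 500))
    def test_translation_invariance(self, offset):
        prof = gaussian_profile(n=800)
        cm0 = geometry.constriction_metrics(prof, ref_station=prof.x[0])
        moved = geometry.align_profile(prof, offset)
        cm1 = geometry.constriction_metrics(moved, ref_station=moved.x[0])
        assert cm1.ratio == pytest.approx(cm0.ratio, rel=1e-12)
        assert cm1.length == pytest.approx(cm0.length, rel=1e-9)


class TestAlignProfile:
    def test_round_trip_exact(self):
        prof = gaussian_profile(n=100)
        back = geometry.align_profile(geometry.align_profile(prof, 5.0), -5.0)
        assert np.array_equal(back.x, prof.x) and np.array_equal(back.A, prof.A)

    def test_landmark_coincidence(self):
        prof = gaussian_profile(x0=-85.0, n=200)
        other = geometry.align_profile(prof, 30.0)
        realigned = geometry.align_profile(other, -30.0)
        i = np.argmin(prof.A)
        assert realigned.x[np.argmin(realigned.A)] == pytest.approx(prof.x[i])


def test_profile_csv_round_trip(tmp_path):
    prof = gaussian_profile(n=50)
    path = tmp_path / "profile.csv"
    geometry.write_profile_csv(path, prof)
    back = geometry.read_profile_csv(path)
    assert np.allclose(back.x, prof.x) and np.allclose(back.A, prof.A)
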