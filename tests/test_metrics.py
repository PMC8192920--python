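"""Morphometric metrics, agreement statistics, and TAWSS."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stentrec.core import FrameField
from stentrec.errors import InsufficientInputError, InvalidInputError
from stentrec.metrics import (
    CrossSectionSeries,
    WSSHistory,
    bland_altman,
    cross_sections,
    ellipse_ratio,
    malapposition,
    mean_stent_diameter,
    slice_diameter,
    stent_length,
    tawss,
)
from stentrec.rollback import Wire3D


def _ellipse_ratio_bruteforce(pts):
    """Independent O(n^2) oracle: furthest pair, then max perpendicular pair."""
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    best, pair = -1.0, None
    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(*(pts[i] - pts[j]))
            if d > best:
                best, pair = d, (i, j)
    X = best
    axis = (pts[pair[1]] - pts[pair[0]]) / X
    perp = np.array([-axis[1], axis[0]])
    Y = -1.0
    for i in range(n):
        for j in range(i + 1, n):
            Y = max(Y, abs(np.dot(pts[i] - pts[j], perp)))
    return X / Y


class TestEllipseRatio:
    def test_circle_is_one(self):
        th = 2 * np.pi * np.arange(256) / 256
        pts = np.column_stack([np.cos(th), np.sin(th)])
        assert ellipse_ratio(pts) == pytest.approx(1.0, abs=1e-3)

    def test_ellipse_two_to_one(self):
        th = 2 * np.pi * np.arange(2000) / 2000
        pts = np.column_stack([2 * np.cos(th), np.sin(th)])
        assert ellipse_ratio(pts) == pytest.approx(2.0, abs=1e-3)
        assert ellipse_ratio(pts) == pytest.approx(_ellipse_ratio_bruteforce(pts[::10]),
                                                   abs=5e-3)

    def test_square_corners(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        assert ellipse_ratio(pts) == pytest.approx(_ellipse_ratio_bruteforce(pts))
        assert ellipse_ratio(pts) == pytest.approx(1.0)

    def test_matches_bruteforce_on_random_slices(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            pts = rng.normal(size=(40, 2)) * [2.0, 1.0]
            assert ellipse_ratio(pts) == pytest.approx(
                _ellipse_ratio_bruteforce(pts), abs=1e-12
            )

    def test_collinear_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5)])
        with pytest.raises(InvalidInputError):
            ellipse_ratio(pts)

    @settings(max_examples=30, deadline=None)
    @given(
        st.floats(0.1, 50.0),
        st.floats(0, 2 * np.pi),
        st.integers(0, 2**31 - 1),
    )
    def test_at_least_one_scale_rotation_invariant(self, scale, angle, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(12, 2))
        r0 = ellipse_ratio(pts)
        assert r0 >= 1.0 - 1e-12
        R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        assert ellipse_ratio(scale * pts @ R.T) == pytest.approx(r0, rel=1e-9)


class TestDiameters:
    def test_single_circular_slice(self):
        th = 2 * np.pi * np.arange(64) / 64
        pts = 2.0 * np.column_stack([np.cos(th), np.sin(th)])
        # 64-gon area-equivalent diameter of a 4.0 mm circle
        assert slice_diameter(pts) == pytest.approx(4.0, abs=0.01)
        assert slice_diameter(pts, "max_feret") == pytest.approx(4.0, abs=0.01)
        assert slice_diameter(pts, "min_feret") == pytest.approx(4.0, abs=0.02)

    def test_msd_of_linear_taper_is_mean(self):
        # diameters 2.5 -> 3.5 linearly: MSD = 3.0
        stations = np.linspace(0, 10, 101)
        slices = []
        th = 2 * np.pi * np.arange(64) / 64
        ring = np.column_stack([np.cos(th), np.sin(th)])
        for s in stations:
            slices.append((2.5 + s / 10) / 2 * ring)
        msd, st_, dia = mean_stent_diameter(
            CrossSectionSeries(stations=stations, slices=slices)
        )
        assert msd == pytest.approx(3.0, abs=0.02)

    def test_sparse_slices_skipped_with_warning(self):
        series = CrossSectionSeries(
            stations=np.array([0.0, 1.0]),
            slices=[np.zeros((2, 2)), 1.5 * np.column_stack(
                [np.cos(np.linspace(0, 2 * np.pi, 16)), np.sin(np.linspace(0, 2 * np.pi, 16))]
            )],
        )
        with pytest.warns(UserWarning, match="skipped"):
            msd, st_, dia = mean_stent_diameter(series)
        assert len(dia) == 1


class TestStentLengthAndSections:
    def test_phantom_length_matches_truth(self, clean_phantom):
        spec, truth, frames = clean_phantom
        L = stent_length(truth.wire3d, truth.field)
        # crown rounding trims ~0.1 mm from each end of the nominal 16 mm
        assert L == pytest.approx(16.0, abs=0.3)

    def test_curved_length_is_arc_not_chord(self):
        from stentrec.phantom import default_phantom_spec, deploy_stent

        spec = default_phantom_spec(seed=2, jitter_sd=0.0, shadow_width_deg=0.0,
                                    centerline_kind="arc", arc_radius=15.0)
        truth = deploy_stent(spec)
        L = stent_length(truth.wire3d, truth.field)
        assert L == pytest.approx(16.0, abs=0.3)  # arc length, not the chord

    def test_empty_wireframe_rejected(self, straight_centerline):
        field = FrameField(straight_centerline)
        with pytest.raises(InvalidInputError):
            stent_length(Wire3D(nx.Graph()), field)

    def test_cylindrical_phantom_msd(self, clean_phantom):
        spec, truth, frames = clean_phantom
        series = cross_sections(truth.wire3d, truth.field, 0.1)
        msd, st_, dia = mean_stent_diameter(series)
        # slices through full rings measure the 3.0 mm deployment diameter,
        # discretized as the polygon through ~16 leg crossings (inscribed
        # 16-gon area deficit ~ 2.5%)
        assert np.median(dia) == pytest.approx(3.0, abs=0.12)


class TestMalapposition:
    def test_concentric_offset_recovered(self, clean_phantom, straight_centerline):
        from stentrec.lumen import OCTFrame, package_contours, loft_surface
        from conftest import circle_contour

        field = FrameField(straight_centerline)
        frames = [
            OCTFrame(index=i, station=s, lumen_contour=circle_contour(r=1.5, n=200))
            for i, s in enumerate(np.linspace(0, 10, 21))
        ]
        lumen = loft_surface(package_contours(frames, field), 128)
        # strut ring at radius 1.0 inside lumen radius 1.5 -> gap 0.5 everywhere
        th = np.linspace(0, 2 * np.pi, 200)
        ring = np.column_stack([np.cos(th), np.sin(th), np.full_like(th, 5.0)])
        g = nx.Graph()
        g.add_node("a", pos=ring[0], role="valley", ring=0, provenance="observed")
        g.add_node("b", pos=ring[-1], role="valley", ring=0, provenance="observed")
        g.add_edge("a", "b", polyline=ring, apex_idx=[])
        per, mx, pts = malapposition(Wire3D(g), lumen, field)
        assert np.abs(per - 0.5).max() < 5e-3
        # strut lying on the wall: distance ~ 0
        wall = np.column_stack([1.5 * np.cos(th), 1.5 * np.sin(th), np.full_like(th, 5.0)])
        g2 = nx.Graph()
        g2.add_node("a", pos=wall[0], role="valley", ring=0, provenance="observed")
        g2.add_node("b", pos=wall[-1], role="valley", ring=0, provenance="observed")
        g2.add_edge("a", "b", polyline=wall, apex_idx=[])
        per2, mx2, _ = malapposition(Wire3D(g2), lumen, field)
        assert np.abs(per2).max() < 1e-3 + 2 * np.pi * 1.5 / 128


class TestBlandAltman:
    def test_identical_series(self):
        r = bland_altman([1, 2, 3.0], [1, 2, 3.0])
        assert (r.mean_difference, r.loa_low, r.loa_high) == (0, 0, 0)

    def test_constant_difference(self):
        r = bland_altman([1.1, 2.1, 3.1], [1, 2, 3.0])
        assert r.mean_difference == pytest.approx(0.1)
        assert r.loa_low == pytest.approx(0.1)
        assert r.loa_high == pytest.approx(0.1)

    def test_hand_computed_triple(self):
        # d = {-1, 0, 1}: mean 0, sample SD 1, limits -/+ 1.96
        r = bland_altman([0, 1, 2.0], [1, 1, 1.0])
        assert r.mean_difference == pytest.approx(0.0)
        assert r.sd == pytest.approx(1.0)
        assert r.loa_low == pytest.approx(-1.96)
        assert r.loa_high == pytest.approx(1.96)

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            bland_altman([1, 2.0], [1.0])

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=20),
           st.integers(0, 2**31 - 1))
    def test_antisymmetry(self, a, seed):
        rng = np.random.default_rng(seed)
        b = rng.normal(size=len(a))
        r1 = bland_altman(a, b)
        r2 = bland_altman(b, a)
        assert r1.mean_difference == pytest.approx(-r2.mean_difference, abs=1e-9)
        assert r1.loa_low == pytest.approx(-r2.loa_high, abs=1e-9)


class TestTAWSS:
    def test_constant_history(self):
        h = WSSHistory(times=np.linspace(0, 0.8, 50), tau_w=np.ones(50))
        assert tawss(h) == pytest.approx(1.0)

    def test_rectified_sine_two_over_pi(self):
        T = 0.8
        t = np.linspace(0, T, 4001)
        h = WSSHistory(times=t, tau_w=np.abs(np.sin(2 * np.pi * t / T)))
        assert tawss(h) == pytest.approx(2 / np.pi, abs=1e-3)

    def test_per_element_history(self):
        t = np.linspace(0, 1, 100)
        tau = np.column_stack([np.ones(100), 2 * np.ones(100)])
        np.testing.assert_allclose(tawss(WSSHistory(times=t, tau_w=tau)), [1.0, 2.0])

    def test_two_point_history_rejected(self):
        with pytest.raises(InvalidInputError):
            tawss(WSSHistory(times=np.array([0.0, 1.0]), tau_w=np.array([1.0, 1.0])))
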