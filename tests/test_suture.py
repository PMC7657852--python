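"""Suture-curve generation: Koch growth law, lobate morphology, wrapping,
offset safety limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from septamech.errors import GeometryError, ParameterError
from septamech.suture import (
    PlanarCurve,
    SutureSpec,
    count_local_minima,
    koch_curve,
    lobate_curve,
    max_safe_offset,
    polyline_self_intersects,
    wrap_on_cylinder,
)

R = 9.11  # reference cylinder radius, mm
AMP = 0.2 * R


class TestKochCurve:
    @pytest.mark.parametrize(
        "iterations,n_copies,expected",
        [(0, 1, 1), (1, 1, 4), (2, 1, 16), (3, 4, 4 * 4**3)],
    )
    def test_segment_growth_law(self, iterations, n_copies, expected):
        c = koch_curve(iterations, n_copies, amplitude=1.0, smooth=False)
        assert c.n_segments == expected

    def test_iteration_zero_is_flat_baseline(self):
        c = koch_curve(0, 1, amplitude=1.0)
        assert c.n_segments == 1
        assert np.allclose(c.y, 0.0)

    def test_amplitude_is_peak_to_peak(self):
        c = koch_curve(2, 4, amplitude=1.8)
        assert np.ptp(c.y) == pytest.approx(1.8, rel=1e-9)

    def test_negative_iterations_rejected(self):
        with pytest.raises(ParameterError):
            koch_curve(-1, 4, amplitude=1.0)

    def test_smoothed_curve_is_single_valued_through_three_iterations(self):
        # the default generator angle keeps x strictly increasing, so the
        # suture stays a height field over arc position (meshing requirement)
        for it in (1, 2, 3):
            c = koch_curve(it, 4, amplitude=AMP)
            assert np.all(np.diff(c.x) > 0)

    def test_classic_60_degree_generator_bump(self):
        c = koch_curve(1, 1, amplitude=0.0, smooth=False, angle=60.0)
        # apex of the classic generator sits sqrt(3)/6 above the baseline
        assert np.ptp(c.y) == pytest.approx(np.sqrt(3) / 6, rel=1e-9)


class TestLobateCurve:
    @pytest.mark.parametrize("n_lobes", [3, 4, 5, 6])
    def test_exact_lobe_count(self, n_lobes):
        c = lobate_curve(n_lobes, amplitude=2.0)
        assert count_local_minima(c) == n_lobes

    def test_bilateral_symmetry(self):
        c = lobate_curve(3, amplitude=2.0)
        y = c.y[:-1]
        mirrored = np.concatenate([y[:1], y[1:][::-1]])
        assert np.allclose(y, mirrored, atol=1e-9)

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(ParameterError):
            lobate_curve(4, amplitude=0.0)


class TestWrapOnCylinder:
    def test_flat_curve_wraps_to_circle(self):
        flat = PlanarCurve(np.linspace(0, 1, 65), np.zeros(65))
        s = wrap_on_cylinder(flat, R, axial_center=3.0)
        assert np.allclose(s.points[:, 2], 3.0)
        assert s.arc_length == pytest.approx(2 * np.pi * R, rel=1e-3)

    @pytest.mark.parametrize(
        "spec",
        [
            SutureSpec(family="lobate", n_lobes=6),
            SutureSpec(family="koch", iterations=2),
        ],
        ids=["sexilobate", "koch2"],
    )
    def test_wrapped_points_lie_on_cylinder(self, spec):
        s = wrap_on_cylinder(spec.make_planar(R), R)
        r = np.hypot(s.points[:, 0], s.points[:, 1])
        assert np.abs(r - R).max() < 1e-6
        assert np.allclose(s.points[0], s.points[-1])
        assert s.is_simple()

    def test_arc_length_exceeds_circumference_iff_folded(self):
        folded = wrap_on_cylinder(lobate_curve(6, AMP), R)
        assert folded.arc_length > 2 * np.pi * R

    def test_open_curve_rejected(self):
        open_curve = PlanarCurve(np.linspace(0, 1, 12), np.linspace(0, 1, 12),
                                 periodic=False)
        with pytest.raises(GeometryError):
            wrap_on_cylinder(open_curve, R)


class TestSelfIntersection:
    def test_figure_eight_detected(self):
        pts = np.array([[0, 0], [1, 1], [1, 0], [0, 1], [0, 0]], float)
        assert polyline_self_intersects(pts, closed=True)

    def test_square_is_simple(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)
        assert not polyline_self_intersects(pts, closed=True)

    @given(st.integers(min_value=3, max_value=6))
    @settings(max_examples=4, deadline=None, derandomize=True)
    def test_generated_sutures_are_simple(self, n_lobes):
        s = wrap_on_cylinder(lobate_curve(n_lobes, AMP), R)
        assert s.is_simple()


class TestMaxSafeOffset:
    def test_flat_circle_offset_at_least_radius(self):
        flat = PlanarCurve(np.linspace(0, 1, 65), np.zeros(65))
        s = wrap_on_cylinder(flat, R)
        assert max_safe_offset(s) >= R

    def test_koch_limit_below_lobate_limit(self):
        koch = wrap_on_cylinder(koch_curve(3, 4, AMP), R)
        lob = wrap_on_cylinder(lobate_curve(6, AMP), R)
        assert max_safe_offset(koch) < max_safe_offset(lob)

    def test_limit_brackets_the_transition(self):
        s = wrap_on_cylinder(koch_curve(1, 4, AMP), R)
        v = max_safe_offset(s)
        period = 2 * np.pi * s.cylinder_radius
        from septamech.suture import _offset_polyline, _periodic_self_intersects

        pts = s.unrolled()[:-1]
        simple_lo = not any(
            _periodic_self_intersects(_offset_polyline(pts, sgn * 0.97 * v, period), period)
            for sgn in (+1, -1)
        )
        simple_hi = not any(
            _periodic_self_intersects(_offset_polyline(pts, sgn * 1.03 * v, period), period)
            for sgn in (+1, -1)
        )
        assert simple_lo and not simple_hi

    def test_agrees_with_shapely_simplicity_oracle(self):
        # independent detector: shapely's is_simple on the raw offset
        # polyline must agree with the brute-force segment check on both
        # sides of the located limit
        pytest.importorskip("shapely")
        from shapely.geometry import LineString

        from septamech.suture import _offset_polyline

        s = wrap_on_cylinder(koch_curve(2, 4, AMP), R)
        v = max_safe_offset(s)
        period = 2 * np.pi * s.cylinder_radius
        pts = s.unrolled()[:-1]

        def shapely_simple(d):
            for sgn in (+1.0, -1.0):
                off = _offset_polyline(pts, sgn * d, period)
                closed = np.vstack([off, off[:1] + [period, 0.0]])
                if not LineString(closed).is_simple:
                    return False
            return True

        assert shapely_simple(0.95 * v)
        assert not shapely_simple(1.05 * v)
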