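"""Tracer advection, velocity interpolation and FTLE."""

import numpy as np
import pytest

from laflow.fields import StaggeredField
from laflow.geometry import CartesianGrid
from laflow.lagrangian import (PlaneSpec, TracerSet, VelocitySeries,
                               advect_tracers, backward_ftle,
                               interpolate_velocity)


def make_series(grid, field_fn, times):
    """Analytic velocity (mm/ms) sampled onto staggered snapshots."""
    states = []
    for t in times:
        st = StaggeredField.zeros(grid, t_ms=t)
        for ax, comp in enumerate((st.u, st.v, st.w)):
            pts = grid.face_centers(ax)
            comp[...] = field_fn(pts, t)[..., ax]
        states.append(st)
    return VelocitySeries(grid, times, states)


def box_grid(n=32, half=50.0):
    return CartesianGrid(n=(n, n, n), h=2 * half / n, origin=(-half,) * 3)


class TestInterpolation:
    def test_uniform_field(self):
        g = box_grid(16)
        series = make_series(g, lambda p, t: np.broadcast_to(
            [0.3, -0.1, 0.2], p.shape), [0.0, 100.0])
        v = interpolate_velocity(series, np.array([3.0, -7.0, 11.0]), 40.0)
        assert np.allclose(v, [0.3, -0.1, 0.2])

    def test_linear_field_exact(self):
        g = box_grid(16)
        series = make_series(
            g, lambda p, t: np.stack([0.01 * p[..., 0], np.zeros(p.shape[:-1]),
                                      np.zeros(p.shape[:-1])], axis=-1),
            [0.0, 100.0])
        for x in ([1.2, 3.4, -5.6], [-20.0, 13.0, 7.7]):
            v = interpolate_velocity(series, np.array(x), 50.0)
            assert v[0] == pytest.approx(0.01 * x[0], rel=1e-12, abs=1e-14)

    def test_quadratic_field_second_order(self, rng):
        def field(p, t):
            out = np.zeros(p.shape)
            out[..., 0] = 1e-4 * p[..., 0] ** 2 + 2e-4 * p[..., 1] * p[..., 2]
            return out

        errs = []
        pts = rng.uniform(-30, 30, (50, 3))
        for n in (16, 32):
            g = box_grid(n)
            series = make_series(g, field, [0.0, 10.0])
            v = series.velocity(pts, 5.0)
            exact = field(pts, 0.0)
            errs.append(np.abs(v - exact).max())
        assert errs[1] < errs[0] / 3.0

    def test_time_linear(self):
        g = box_grid(8)
        series = make_series(g, lambda p, t: np.broadcast_to(
            [t / 100.0, 0.0, 0.0], p.shape), [0.0, 100.0])
        v = interpolate_velocity(series, np.zeros(3), 25.0)
        assert v[0] == pytest.approx(0.25)

    def test_out_of_span_and_grid_rejected(self):
        g = box_grid(8)
        series = make_series(g, lambda p, t: np.zeros(p.shape), [0.0, 10.0])
        with pytest.raises(ValueError, match="span"):
            interpolate_velocity(series, np.zeros(3), 11.0)
        with pytest.raises(ValueError, match="grid"):
            interpolate_velocity(series, np.array([999.0, 0.0, 0.0]), 5.0)


class TestAdvection:
    def test_uniform_field_exact_displacement(self):
        g = box_grid(8)
        series = make_series(g, lambda p, t: np.broadcast_to(
            [0.1, 0.05, -0.02], p.shape), [0.0, 200.0])
        tr = TracerSet(np.zeros((1, 3)), labels=None)
        advect_tracers(tr, series, 0.0, 100.0, 1.0)
        assert np.allclose(tr.positions[0], [10.0, 5.0, -2.0], atol=1e-10)

    def test_solid_body_rotation_closed_orbit(self):
        omega = 2 * np.pi / 500.0  # one revolution per 500 ms

        def field(p, t):
            out = np.zeros(p.shape)
            out[..., 0] = -omega * p[..., 1]
            out[..., 1] = omega * p[..., 0]
            return out

        g = box_grid(24)
        series = make_series(g, field, [0.0, 500.0])
        r = 20.0
        tr = TracerSet(np.array([[r, 0.0, 0.0]]), labels=None)
        advect_tracers(tr, series, 0.0, 500.0, 0.5)  # 1000 steps
        assert np.linalg.norm(tr.positions[0] - [r, 0.0, 0.0]) < 1e-6 * r

    def test_saddle_flow_exponential(self):
        lam = 1e-3  # 1/ms

        def field(p, t):
            out = np.zeros(p.shape)
            out[..., 0] = lam * p[..., 0]
            out[..., 1] = -lam * p[..., 1]
            return out

        g = box_grid(24)
        series = make_series(g, field, [0.0, 200.0])
        x0 = 5.0
        tr = TracerSet(np.array([[x0, x0, 0.0]]), labels=None)
        advect_tracers(tr, series, 0.0, 200.0, 0.2)
        assert tr.positions[0, 0] == pytest.approx(x0 * np.exp(lam * 200),
                                                   rel=1e-8)
        assert tr.positions[0, 1] == pytest.approx(x0 * np.exp(-lam * 200),
                                                   rel=1e-8)

    def test_wall_termination(self):
        g = box_grid(8)
        series = make_series(g, lambda p, t: np.broadcast_to(
            [0.1, 0.0, 0.0], p.shape), [0.0, 500.0])
        series.sdf_fn = lambda pts, t: pts[:, 0] - 20.0  # wall at x = 20
        tr = TracerSet(np.array([[0.0, 0.0, 0.0]]), labels=None)
        advect_tracers(tr, series, 0.0, 400.0, 1.0)
        assert tr.status[0] == 1  # frozen at the wall
        assert tr.positions[0, 0] <= 20.0 + 0.2

    def test_zero_velocity_tracers_stay(self):
        g = box_grid(8)
        series = make_series(g, lambda p, t: np.zeros(p.shape), [0.0, 100.0])
        seeds = np.array([[1.0, 2.0, 3.0], [-4.0, 0.0, 9.0]])
        tr = TracerSet(seeds.copy(), labels=None)
        advect_tracers(tr, series, 0.0, 100.0, 1.0)
        assert np.allclose(tr.positions, seeds)


class TestBackwardFTLE:
    def steady_series(self, field, n=32, half=50.0, t0=-100.0, t1=10.0):
        g = box_grid(n, half)
        return make_series(g, field, [t0, t1])

    def test_uniform_translation_zero(self):
        series = self.steady_series(lambda p, t: np.broadcast_to(
            [0.05, -0.02, 0.0], p.shape))
        fld = backward_ftle(series, PlaneSpec((0, 0, 0), (0, 0, 1)), 0.0,
                            tau_ms=-50.0, delta_mm=2.0, half_extent_mm=20.0)
        vals = fld.values[np.isfinite(fld.values)]
        assert np.abs(vals).max() < 1e-10

    def test_linear_saddle_exponent(self):
        lam_s = 1.0  # 1/s
        lam = lam_s * 1e-3  # 1/ms

        def field(p, t):
            out = np.zeros(p.shape)
            out[..., 0] = lam * p[..., 0]
            out[..., 1] = -lam * p[..., 1]
            return out

        series = self.steady_series(field)
        fld = backward_ftle(series, PlaneSpec((0, 0, 0), (0, 0, 1)), 0.0,
                            tau_ms=-50.0, delta_mm=1.0, half_extent_mm=10.0)
        vals = fld.values[np.isfinite(fld.values)]
        # backward map of the saddle stretches along y: sigma = e^{lam |tau|}
        assert np.median(vals) == pytest.approx(lam_s, rel=0.01)

    def test_galilean_invariance(self):
        lam = 1e-3

        def saddle(p, t):
            out = np.zeros(p.shape)
            out[..., 0] = lam * p[..., 0]
            out[..., 1] = -lam * p[..., 1]
            return out

        def boosted(p, t):
            out = saddle(p, t)
            out[..., 0] += 0.03
            return out

        plane = PlaneSpec((0, 0, 0), (0, 0, 1))
        f1 = backward_ftle(self.steady_series(saddle), plane, 0.0, -50.0,
                           delta_mm=2.0, half_extent_mm=10.0)
        f2 = backward_ftle(self.steady_series(boosted), plane, 0.0, -50.0,
                           delta_mm=2.0, half_extent_mm=10.0)
        both = np.isfinite(f1.values) & np.isfinite(f2.values)
        assert np.abs(f1.values[both] - f2.values[both]).max() < 1e-8

    def test_backward_equals_forward_of_reversed_flow(self):
        lam = 1e-3

        def saddle(p, t):
            out = np.zeros(p.shape)
            out[..., 0] = lam * p[..., 0]
            out[..., 1] = -lam * p[..., 1]
            return out

        def reversed_saddle(p, t):
            return -saddle(p, t)

        plane = PlaneSpec((0, 0, 0), (0, 0, 1))
        fb = backward_ftle(self.steady_series(saddle), plane, 0.0, -50.0,
                           delta_mm=2.0, half_extent_mm=10.0)
        ff = backward_ftle(self.steady_series(reversed_saddle), plane, -50.0,
                           +50.0, delta_mm=2.0, half_extent_mm=10.0)
        both = np.isfinite(fb.values) & np.isfinite(ff.values)
        assert np.abs(fb.values[both] - ff.values[both]).max() < 1e-10

    def test_zero_tau_rejected(self):
        series = self.steady_series(lambda p, t: np.zeros(p.shape))
        with pytest.raises(ValueError):
            backward_ftle(series, PlaneSpec((0, 0, 0), (0, 0, 1)), 0.0, 0.0)
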