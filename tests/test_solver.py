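"""Flow-solver operations: resistances, valve state, operators, stepping."""

import numpy as np
import pytest

from laflow import fourier
from laflow.config import (AnatomyConfig, FluidProperties, SolverConfig,
                           subject_config)
from laflow.fields import StaggeredField, divergence
from laflow.geometry import CartesianGrid
from laflow.solver import (FlowSolver, compute_pv_resistances, mv_state,
                           port_flux)

SUBJECT1_AREAS = (211.0, 97.2, 194.0, 212.0)


class TestPvResistances:
    def test_inverse_area_ratios(self):
        K = compute_pv_resistances(SUBJECT1_AREAS, kappa=1.0)
        assert np.allclose(K, [1 / a for a in SUBJECT1_AREAS])
        # LIPV (smallest vein) carries the largest resistance
        assert np.argmax(K) == 1

    def test_equal_areas_equal_K(self):
        assert np.ptp(compute_pv_resistances([150.0] * 4, kappa=5.0)) == 0.0

    def test_K_times_area_invariant(self):
        for kappa in (0.3, 5.0, 50.0):
            K = compute_pv_resistances(SUBJECT1_AREAS, kappa)
            prods = K * np.asarray(SUBJECT1_AREAS)
            assert np.allclose(prods, prods[0])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_pv_resistances([100.0, -1.0], 1.0)
        with pytest.raises(ValueError):
            compute_pv_resistances([100.0], 0.0)


class TestMvState:
    def test_constant_volume_closed(self):
        phase, q = mv_state([100.0], 123.0, 870.0)
        assert phase == "closed" and q == 0.0

    def test_sinusoidal_volume(self):
        # V = V0 + A sin(2 pi t / T): filling (open) on the rising half
        T = 1000.0
        coeffs = [100.0, 0.0, 20.0]  # b1 = 20 in phase-fraction units
        phase, q = mv_state(coeffs, 100.0, T)
        assert phase == "open" and q > 0
        phase, _ = mv_state(coeffs, 600.0, T, previous="open")
        assert phase == "closed"

    def test_volume_rate_integrates_to_zero_over_cycle(self):
        # periodic LV volume: its rate integrates to zero over one period,
        # so the gated valve throughput equals the total filling volume
        cfg = subject_config(2)
        t = np.linspace(0.0, cfg.period_ms, 4001)
        rate = cfg.lv_volume_rate(t)
        net = np.trapezoid(rate, t)
        assert abs(net) < 1e-9 * np.abs(rate).max() * cfg.period_ms
        throughput = np.trapezoid(np.maximum(rate, 0.0), t)
        gated = np.array([mv_state(cfg.lv_volume_coeffs, ti, cfg.period_ms)[1]
                          for ti in t])
        assert np.trapezoid(gated, t) == pytest.approx(throughput, rel=2e-3)

    def test_hysteresis_suppresses_chatter(self):
        T = 1000.0
        coeffs = [100.0, 0.0, 20.0]
        # dV/dt = (40 pi / T) cos(2 pi t / T) crosses zero at t = T/4; just
        # after the crossing the lagged check keeps the valve open briefly
        phase, _ = mv_state(coeffs, 250.05, T, hysteresis_ms=1.0, previous="open")
        assert phase == "open"


class TestDivergenceOperator:
    def grid(self, n=12, h=0.5):
        return CartesianGrid(n=(n, n, n), h=h)

    def test_uniform_field_zero(self):
        g = self.grid()
        st = StaggeredField.zeros(g)
        st.u += 3.0
        st.v -= 1.0
        assert np.abs(divergence(st, g)).max() == 0.0

    def test_linear_solenoidal_exact(self):
        g = self.grid()
        st = StaggeredField.zeros(g)
        xf = g.axis_faces(0) * 1e-3
        yc = g.axis_centers(1) * 1e-3
        st.u = np.broadcast_to(xf[:, None, None], st.u.shape).copy()
        st.v = -np.broadcast_to(g.axis_faces(1)[None, :, None] * 1e-3,
                                st.v.shape).copy()
        div = divergence(st, g)
        assert np.abs(div).max() < 1e-10 * (np.abs(xf).max() / (g.h * 1e-3))

    def test_quadratic_field_second_order(self):
        # v = (x^2, 0, 0): discrete divergence -> 2x (exact at cell centers
        # for the staggered central difference)
        g = self.grid(16, 1.0)
        st = StaggeredField.zeros(g)
        xf = g.axis_faces(0) * 1e-3
        st.u = np.broadcast_to((xf ** 2)[:, None, None], st.u.shape).copy()
        div = divergence(st, g)
        xc = g.axis_centers(0) * 1e-3
        expected = np.broadcast_to(2 * xc[:, None, None], g.n)
        assert np.abs(div - expected).max() < 1e-9 * np.abs(expected).max()


class TestPortFlux:
    def grid(self):
        return CartesianGrid(n=(24, 24, 24), h=1.0, origin=(-12.0, -12.0, -12.0))

    def test_uniform_normal_velocity(self):
        g = self.grid()
        st = StaggeredField.zeros(g)
        st.w += 0.25  # mm/ms
        area = np.pi * 6.0 ** 2
        q = port_flux(st, g, (0, 0, 0), (0, 0, 1), area)
        assert q == pytest.approx(0.25 * area * 1e3, rel=0.01)

    def test_zero_field(self):
        g = self.grid()
        st = StaggeredField.zeros(g)
        assert port_flux(st, g, (0, 0, 0), (0, 0, 1), 100.0) == 0.0

    def test_in_plane_rotation_cancels(self):
        # solid-body rotation about the plane normal: no through-plane flux
        g = self.grid()
        st = StaggeredField.zeros(g)
        yc = g.axis_centers(1)
        xc = g.axis_centers(0)
        st.u = np.broadcast_to(-yc[None, :, None], st.u.shape).copy() * 0.01
        st.v = np.broadcast_to(xc[:, None, None], st.v.shape).copy() * 0.01
        q = port_flux(st, g, (0, 0, 0), (0, 0, 1), np.pi * 36.0)
        assert abs(q) < 1e-10 * np.pi * 36.0 * 1e3


class TestStepping:
    def test_rest_state_is_a_solution(self):
        # static box, no domain, no forcing: the state stays identically zero
        g = CartesianGrid(n=(12, 12, 12), h=1.0)
        s = FlowSolver(g, FluidProperties(), SolverConfig(grid_n=12))
        for _ in range(5):
            s.step(1e-3)
        assert s.state.max_speed() == 0.0

    def test_rest_state_static_anatomy(self):
        # static chamber, MV closed, PV baseline pressures zero: remains rest
        from laflow.anatomy import build_idealized_la
        from laflow.geometry import AnalyticImmersion
        from laflow.solver import _LAPorts
        base = subject_config(1)
        cfg = AnatomyConfig(pv_specs=base.pv_specs, mv_spec=base.mv_spec,
                            period_ms=base.period_ms,
                            la_volume_coeffs=(base.la_volume(0.0),),
                            lv_volume_coeffs=(100.0,))
        surf = build_idealized_la(cfg)
        scfg = SolverConfig(grid_n=24, n_cycles=1)
        grid = CartesianGrid.from_bounds(surf.geometry.bounds(6.0), 24)
        imm = AnalyticImmersion(surf.geometry, grid, 2 * grid.h)
        ports = _LAPorts(imm, cfg, scfg, FluidProperties())
        s = FlowSolver(grid, FluidProperties(), scfg,
                       domain_provider=ports.domain_provider,
                       pressure_bc=ports.pressure_bc,
                       wall_calibration=ports.calibrate)
        for _ in range(5):
            s.step(5e-4)
            ports.measure(s.state, grid, s)
        assert s.state.max_speed() < 1e-12

    def test_divergence_clean_after_projection(self):
        # an arbitrary initial field is projected to the discrete div-free
        # space within the solver tolerance
        g = CartesianGrid(n=(16, 16, 16), h=1.0)
        s = FlowSolver(g, FluidProperties(), SolverConfig(grid_n=16),
                       periodic=(True, True, True))
        rng = np.random.default_rng(3)
        s.state.u[:] = 0.01 * rng.standard_normal(s.state.u.shape)
        s.state.v[:] = 0.01 * rng.standard_normal(s.state.v.shape)
        s.state.w[:] = 0.01 * rng.standard_normal(s.state.w.shape)
        s._sync_periodic()
        s.step(1e-4)
        assert s.max_div_ratio <= 1e-6
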