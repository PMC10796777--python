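"""Kinetic energy and viscous dissipation integrals."""

import numpy as np
import pytest

from laflow.config import FluidProperties
from laflow.energetics import dissipation_rate, kinetic_energy
from laflow.fields import StaggeredField
from laflow.geometry import CartesianGrid


def box(n=20, h=2.0):
    return CartesianGrid(n=(n, n, n), h=h)


def mask_of_volume(grid, volume_mm3):
    """Boolean mask selecting exactly volume/h^3 cells (corner block)."""
    n_cells = int(round(volume_mm3 / grid.cell_volume_mm3))
    m = np.zeros(grid.n, dtype=bool)
    m.reshape(-1)[:n_cells] = True
    assert m.sum() * grid.cell_volume_mm3 == pytest.approx(volume_mm3)
    return m


class TestKineticEnergy:
    def test_uniform_speed_closed_form(self):
        # 100 mm/s over 100 mL: 0.5 * 1050 * 0.1^2 * 1e-4 m^3 = 0.525 mJ
        g = box(25, 2.0)  # cell 8 mm^3; 12500 cells make up 1e5 mm^3
        st = StaggeredField.zeros(g)
        st.u += 0.1  # 100 mm/s in m/s
        mask = mask_of_volume(g, 1e5)
        ke = kinetic_energy(st, g, FluidProperties(), fluid_mask=mask)
        assert ke == pytest.approx(0.525, rel=1e-6)

    def test_zero_field(self):
        g = box()
        ke = kinetic_energy(StaggeredField.zeros(g), g, FluidProperties())
        assert ke == 0.0

    def test_brute_force_cell_sum(self, rng):
        g = box(10, 1.5)
        st = StaggeredField.zeros(g)
        st.u[:] = rng.standard_normal(st.u.shape) * 0.1
        st.v[:] = rng.standard_normal(st.v.shape) * 0.1
        st.w[:] = rng.standard_normal(st.w.shape) * 0.1
        props = FluidProperties()
        ke = kinetic_energy(st, g, props)
        # independent summation: explicit python loop over cells
        total = 0.0
        for i in range(10):
            for j in range(10):
                for k in range(10):
                    vx = 0.5 * (st.u[i, j, k] + st.u[i + 1, j, k])
                    vy = 0.5 * (st.v[i, j, k] + st.v[i, j + 1, k])
                    vz = 0.5 * (st.w[i, j, k] + st.w[i, j, k + 1])
                    total += 0.5 * props.density * (vx ** 2 + vy ** 2 + vz ** 2)
        total *= (g.h * 1e-3) ** 3 * 1e3
        assert ke == pytest.approx(total, rel=1e-12)

    def test_linear_in_density(self):
        g = box(8)
        st = StaggeredField.zeros(g)
        st.v += 0.2
        k1 = kinetic_energy(st, g, FluidProperties(density=1000.0))
        k2 = kinetic_energy(st, g, FluidProperties(density=2000.0))
        assert k2 == pytest.approx(2 * k1, rel=1e-12)


class TestDissipationRate:
    def test_uniform_flow_zero(self):
        g = box()
        st = StaggeredField.zeros(g)
        st.u += 0.5
        assert dissipation_rate(st, g, FluidProperties()) == pytest.approx(0.0,
                                                                           abs=1e-15)

    def test_simple_shear_closed_form(self):
        # v = (gamma y, 0, 0), gamma = 100 1/s over 1e5 mm^3:
        # 2 eta S:S = eta gamma^2 = 35 W/m^3 -> 3.5 mJ/s
        g = box(25, 2.0)
        st = StaggeredField.zeros(g)
        gamma = 100.0
        yc = g.axis_centers(1) * 1e-3
        st.u[:] = np.broadcast_to(gamma * yc[None, :, None], st.u.shape)
        mask = mask_of_volume(g, 1e5)
        d = dissipation_rate(st, g, FluidProperties(), fluid_mask=mask)
        assert d == pytest.approx(3.5, rel=1e-6)

    def test_linear_in_viscosity(self):
        g = box(10)
        st = StaggeredField.zeros(g)
        yc = g.axis_centers(1) * 1e-3
        st.u[:] = np.broadcast_to(50.0 * yc[None, :, None], st.u.shape)
        d1 = dissipation_rate(st, g, FluidProperties(viscosity=3.5e-3))
        d2 = dissipation_rate(st, g, FluidProperties(viscosity=7.0e-3))
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_band_weighting_suppresses_wall_shear(self):
        # a velocity jump at a diffuse wall: weighting by fluid fraction
        # must reduce the band's contribution
        g = box(16, 1.0)
        st = StaggeredField.zeros(g)
        st.u[:, 8:, :] = 0.3
        sdf = np.zeros(g.n)
        sdf[:, 8:, :] = 2.0   # solid above the jump
        sdf[:, :8, :] = -2.0
        d_masked = dissipation_rate(st, g, FluidProperties(), sdf=sdf,
                                    epsilon_mm=2.0)
        d_raw = dissipation_rate(st, g, FluidProperties())
        assert d_masked < 0.6 * d_raw
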