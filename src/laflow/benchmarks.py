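"""Canonical verification problems with closed-form references.

Shared between the test suite and the reproduction script:

- decaying 2D Taylor-Green vortex (periodic box): exact Navier-Stokes
  solution; checks the advection/diffusion/projection core and the
  kinetic-energy/dissipation budget;
- plane Poiseuille flow between immersed (BDIM) plates: checks the diffuse
  no-slip wall against the parabolic profile;
- the periodically perturbed double gyre: a standard FTLE benchmark field.
"""

from __future__ import annotations

import numpy as np

from .config import FluidProperties, SolverConfig
from .energetics import dissipation_rate, kinetic_energy
from .fields import StaggeredField
from .geometry import CartesianGrid, ImmersedDomain, bdim_weights
from .lagrangian import VelocitySeries
from .solver import FlowSolver

__all__ = [
    "taylor_green_benchmark",
    "poiseuille_benchmark",
    "double_gyre_series",
]


def taylor_green_benchmark(n: int = 64, cfl: float = 0.1, u0: float = 0.01,
                           box_mm: float = 2 * np.pi * 10.0,
                           props: FluidProperties | None = None,
                           n_efolds: float = 1.0) -> dict:
    """Run the 2D Taylor-Green vortex for ``n_efolds`` viscous e-folds.

    Returns the relative error of the decayed velocity amplitude against
    ``exp(-2 nu k^2 t)``, the relative closure error of the energy budget
    (time-integrated dissipation vs. kinetic-energy drop), and solver
    diagnostics.
    """
    props = props or FluidProperties()
    grid = CartesianGrid(n=(n, n, 1), h=box_mm / n, origin=(0.0, 0.0, 0.0))
    nu = props.nu
    k = 2 * np.pi / (box_mm * 1e-3)  # 1/m
    cfg = SolverConfig(grid_n=n, cfl=cfl, n_cycles=1)
    solver = FlowSolver(grid, props, cfg, periodic=(True, True, True))
    xf = grid.axis_faces(0)[: n + 1] * 1e-3
    xc = grid.axis_centers(0) * 1e-3
    yf = grid.axis_faces(1)[: n + 1] * 1e-3
    yc = grid.axis_centers(1) * 1e-3
    X, Y = np.meshgrid(xf, yc, indexing="ij")
    solver.state.u[:, :, 0] = u0 * np.cos(k * X) * np.sin(k * Y)
    X2, Y2 = np.meshgrid(xc, yf, indexing="ij")
    solver.state.v[:, :, 0] = -u0 * np.sin(k * X2) * np.cos(k * Y2)
    solver._sync_periodic()

    t_end = n_efolds / (2 * nu * k * k)
    ke = [kinetic_energy(solver.state, grid, props)]
    diss = [dissipation_rate(solver.state, grid, props)]
    times = [0.0]
    t = 0.0
    while t < t_end - 1e-12:
        dt = min(solver.stable_dt(), t_end - t)
        solver.step(dt)
        t += dt
        ke.append(kinetic_energy(solver.state, grid, props))
        diss.append(dissipation_rate(solver.state, grid, props))
        times.append(t)
    amp = float(np.abs(solver.state.u).max())
    expected = u0 * np.exp(-2 * nu * k * k * t_end)
    dissipated = float(np.trapezoid(diss, times))
    budget_err = abs(dissipated - (ke[0] - ke[-1])) / (ke[0] - ke[-1])
    return dict(
        amplitude_rel_err=abs(amp - expected) / expected,
        energy_budget_rel_err=budget_err,
        max_div_ratio=solver.max_div_ratio,
        max_cfl=solver.max_cfl,
        steps=solver.step_count,
        n=n,
    )


def poiseuille_benchmark(n_gap: int = 16, u_center: float = 0.01,
                         props: FluidProperties | None = None,
                         settle_factor: float = 5.0) -> dict:
    """Pressure-driven channel between BDIM plates, ``n_gap`` cells across.

    The flow is driven by a body force G with analytic centerline speed
    ``G H^2 / (8 eta)``; the run marches to steady state and reports the
    relative L2 profile error over the fluid cells.
    """
    props = props or FluidProperties()
    h = 1.0  # mm
    ny = n_gap + 8
    grid = CartesianGrid(n=(4, ny, 1), h=h, origin=(0.0, 0.0, 0.0))
    H = n_gap * h * 1e-3  # m
    yc_mm = grid.axis_centers(1)
    y_mid = 0.5 * ny * h
    sdf = np.broadcast_to(
        (np.abs(yc_mm - y_mid) - 0.5 * n_gap * h)[None, :, None], grid.n
    ).copy()
    eps = 2.0 * h
    mu = bdim_weights(sdf, eps)
    wall = tuple(np.zeros_like(m) for m in mu)
    domain = ImmersedDomain(grid=grid, t_ms=0.0, sdf=sdf, mu=mu,
                            wall_velocity=wall, epsilon_mm=eps)

    G = 8.0 * props.viscosity * u_center / H ** 2  # Pa/m
    cfg = SolverConfig(grid_n=16, cfl=0.1, n_cycles=1)
    solver = FlowSolver(grid, props, cfg, periodic=(True, False, True),
                        domain_provider=lambda t: domain,
                        body_accel=(G / props.density, 0.0, 0.0))
    t_end = settle_factor * H ** 2 / (np.pi ** 2 * props.nu)
    t = 0.0
    while t < t_end:
        dt = min(solver.stable_dt(extra_speed=u_center), t_end - t)
        solver.step(dt)
        t += dt

    u_profile = solver.state.u[0, :, 0]  # x-independent
    y_m = yc_mm * 1e-3
    yc0 = y_mid * 1e-3
    exact = u_center * (1.0 - (2.0 * (y_m - yc0) / H) ** 2)
    fluid = sdf[0, :, 0] < 0
    err = np.linalg.norm(u_profile[fluid] - exact[fluid])
    ref = np.linalg.norm(exact[fluid])
    return dict(
        l2_rel_err=float(err / ref),
        max_div_ratio=solver.max_div_ratio,
        steps=solver.step_count,
        n_gap=n_gap,
    )


def _double_gyre_velocity(pts, t, A=0.1, eps=0.25, omega=2 * np.pi / 10.0):
    x = pts[..., 0]
    y = pts[..., 1]
    a = eps * np.sin(omega * t)
    b = 1.0 - 2.0 * eps * np.sin(omega * t)
    f = a * x ** 2 + b * x
    dfdx = 2.0 * a * x + b
    out = np.zeros(pts.shape)
    out[..., 0] = -np.pi * A * np.sin(np.pi * f) * np.cos(np.pi * y)
    out[..., 1] = np.pi * A * np.cos(np.pi * f) * np.sin(np.pi * y) * dfdx
    return out


def double_gyre_series(n: int = 64, t0: float = 0.0, t1: float = 5.0,
                       dt_snap: float = 0.25) -> VelocitySeries:
    """Snapshots of the double-gyre field on [0,2]x[0,1] (length units are
    nominal mm, times nominal ms)."""
    grid = CartesianGrid(n=(n, n // 2, 1), h=2.0 / n, origin=(0.0, 0.0, 0.0))
    times = np.arange(t0, t1 + 1e-9, dt_snap)
    states = []
    for t in times:
        st = StaggeredField.zeros(grid, t_ms=t)
        for ax, comp in enumerate((st.u, st.v, st.w)):
            comp[...] = _double_gyre_velocity(grid.face_centers(ax), t)[..., ax]
        states.append(st)
    return VelocitySeries(grid, times, states)
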