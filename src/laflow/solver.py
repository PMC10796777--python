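"""Incompressible Navier-Stokes solver on a staggered Cartesian grid.

Fractional-step (Chorin projection) scheme with boundary data immersion
(BDIM) walls:

1. provisional velocity: explicit Adams-Bashforth-2 convection (QUICK
   fluxes) + explicit Euler diffusion (+ optional body force);
2. BDIM blend ``u* <- mu u* + (1 - mu) u_wall`` toward the prescribed
   moving-wall velocity;
3. variable-coefficient pressure Poisson equation
   ``div(mu grad p) = (rho/dt) div u*`` with Dirichlet pressures on the
   pulmonary-vein port layers and homogeneous Neumann elsewhere, solved by
   Jacobi-preconditioned conjugate gradients;
4. projection ``u <- u - (dt/rho) mu grad p``.

The pulmonary veins carry resistance-type pressure boundaries
``P_PV = P0 + K_i Q_PV`` with ``K_i`` inversely proportional to the vein
cross-sectional area (the terminal resistance model); the mitral valve is a
wall while the ventricle ejects and a uniform-velocity outlet while it
fills, with the flow rate prescribed by the ventricular volume curve.

Internal units are SI (m, s, Pa); the geometry API is mm/ms, and mm/ms
equals m/s numerically, so velocities pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kernels
from .anatomy import MovingSurface
from .config import (AnatomyConfig, FluidProperties, SolverConfig, PV_LABELS,
                     MV_LABEL)
from .fields import StaggeredField, interpolate_staggered
from .geometry import AnalyticImmersion, CartesianGrid, ImmersedDomain

__all__ = [
    "PortModel",
    "compute_pv_resistances",
    "mv_state",
    "port_flux",
    "FlowSolver",
    "run_simulation",
    "SimulationResult",
    "SolverError",
]

MM3_TO_M3 = 1e-9
PA_S_PER_MM3_TO_SI = 1e9  # Pa s / mm^3 -> Pa s / m^3


def compute_pv_resistances(areas_mm2, kappa: float):
    """Terminal resistances ``K_i = kappa / A_i`` (Pa s / mm^3).

    ``kappa`` (Pa s / mm) fixes the magnitude; only the ratios — inverse
    area ratios, i.e. equal design inflow velocity across the veins — are
    physically constrained.
    """
    areas = np.asarray(areas_mm2, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("PV areas must be positive")
    if kappa <= 0:
        raise ValueError("resistance scale must be positive")
    return kappa / areas


def mv_state(lv_volume_coeffs, t_ms: float, period_ms: float,
             hysteresis_ms: float = 1.0, previous: str | None = None):
    """Mitral valve phase from the ventricular volume curve.

    Open iff dV_LV/dt > 0 (the ventricle fills through the valve); a small
    hysteresis window avoids chattering at the zero crossings. Returns
    ``(phase, q_ml_per_ms)`` with phase in {"open", "closed"} and the valve
    flow rate (0 when closed).
    """
    from . import fourier

    coeffs = np.asarray(lv_volume_coeffs, dtype=float)
    dcoeffs = fourier.derivative(coeffs, 1.0) / period_ms
    q_now = float(fourier.evaluate(dcoeffs, t_ms / period_ms, 1.0))
    q_lag = float(fourier.evaluate(dcoeffs, (t_ms - hysteresis_ms) / period_ms, 1.0))
    if previous is None:
        phase = "open" if q_now > 0 else "closed"
    elif previous == "closed":
        phase = "open" if (q_now > 0 and q_lag > 0) else "closed"
    else:
        phase = "closed" if (q_now < 0 and q_lag < 0) else "open"
    return phase, (q_now if phase == "open" else 0.0)


class SolverError(RuntimeError):
    pass


def port_flux(state: "StaggeredField", grid: "CartesianGrid", center_mm,
              normal, area_mm2: float, n_r: int = 6, n_t: int = 16) -> float:
    """Flux (mm^3/s) of the interpolated velocity through a port disk.

    Midpoint quadrature on equal-angle annular sectors; positive along
    ``normal``.
    """
    from .anatomy import _orthonormal_basis

    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    e1, e2 = _orthonormal_basis(normal)
    radius = float(np.sqrt(area_mm2 / np.pi))
    rr = (np.arange(n_r) + 0.5) / n_r
    tt = 2 * np.pi * np.arange(n_t) / n_t
    R, T = np.meshgrid(rr, tt, indexing="ij")
    pts = (np.asarray(center_mm, dtype=float)[None, :]
           + (radius * R * np.cos(T)).reshape(-1, 1) * e1[None, :]
           + (radius * R * np.sin(T)).reshape(-1, 1) * e2[None, :])
    ring_w = (2.0 * np.arange(n_r) + 1.0) / n_r ** 2
    w = np.repeat(ring_w / n_t, n_t)
    vel = interpolate_staggered(state, grid, pts)  # m/s == mm/ms
    vn = vel @ normal
    return float((vn * w).sum() * area_mm2 * 1e3)  # mm^3/ms -> mm^3/s


class _MGPreconditioner:
    """Geometric multigrid V-cycle for the masked variable-coefficient
    Poisson operator, used as a preconditioner inside CG.

    Cell-centered coarsening: face coefficients are averaged over the fine
    faces they straddle, the unknown mask is block-ORed, restriction is the
    block mean and prolongation piecewise-constant injection (a symmetric
    pair up to a scalar, so CG stays well-defined with symmetric damped-
    Jacobi smoothing). Axes of odd or tiny extent are simply not coarsened,
    which also covers quasi-2D grids.
    """

    COARSE_SWEEPS = 6  # forward/backward pairs at the coarsest level

    def __init__(self, periodic):
        self.periodic = tuple(periodic)
        self.levels = []

    @staticmethod
    def _factors(shape):
        return tuple(2 if (n % 2 == 0 and n >= 6) else 1 for n in shape)

    @staticmethod
    def _block_reduce(a, factors, op="mean"):
        for ax, f in enumerate(factors):
            if f == 2:
                sl_even = [slice(None)] * a.ndim
                sl_odd = [slice(None)] * a.ndim
                sl_even[ax] = slice(0, None, 2)
                sl_odd[ax] = slice(1, None, 2)
                if op == "mean":
                    a = 0.5 * (a[tuple(sl_even)] + a[tuple(sl_odd)])
                else:
                    a = a[tuple(sl_even)] | a[tuple(sl_odd)]
        return a

    def _coarsen_faces(self, b, axis, factors):
        # normal direction: take every other face; transverse: average pairs
        if factors[axis] == 2:
            sl = [slice(None)] * 3
            sl[axis] = slice(0, None, 2)
            b = b[tuple(sl)]
        tf = list(factors)
        tf[axis] = 1
        return self._block_reduce(b, tf, op="mean")

    def setup(self, bx, by, bz, unknown, inv_h2):
        self.levels = []
        while True:
            self.levels.append(dict(bx=np.ascontiguousarray(bx),
                                    by=np.ascontiguousarray(by),
                                    bz=np.ascontiguousarray(bz),
                                    unknown=np.ascontiguousarray(unknown),
                                    inv_h2=inv_h2, shape=unknown.shape))
            factors = self._factors(unknown.shape)
            if all(f == 1 for f in factors) or len(self.levels) > 8:
                break
            bx = self._coarsen_faces(bx, 0, factors)
            by = self._coarsen_faces(by, 1, factors)
            bz = self._coarsen_faces(bz, 2, factors)
            unknown = self._block_reduce(unknown, factors, op="or")
            # halving h quarters 1/h^2 (only along coarsened axes; for mixed
            # factors this is approximate, which a preconditioner tolerates)
            if 2 in factors:
                inv_h2 = inv_h2 / 4.0
        self._factor_chain = [self._factors(lv["shape"]) for lv in self.levels]

    def _sweep(self, lv, x, r, reverse):
        px, py, pz = self.periodic
        kernels.gauss_seidel(x, r, lv["bx"], lv["by"], lv["bz"], lv["unknown"],
                             px, py, pz, lv["inv_h2"], reverse)
        return x

    def _vcycle(self, li, r):
        lv = self.levels[li]
        x = np.zeros_like(r)
        if li == len(self.levels) - 1:
            for _ in range(self.COARSE_SWEEPS):
                self._sweep(lv, x, r, False)
                self._sweep(lv, x, r, True)
            return x
        self._sweep(lv, x, r, False)
        px, py, pz = self.periodic
        Ax = np.empty_like(x)
        kernels.poisson_apply(x, lv["bx"], lv["by"], lv["bz"], lv["unknown"],
                              px, py, pz, lv["inv_h2"], Ax)
        res = r - Ax
        factors = self._factor_chain[li]
        rc = self._block_reduce(res, factors, op="mean")
        ec = self._vcycle(li + 1, np.ascontiguousarray(rc))
        for ax, f in enumerate(factors):
            if f == 2:
                ec = np.repeat(ec, 2, axis=ax)
        x += np.where(lv["unknown"], ec, 0.0)
        return self._sweep(lv, x, r, True)

    def __call__(self, r):
        return self._vcycle(0, r)


class FlowSolver:
    """Generic stepper; LA-specific boundary plumbing is layered on top.

    Parameters
    ----------
    grid : CartesianGrid (mm).
    props : FluidProperties.
    config : SolverConfig (CFL, Poisson tolerance, ...).
    periodic : per-axis periodicity of the box.
    domain_provider : callable t_ms -> ImmersedDomain, or None for a fully
        fluid box.
    pressure_bc : callable (t_ms, solver) -> (mask, values) giving cells
        with fixed pressure (Pa), or None.
    body_accel : constant acceleration (m/s^2) added to the momentum
        equation (used by the channel-flow benchmark).
    """

    def __init__(self, grid: CartesianGrid, props: FluidProperties,
                 config: SolverConfig, periodic=(False, False, False),
                 domain_provider=None, pressure_bc=None,
                 body_accel=(0.0, 0.0, 0.0), wall_calibration=None):
        self.grid = grid
        self.props = props
        self.config = config
        self.periodic = tuple(bool(p) for p in periodic)
        self.domain_provider = domain_provider
        self.pressure_bc = pressure_bc
        self.wall_calibration = wall_calibration
        self.body_accel = tuple(float(a) for a in body_accel)
        self.h_m = grid.h * 1e-3
        self.state = StaggeredField.zeros(grid)
        self._conv_prev = None
        self._have_prev = False
        nx, ny, nz = grid.n
        self._conv = [np.zeros_like(self.state.u), np.zeros_like(self.state.v),
                      np.zeros_like(self.state.w)]
        self._lap = [np.zeros_like(self.state.u), np.zeros_like(self.state.v),
                     np.zeros_like(self.state.w)]
        self._div = np.zeros(grid.n)
        self._Ap = np.zeros(grid.n)
        self.domain: ImmersedDomain | None = None
        self._p_old = None
        self._mg = None
        # diagnostics
        self.step_count = 0
        self.max_div_ratio = 0.0
        self.max_cfl = 0.0
        self.max_cfl_post = 0.0
        self.last_poisson_iters = 0
        self.poisson_iter_total = 0

    # -- helpers ------------------------------------------------------------
    def _sync_periodic(self):
        if self.periodic[0]:
            self.state.u[-1] = self.state.u[0]
        if self.periodic[1]:
            self.state.v[:, -1] = self.state.v[:, 0]
        if self.periodic[2]:
            self.state.w[:, :, -1] = self.state.w[:, :, 0]

    def _face_coeffs(self, domain):
        nx, ny, nz = self.grid.n
        if domain is None:
            bx = np.ones((nx + 1, ny, nz))
            by = np.ones((nx, ny + 1, nz))
            bz = np.ones((nx, ny, nz + 1))
        else:
            bx, by, bz = (m.copy() for m in domain.mu)
            # restrict the projection to the fluid side: only faces between
            # two fluid cells carry a pressure correction. Wall-band fluxes
            # are fixed by the BDIM blend instead; without this, the large
            # port/chamber pressure differences pump a spurious circulation
            # through the permeable diffuse wall into the exterior region.
            fl = domain.fluid_mask
            bx[1:-1] *= fl[:-1] & fl[1:]
            by[:, 1:-1] *= fl[:, :-1] & fl[:, 1:]
            bz[:, :, 1:-1] *= fl[:, :, :-1] & fl[:, :, 1:]
            wrap = [fl[-1] & fl[0], fl[:, -1] & fl[:, 0], fl[:, :, -1] & fl[:, :, 0]]
            for ax, b in enumerate((bx, by, bz)):
                sl0 = [slice(None)] * 3
                sl1 = [slice(None)] * 3
                sl0[ax] = 0
                sl1[ax] = -1
                edge = wrap[ax] if self.periodic[ax] else 0.0
                b[tuple(sl0)] *= edge
                b[tuple(sl1)] *= edge
            # drop the near-zero tail to keep the conditioning benign
            for b in (bx, by, bz):
                b[b < 1e-3] = 0.0
        if not self.periodic[0]:
            bx[0] = 0.0
            bx[-1] = 0.0
        if not self.periodic[1]:
            by[:, 0] = 0.0
            by[:, -1] = 0.0
        if not self.periodic[2]:
            bz[:, :, 0] = 0.0
            bz[:, :, -1] = 0.0
        return bx, by, bz

    def _apply_wall_model(self, domain, star, bb):
        """Impose the immersed wall on the provisional velocity.

        Three classes of non-projected (b = 0) faces:

        - *mass* faces (adjacent to a fluid cell, i.e. the boundary of the
          fluid region): frozen at ``(1 - mu) w`` — these carry the wall
          volume flux the projection balances, and the wall-flux
          calibration rescales ``w`` so the discrete source is exact;
        - *ghost* faces (inside the solid within the band): mirrored value
          ``2 w - u(mirror)`` across the interface, which places the
          effective no-slip plane on the zero level set to second order
          (these faces only enter viscous/advective stencils of nearby
          fluid faces, never a fluid cell's divergence);
        - deep solid faces: the wall velocity itself (zero away from the
          band).

        Projected faces (b > 0) are left untouched: damping them toward the
        wall velocity would displace the effective wall into the fluid.
        """
        from .geometry import _face_sdf_from_cells
        from .fields import _interp_lattice

        fl = domain.fluid_mask
        eps = domain.epsilon_mm
        # cell-centered sdf gradient -> interface normal (flat axes: zero)
        grads = [np.gradient(domain.sdf, self.grid.h, axis=a)
                 if domain.sdf.shape[a] > 1 else np.zeros_like(domain.sdf)
                 for a in range(3)]
        for ax in range(3):
            b = bb[ax]
            mu = domain.mu[ax]
            w = domain.wall_velocity[ax]
            fs = (domain.face_sdf[ax] if domain.face_sdf is not None
                  else _face_sdf_from_cells(domain.sdf, ax))
            nonproj = b == 0.0
            pad = [(0, 0)] * 3
            pad[ax] = (1, 1)
            fl_pad = np.pad(fl, pad, mode="edge")
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[ax] = slice(0, fs.shape[ax])
            hi[ax] = slice(1, fs.shape[ax] + 1)
            touches_fluid = fl_pad[tuple(lo)] | fl_pad[tuple(hi)]
            mass = nonproj & touches_fluid
            ghost = nonproj & ~touches_fluid & (fs > 0.0) & (fs < eps)
            deep = nonproj & ~mass & ~ghost

            star_ax = star[ax]
            if np.any(ghost):
                idx = np.argwhere(ghost).astype(float)
                pts = (idx + 0.5) * self.grid.h + np.asarray(self.grid.origin)
                pts[:, ax] -= 0.5 * self.grid.h
                # face normal from the adjacent-cell-averaged gradient
                gvec = np.stack(
                    [0.5 * (np.pad(g, pad, mode="edge")[tuple(lo)]
                            + np.pad(g, pad, mode="edge")[tuple(hi)])[ghost]
                     for g in grads], axis=1)
                norm = np.linalg.norm(gvec, axis=1, keepdims=True)
                gvec /= np.maximum(norm, 1e-12)
                mirror = pts - 2.0 * fs[ghost][:, None] * gvec
                u_mirror = _interp_lattice(star_ax, self.grid, mirror, ax)
                star_ax[ghost] = 2.0 * w[ghost] - u_mirror
            star_ax[mass] = ((1.0 - mu) * w)[mass]
            star_ax[deep] = w[deep]

    def stable_dt(self, extra_speed: float = 0.0) -> float:
        """CFL- and diffusion-limited time step (s)."""
        umax = max(self.state.max_speed(), extra_speed, 1e-12)
        dt_cfl = self.config.cfl * self.h_m / umax
        dt_visc = self.h_m ** 2 / (6.0 * self.props.nu)
        return min(dt_cfl, dt_visc)

    # -- Poisson solve ------------------------------------------------------
    def _solve_pressure(self, rhs, bx, by, bz, unknown, p_fix, dirichlet,
                        tol_inf_r):
        px, py, pz = self.periodic
        inv_h2 = 1.0 / self.h_m ** 2
        # fold fixed Dirichlet values into the right-hand side
        if dirichlet is not None and np.any(dirichlet):
            kernels.poisson_apply(p_fix, bx, by, bz, unknown, px, py, pz,
                                  inv_h2, self._Ap)
            rhs = rhs - self._Ap
        else:
            m = rhs[unknown].mean() if np.any(unknown) else 0.0
            rhs = rhs - m
        rhs = np.where(unknown, rhs, 0.0)

        # warm start: linear extrapolation of the two previous pressures
        if self._p_old is not None and self._p_old.shape == self.state.p.shape:
            x = np.where(unknown, 2.0 * self.state.p - self._p_old, 0.0)
        else:
            x = np.where(unknown, self.state.p, 0.0)
        self._p_old = self.state.p
        if self._mg is None:
            self._mg = _MGPreconditioner(self.periodic)
        self._mg.setup(bx, by, bz, unknown, inv_h2)
        apply_M = lambda rr: np.where(unknown, self._mg(rr), 0.0)
        Ap = self._Ap
        kernels.poisson_apply(x, bx, by, bz, unknown, px, py, pz, inv_h2, Ap)
        r = rhs - Ap
        r[~unknown] = 0.0
        z = apply_M(r)
        pvec = z.copy()
        rz = float((r * z).sum())
        rhs_norm = float(np.linalg.norm(rhs))
        # a nonzero residual *sum* shows up directly as spurious created/lost
        # mass attributed to the ports, so control it alongside the max norm
        tol_sum_r = 10.0 * tol_inf_r
        it = 0
        r_inf = float(np.abs(r).max()) if r.size else 0.0
        r_sum = abs(float(r.sum()))
        while it < self.config.max_poisson_iter:
            if r_inf <= tol_inf_r and r_sum <= tol_sum_r:
                break
            if rhs_norm > 0 and np.linalg.norm(r) <= self.config.poisson_rtol * rhs_norm:
                break
            kernels.poisson_apply(pvec, bx, by, bz, unknown, px, py, pz, inv_h2, Ap)
            pAp = float((pvec * Ap).sum())
            if pAp <= 0:
                break
            alpha = rz / pAp
            x += alpha * pvec
            r -= alpha * Ap
            r[~unknown] = 0.0
            z = apply_M(r)
            rz_new = float((r * z).sum())
            beta = rz_new / rz if rz != 0 else 0.0
            rz = rz_new
            pvec = z + beta * pvec
            it += 1
            if it % 4 == 0 or rz == 0:
                r_inf = float(np.abs(r).max())
                r_sum = abs(float(r.sum()))
        else:
            r_inf = float(np.abs(r).max())
            if r_inf > 100 * tol_inf_r:
                raise SolverError(
                    f"pressure Poisson solve stalled: residual {r_inf:.3e} "
                    f"(target {tol_inf_r:.3e}) after {it} iterations")
        self.last_poisson_iters = it
        self.poisson_iter_total += it
        if dirichlet is not None and np.any(dirichlet):
            x = np.where(dirichlet, p_fix, x)
        elif np.any(unknown):
            x -= x[unknown].mean()
        return x

    # -- single step --------------------------------------------------------
    def step(self, dt_s: float):
        st = self.state
        cfg = self.config
        h_m = self.h_m
        inv_h = 1.0 / h_m
        nu = self.props.nu
        rho = self.props.density
        t_mid_ms = st.t_ms + 0.5 * dt_s * 1e3
        u_pre = st.max_speed()

        domain = (self.domain_provider(t_mid_ms)
                  if self.domain_provider is not None else None)
        self.domain = domain
        bx, by, bz = self._face_coeffs(domain)
        if domain is not None and self.wall_calibration is not None:
            self.wall_calibration(t_mid_ms, self, domain, (bx, by, bz))

        comps = [st.u, st.v, st.w]
        px, py, pz = self.periodic
        views = [
            # (component, transverse-1, transverse-2, flags, conv out, lap out)
            (st.u, st.v, st.w, (px, py, pz), self._conv[0], self._lap[0]),
            (st.v.transpose(1, 0, 2), st.u.transpose(1, 0, 2),
             st.w.transpose(1, 0, 2), (py, px, pz),
             self._conv[1].transpose(1, 0, 2), self._lap[1].transpose(1, 0, 2)),
            (st.w.transpose(2, 0, 1), st.u.transpose(2, 0, 1),
             st.v.transpose(2, 0, 1), (pz, px, py),
             self._conv[2].transpose(2, 0, 1), self._lap[2].transpose(2, 0, 1)),
        ]
        for c, a1, a2, (p0, p1, p2), conv_view, lap_view in views:
            kernels.convective_term(c, a1, a2, p0, p1, p2, inv_h, conv_view)
            kernels.diffusive_term(c, p0, p1, p2, inv_h * inv_h, lap_view)

        if self._have_prev:
            c_now, c_old = 1.5, -0.5
        else:
            c_now, c_old = 1.0, 0.0
            self._conv_prev = [np.zeros_like(a) for a in self._conv]

        star = []
        for ax, comp in enumerate(comps):
            rhs = (-(c_now * self._conv[ax] + c_old * self._conv_prev[ax])
                   + nu * self._lap[ax])
            if self.body_accel[ax] != 0.0:
                rhs = rhs + self.body_accel[ax]
            star.append(comp + dt_s * rhs)
        self._conv_prev, self._conv = self._conv, self._conv_prev
        self._have_prev = True

        if domain is not None:
            self._apply_wall_model(domain, star, (bx, by, bz))
        for ax in range(3):
            if not self.periodic[ax]:
                sl = [slice(None)] * 3
                for edge in (0, -1):
                    sl[ax] = edge
                    star[ax][tuple(sl)] = 0.0

        st.u, st.v, st.w = star
        self._sync_periodic()

        kernels.divergence(st.u, st.v, st.w, inv_h, self._div)
        diag_mask = ((bx[:-1] + bx[1:] + by[:, :-1] + by[:, 1:]
                      + bz[:, :, :-1] + bz[:, :, 1:]) > 0)

        if self.pressure_bc is not None:
            dirichlet, p_fix = self.pressure_bc(t_mid_ms, self)
        else:
            dirichlet, p_fix = None, None
        unknown = diag_mask.copy()
        if dirichlet is not None:
            unknown &= ~dirichlet

        u_ref = max(st.max_speed(), 1e-12)
        tol_div = 4e-7 * u_ref / self.h_m          # target max |div| (1/s)
        tol_inf_r = tol_div * rho / dt_s
        # A = -div(beta grad .): solve A p = -(rho/dt) div u*
        rhs = (-rho / dt_s) * self._div
        p = self._solve_pressure(rhs, bx, by, bz, unknown, p_fix, dirichlet,
                                 tol_inf_r)
        st.p = p
        kernels.pressure_correct(st.u, st.v, st.w, p, bx, by, bz,
                                 *self.periodic, (dt_s / rho) * inv_h)
        self._sync_periodic()

        # diagnostics: divergence on interior fluid cells (pressure unknowns)
        kernels.divergence(st.u, st.v, st.w, inv_h, self._div)
        record = unknown if domain is None else (unknown & domain.fluid_mask)
        if np.any(record):
            u_ref2 = max(st.max_speed(), 1e-12)
            ratio = float(np.abs(self._div[record]).max()) / (u_ref2 / self.h_m)
            self.max_div_ratio = max(self.max_div_ratio, ratio)
        # CFL with the speed the step was chosen against (pre-step), plus a
        # post-step monitor
        self.max_cfl = max(self.max_cfl, dt_s * u_pre / h_m)
        self.max_cfl_post = max(self.max_cfl_post, dt_s * st.max_speed() / h_m)

        st.t_ms += dt_s * 1e3
        self.step_count += 1
        if not st.is_finite():
            raise SolverError(f"non-finite field at t = {st.t_ms:.2f} ms")
        return st

    def advance_to(self, t_target_ms: float, extra_speed: float = 0.0,
                   max_steps: int = 10_000_000):
        """Step until ``t_target_ms``, choosing dt from the CFL bound."""
        n = 0
        while self.state.t_ms < t_target_ms - 1e-9:
            dt = self.stable_dt(extra_speed=extra_speed)
            dt = min(dt, (t_target_ms - self.state.t_ms) * 1e-3)
            self.step(dt)
            n += 1
            if n > max_steps:
                raise SolverError("step budget exceeded")
        return self.state


# ---------------------------------------------------------------------------
# LA port system
# ---------------------------------------------------------------------------

@dataclass
class PortModel:
    """State of one boundary port (PV inlet or MV outlet)."""

    label: str
    role: str                       # "PV" | "MV"
    area_mm2: float
    resistance_K: float = 0.0       # Pa s / mm^3 (PV only)
    baseline_P0: float = 0.0        # Pa
    flux_Q: float = 0.0             # mm^3/s, positive into the LA (PV) / out (MV)
    pressure: float = 0.0           # Pa (PV boundary value)
    outlet_speed: float = 0.0       # mm/ms (MV, diastole)


class _LAPorts:
    """Per-step boundary plumbing for the idealized LA run."""

    def __init__(self, immersion: AnalyticImmersion, anatomy: AnatomyConfig,
                 solver_cfg: SolverConfig, props: FluidProperties):
        self.imm = immersion
        self.geometry = immersion.geometry
        self.anatomy = anatomy
        self.cfg = solver_cfg
        self.props = props
        h = immersion.grid.h
        self.ports: dict[str, PortModel] = {}
        self.pv_indices: dict[str, int] = {}
        for i, tube in enumerate(self.geometry.tubes):
            if tube.role == "PV" and not tube.resected:
                K = float(compute_pv_resistances([tube.area_mm2], solver_cfg.kappa)[0])
                self.ports[tube.label] = PortModel(
                    label=tube.label, role="PV", area_mm2=tube.area_mm2,
                    resistance_K=K)
                self.pv_indices[tube.label] = i
            elif tube.role == "MV":
                self.ports[MV_LABEL] = PortModel(
                    label=MV_LABEL, role="MV", area_mm2=tube.area_mm2)
                self.mv_index = i
        self.h = h
        self.mv_phase = "closed"
        self._q_mv_m3_s = 0.0
        self.last_lambda = 1.0
        self.last_mv_speed = 0.0

    # -- MV handling --------------------------------------------------------
    def update_mv(self, t_ms: float):
        self.mv_phase, q = mv_state(self.anatomy.lv_volume_coeffs, t_ms,
                                    self.anatomy.period_ms,
                                    self.cfg.mv_hysteresis_ms, self.mv_phase)
        port = self.ports[MV_LABEL]
        # q in mL/ms -> outlet speed mm/ms over the MV area
        q_mm3_per_ms = q * 1000.0
        port.outlet_speed = q_mm3_per_ms / port.area_mm2 if q > 0 else 0.0
        self._q_mv_m3_s = q * 1e-3 if q > 0 else 0.0  # mL/ms -> m^3/s
        return port.outlet_speed

    # -- discrete wall-flux calibration --------------------------------------
    def calibrate(self, t_ms: float, solver: "FlowSolver", domain, b):
        """Rescale the wall motion and MV piston speed so the *discrete*
        boundary sources match the analytic chamber volume rate and the
        prescribed valve flow rate.

        The diffuse (BDIM) wall imposes its flux through the frozen
        (non-projected) faces as (1 - mu) * w; on coarse grids the volume
        rate this realizes differs from the analytic d(V)/dt by O(h/R).
        A single global factor on the motion field, and the effective
        piston speed Q_MV / A_discrete, remove that mismatch.
        """
        if domain.wall_motion is None:
            return
        h_m = solver.h_m
        fl = domain.fluid_mask
        div = np.empty(solver.grid.n)

        def source(g):
            comps = []
            for ax in range(3):
                comps.append(np.where(b[ax] == 0.0,
                                      (1.0 - domain.mu[ax]) * g[ax], 0.0))
            kernels.divergence(comps[0], comps[1], comps[2], 1.0 / h_m, div)
            return float(div[fl].sum()) * h_m ** 3  # m^3/s

        target = self.geometry.chamber_volume_rate(t_ms) * 1e-6  # mm^3/ms -> m^3/s
        s_wall = source(domain.wall_motion)
        scale_ref = max(abs(target), 1e-8)
        # the single frozen crossing face per normal line carries ~(1 - mu)
        # of the wall velocity, so the raw discrete source is roughly half
        # the analytic rate and lambda ~ 2 is typical
        if abs(s_wall) > 0.2 * scale_ref and target != 0.0:
            lam = float(np.clip(target / s_wall, 0.2, 5.0))
        else:
            lam = 1.0

        q_mv = self._q_mv_m3_s
        u_geom = self.ports[MV_LABEL].outlet_speed
        u_eff = 0.0
        if q_mv > 0.0:
            a_disc = source(domain.piston_unit)  # m^2 per unit speed
            a_geom = self.ports[MV_LABEL].area_mm2 * 1e-6
            if a_disc > 0.3 * a_geom:
                u_eff = q_mv / a_disc
            else:
                u_eff = u_geom
        self.last_lambda = lam
        self.last_mv_speed = u_eff
        self.last_dVdt_mm3_s = target * 1e9  # the rate enforced this step
        domain.wall_velocity = tuple(
            lam * m + u_eff * p
            for m, p in zip(domain.wall_motion, domain.piston_unit))

    # -- domain provider ----------------------------------------------------
    def domain_provider(self, t_ms: float) -> ImmersedDomain:
        speed = self.update_mv(t_ms)
        band = self.imm.epsilon_mm + 0.75 * self.h
        return self.imm.domain(t_ms, mv_normal_speed=speed, mv_band_mm=band)

    # -- PV pressure Dirichlet layer ----------------------------------------
    def pressure_bc(self, t_ms: float, solver: FlowSolver):
        s = self.geometry.scale(t_ms)
        sdf_flat = solver.domain.sdf.reshape(-1)
        mask = np.zeros(sdf_flat.shape, dtype=bool)
        vals = np.zeros(sdf_flat.shape)
        h = self.h
        self._dirichlet_cells = {}
        for label, i in self.pv_indices.items():
            tube = self.geometry.tubes[i]
            y = self.imm._axial[i] - s * tube.attach_mm
            rho = self.imm._rho[i]
            port = self.ports[label]
            sel = ((rho < tube.radius_mm) & (sdf_flat < 0.0)
                   & (y > tube.length_mm - 3.0 * h)
                   & (y < tube.length_mm - 1.0 * h))
            if not np.any(sel):
                raise SolverError(
                    f"{label}: no pressure-boundary cells (tube too short "
                    f"for this grid resolution)")
            mask |= sel
            vals[sel] = port.pressure
            self._dirichlet_cells[label] = sel
        return mask.reshape(solver.grid.n), vals.reshape(solver.grid.n)

    # -- flux measurement ----------------------------------------------------
    def _plane_flux(self, state: StaggeredField, grid: CartesianGrid,
                    tube, offset_mm: float) -> float:
        """Flux through the tube cross-section ``offset_mm`` before its end
        (mm^3/s, positive along the outward tube axis)."""
        s = self.geometry.scale(state.t_ms)
        center = (s * tube.attach_mm + tube.length_mm - offset_mm) * tube.direction
        return port_flux(state, grid, center, tube.direction, tube.area_mm2)

    def measure(self, state: StaggeredField, grid: CartesianGrid,
                solver: FlowSolver | None = None, with_plane: bool = False):
        """Record port fluxes and update the lagged boundary pressures.

        PV fluxes are the exact discrete fluxes through each port section
        (Gauss: cell volume times divergence summed over the port's
        pressure-boundary layer); the plane-quadrature flux is recorded
        alongside. The MV flux is the discretely realized piston rate.
        """
        cell_m3 = (grid.h * 1e-3) ** 3
        rows = []
        for label, port in self.ports.items():
            if port.role == "PV":
                tube = self.geometry.tubes[self.pv_indices[label]]
                q_plane = (-self._plane_flux(state, grid, tube, offset_mm=4.5 * self.h)
                           if (with_plane or solver is None) else np.nan)
                if solver is not None and label in getattr(self, "_dirichlet_cells", {}):
                    sel = self._dirichlet_cells[label]
                    q_in = float(solver._div.reshape(-1)[sel].sum()) * cell_m3 * 1e9
                else:
                    q_in = q_plane
                port.flux_Q = q_in  # mm^3/s, positive INTO the chamber
                # resistance law with the flux signed toward the vein (out of
                # the LA): inflow pulls the boundary pressure below baseline,
                # the stabilizing direction of the terminal-resistance model.
                # Applied to the next step (lagged, explicit coupling).
                port.pressure = port.baseline_P0 - port.resistance_K * q_in
            else:
                tube = self.geometry.tubes[self.mv_index]
                q_plane = (self._plane_flux(state, grid, tube, offset_mm=2.5 * self.h)
                           if with_plane else np.nan)
                port.flux_Q = self._q_mv_m3_s * 1e9  # realized piston rate
            rows.append(dict(t_ms=state.t_ms, label=label, role=port.role,
                             Q_mm3_s=port.flux_Q,
                             Q_plane_mm3_s=q_plane,
                             Q_vein_mm3_s=(-port.flux_Q if port.role == "PV"
                                           else port.flux_Q),
                             P_Pa=port.pressure,
                             K=port.resistance_K, mv_phase=self.mv_phase))
        return rows


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Velocity snapshots, port series and diagnostics of one case run."""

    grid: CartesianGrid
    surface: MovingSurface
    solver_config: SolverConfig
    props: FluidProperties
    snapshot_times_ms: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)          # StaggeredField (float32)
    snapshot_domains: list = field(default_factory=list)   # ImmersedDomain sdf only
    port_rows: list = field(default_factory=list)
    balance_rows: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def period_ms(self) -> float:
        return self.surface.period_ms

    @property
    def final_cycle_start_ms(self) -> float:
        return (self.solver_config.n_cycles - 1) * self.period_ms

    def port_series(self) -> pd.DataFrame:
        return pd.DataFrame(self.port_rows)

    def balance_series(self) -> pd.DataFrame:
        return pd.DataFrame(self.balance_rows)

    def final_cycle_mask(self, df: pd.DataFrame) -> pd.Series:
        return df["t_ms"] >= self.final_cycle_start_ms - 1e-6


def run_simulation(surface: MovingSurface, config: SolverConfig,
                   props: FluidProperties | None = None,
                   progress: bool = False) -> SimulationResult:
    """Run ``config.n_cycles`` cardiac cycles of the idealized LA from rest.

    Snapshots are stored densely (``final_cycle_snapshot_dt_ms``) over the
    final cycle for postprocessing (energetics, FTLE, pathlines); port
    fluxes/pressures and global mass-balance terms are recorded every step.
    """
    if surface.geometry is None or surface.config is None:
        raise ValueError("run_simulation requires an idealized (built) surface")
    props = props or FluidProperties()
    geometry = surface.geometry
    anatomy = surface.config
    grid = CartesianGrid.from_bounds(
        geometry.bounds(margin_mm=config.domain_margin_mm), config.grid_n)
    eps = config.bdim_epsilon_cells * grid.h
    imm = AnalyticImmersion(geometry, grid, eps)
    ports = _LAPorts(imm, anatomy, config, props)
    solver = FlowSolver(grid, props, config,
                        domain_provider=ports.domain_provider,
                        pressure_bc=ports.pressure_bc,
                        wall_calibration=ports.calibrate)

    T = anatomy.period_ms
    t_end = config.n_cycles * T
    final_start = (config.n_cycles - 1) * T
    snap_times = np.arange(final_start, t_end + 1e-9,
                           config.final_cycle_snapshot_dt_ms)

    result = SimulationResult(grid=grid, surface=surface, solver_config=config,
                              props=props)

    mv_area = geometry.tube(MV_LABEL).area_mm2 if any(
        t.role == "MV" for t in geometry.tubes) else 1.0

    def anticipated_speed(t_ms: float) -> float:
        """Upcoming MV outlet speed (mm/ms); keeps the CFL bound honest
        across the impulsive valve opening."""
        q = max(float(anatomy.lv_volume_rate(t_ms)), 0.0)
        return q * 1000.0 / mv_area

    dt_cap = T * 1e-3 / 600.0  # absolute cap: >= 600 steps per cycle
    next_snap = 0

    def store_due_snapshots():
        nonlocal next_snap
        while (next_snap < len(snap_times)
               and solver.state.t_ms >= snap_times[next_snap] - 1e-6):
            result.snapshot_times_ms.append(snap_times[next_snap])
            result.snapshots.append(solver.state.copy(dtype=np.float32))
            sdf = (solver.domain.sdf if solver.domain is not None
                   else imm.cell_sdf(solver.state.t_ms))
            result.snapshot_domains.append(np.asarray(sdf, dtype=np.float32))
            next_snap += 1

    store_due_snapshots()
    while solver.state.t_ms < t_end - 1e-9:
        u_eff = 1.15 * max(solver.state.max_speed(),
                           anticipated_speed(solver.state.t_ms + 2.0), 1e-9)
        dt = min(config.cfl * solver.h_m / u_eff,
                 solver.h_m ** 2 / (6.0 * props.nu), dt_cap)
        t_next = t_end
        if next_snap < len(snap_times):
            t_next = min(t_next, snap_times[next_snap])
        dt = min(dt, max((t_next - solver.state.t_ms) * 1e-3, 1e-9))
        solver.step(dt)
        rows = ports.measure(solver.state, grid, solver)
        result.port_rows.extend(rows)
        q_pv = sum(r["Q_mm3_s"] for r in rows if r["role"] == "PV")
        q_mv = sum(r["Q_mm3_s"] for r in rows if r["role"] == "MV")
        result.balance_rows.append(dict(
            t_ms=solver.state.t_ms,
            sum_pv_inflow_mm3_s=q_pv,
            mv_outflow_mm3_s=q_mv,
            # the chamber volume rate enforced over this step (evaluated at
            # the step midpoint, like the rest of the geometry)
            dVdt_chamber_mm3_s=getattr(ports, "last_dVdt_mm3_s",
                                       geometry.chamber_volume_rate(
                                           solver.state.t_ms) * 1e3),
            mv_phase=ports.mv_phase,
        ))
        store_due_snapshots()
        if progress and solver.step_count % 200 == 0:
            print(f"  t = {solver.state.t_ms:8.1f} ms  steps = {solver.step_count}"
                  f"  umax = {solver.state.max_speed():6.3f} m/s"
                  f"  poisson iters = {solver.last_poisson_iters}")

    result.diagnostics = dict(
        steps=solver.step_count,
        max_div_ratio=solver.max_div_ratio,
        max_cfl=solver.max_cfl,
        max_cfl_post=solver.max_cfl_post,
        poisson_iters_mean=solver.poisson_iter_total / max(solver.step_count, 1),
    )
    return result
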