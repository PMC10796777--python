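"""Numba kernels for the staggered-grid solver.

MAC layout: the velocity component normal to direction 0 lives on a
``(n0+1, n1, n2)`` face lattice (both boundary faces stored; on periodic
axes the caller keeps ``c[n0] == c[0]``), transverse components on their
own lattices, pressure at cell centers ``(n0, n1, n2)``.

The advection/diffusion kernels are written for a generic component whose
own direction is axis 0; callers pass transposed views for the v and w
components. Indices beyond a non-periodic boundary are clamped, which is
harmless here because flow domains are immersed strictly inside the box
(boundary-adjacent faces are solid).

Advection uses conservative fluxes with upwind-biased third-order (QUICK)
face interpolation: at the coarse test grids the cell Peclet number is far
above the centered-scheme comfort zone and a pure centered convective term
accumulates grid-scale oscillations; QUICK's scale-selective dissipation is
negligible on resolved scales (verified by the decaying-vortex benchmark).
"""

from __future__ import annotations

from numba import njit

__all__ = [
    "divergence",
    "convective_term",
    "diffusive_term",
    "poisson_apply",
    "pressure_correct",
]


@njit(cache=True, fastmath=True)
def divergence(u, v, w, inv_h, out):
    nx, ny, nz = out.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                out[i, j, k] = (
                    (u[i + 1, j, k] - u[i, j, k])
                    + (v[i, j + 1, k] - v[i, j, k])
                    + (w[i, j, k + 1] - w[i, j, k])
                ) * inv_h


@njit(cache=True, fastmath=True, inline="always")
def _quick(up2, up1, dn1, dn2, vel):
    """QUICK interpolation at a face; up/down defined for positive vel."""
    if vel >= 0.0:
        return 0.375 * dn1 + 0.75 * up1 - 0.125 * up2
    return 0.375 * up1 + 0.75 * dn1 - 0.125 * dn2


@njit(cache=True, fastmath=True, inline="always")
def _idx(i, n, periodic):
    """Wrap (periodic) or clamp (wall) an index into [0, n)."""
    if periodic:
        return i % n
    if i < 0:
        return 0
    if i >= n:
        return n - 1
    return i


@njit(cache=True, fastmath=True)
def convective_term(c, a1, a2, p0, p1, p2, inv_h, out):
    """div(velocity * c) for component ``c`` collocated on direction-0 faces.

    c : (n0+1, n1, n2); a1 : (n0, n1+1, n2); a2 : (n0, n1, n2+1).
    Writes interior faces of ``out`` (all faces 0..n0-1 when periodic).
    """
    n0 = a1.shape[0]
    n1 = c.shape[1]
    n2 = c.shape[2]
    i_start = 0 if p0 else 1
    for i in range(i_start, n0):
        if p0:
            ifm1 = (i - 1) % n0
            ifp1 = (i + 1) % n0
            ifm2 = (i - 2) % n0
            ifp2 = (i + 2) % n0
            icm = (i - 1) % n0
        else:
            ifm1 = i - 1
            ifp1 = i + 1
            ifm2 = i - 2 if i >= 2 else 0
            ifp2 = i + 2 if i + 2 <= n0 else n0
            icm = i - 1
        ic = i if i < n0 else 0
        for j in range(n1):
            jm2 = _idx(j - 2, n1, p1)
            jm1 = _idx(j - 1, n1, p1)
            jp1 = _idx(j + 1, n1, p1)
            jp2 = _idx(j + 2, n1, p1)
            for k in range(n2):
                km2 = _idx(k - 2, n2, p2)
                km1 = _idx(k - 1, n2, p2)
                kp1 = _idx(k + 1, n2, p2)
                kp2 = _idx(k + 2, n2, p2)

                # direction 0: fluxes at the two neighboring cell centers
                ub_hi = 0.5 * (c[i, j, k] + c[ifp1, j, k])
                f_hi = ub_hi * _quick(c[ifm1, j, k], c[i, j, k],
                                      c[ifp1, j, k], c[ifp2, j, k], ub_hi)
                ub_lo = 0.5 * (c[ifm1, j, k] + c[i, j, k])
                f_lo = ub_lo * _quick(c[ifm2, j, k], c[ifm1, j, k],
                                      c[i, j, k], c[ifp1, j, k], ub_lo)
                acc = (f_hi - f_lo) * inv_h

                # direction 1: fluxes at the j and j+1 edges of this face
                v_lo = 0.5 * (a1[icm, j, k] + a1[ic, j, k])
                g_lo = v_lo * _quick(c[i, jm2, k], c[i, jm1, k],
                                     c[i, j, k], c[i, jp1, k], v_lo)
                v_hi = 0.5 * (a1[icm, j + 1, k] + a1[ic, j + 1, k])
                g_hi = v_hi * _quick(c[i, jm1, k], c[i, j, k],
                                     c[i, jp1, k], c[i, jp2, k], v_hi)
                acc += (g_hi - g_lo) * inv_h

                # direction 2
                w_lo = 0.5 * (a2[icm, j, k] + a2[ic, j, k])
                h_lo = w_lo * _quick(c[i, j, km2], c[i, j, km1],
                                     c[i, j, k], c[i, j, kp1], w_lo)
                w_hi = 0.5 * (a2[icm, j, k + 1] + a2[ic, j, k + 1])
                h_hi = w_hi * _quick(c[i, j, km1], c[i, j, k],
                                     c[i, j, kp1], c[i, j, kp2], w_hi)
                acc += (h_hi - h_lo) * inv_h

                out[i, j, k] = acc


@njit(cache=True, fastmath=True)
def diffusive_term(c, p0, p1, p2, inv_h2, out):
    """7-point Laplacian of a face-collocated component (interior faces)."""
    n0 = c.shape[0] - 1
    n1 = c.shape[1]
    n2 = c.shape[2]
    i_start = 0 if p0 else 1
    for i in range(i_start, n0):
        if p0:
            im = (i - 1) % n0
            ip = (i + 1) % n0
        else:
            im = i - 1
            ip = i + 1
        for j in range(n1):
            jm = _idx(j - 1, n1, p1)
            jp = _idx(j + 1, n1, p1)
            for k in range(n2):
                km = _idx(k - 1, n2, p2)
                kp = _idx(k + 1, n2, p2)
                out[i, j, k] = (
                    c[ip, j, k] + c[im, j, k] + c[i, jp, k] + c[i, jm, k]
                    + c[i, j, kp] + c[i, j, km] - 6.0 * c[i, j, k]
                ) * inv_h2


@njit(cache=True, fastmath=True)
def poisson_apply(p, bx, by, bz, unknown, px, py, pz, inv_h2, out):
    """out = -div(beta grad p) on unknown cells (0 elsewhere).

    ``p`` must hold zeros outside the unknown set for the homogeneous
    operator (fixed Dirichlet values are folded into the right-hand side by
    the caller). Face coefficients are zero on solid and box-boundary faces,
    which encodes the Neumann walls.
    """
    nx, ny, nz = out.shape
    for i in range(nx):
        im = _idx(i - 1, nx, px)
        ip = _idx(i + 1, nx, px)
        for j in range(ny):
            jm = _idx(j - 1, ny, py)
            jp = _idx(j + 1, ny, py)
            for k in range(nz):
                if not unknown[i, j, k]:
                    out[i, j, k] = 0.0
                    continue
                km = _idx(k - 1, nz, pz)
                kp = _idx(k + 1, nz, pz)
                pc = p[i, j, k]
                acc = bx[i + 1, j, k] * (pc - p[ip, j, k])
                acc += bx[i, j, k] * (pc - p[im, j, k])
                acc += by[i, j + 1, k] * (pc - p[i, jp, k])
                acc += by[i, j, k] * (pc - p[i, jm, k])
                acc += bz[i, j, k + 1] * (pc - p[i, j, kp])
                acc += bz[i, j, k] * (pc - p[i, j, km])
                out[i, j, k] = acc * inv_h2


@njit(cache=True, fastmath=True)
def gauss_seidel(p, rhs, bx, by, bz, unknown, px, py, pz, inv_h2, reverse):
    """One lexicographic Gauss-Seidel sweep of -div(beta grad p) = rhs.

    ``reverse`` selects the backward ordering; a forward/backward pair is a
    symmetric smoother (SSOR with omega = 1), which keeps a multigrid
    V-cycle usable as a CG preconditioner.
    """
    nx, ny, nz = p.shape
    ii = range(nx - 1, -1, -1) if reverse else range(nx)
    for i in ii:
        im = _idx(i - 1, nx, px)
        ip = _idx(i + 1, nx, px)
        jj = range(ny - 1, -1, -1) if reverse else range(ny)
        for j in jj:
            jm = _idx(j - 1, ny, py)
            jp = _idx(j + 1, ny, py)
            kk = range(nz - 1, -1, -1) if reverse else range(nz)
            for k in kk:
                if not unknown[i, j, k]:
                    continue
                km = _idx(k - 1, nz, pz)
                kp = _idx(k + 1, nz, pz)
                diag = (bx[i + 1, j, k] + bx[i, j, k] + by[i, j + 1, k]
                        + by[i, j, k] + bz[i, j, k + 1] + bz[i, j, k])
                if diag <= 0.0:
                    continue
                off = (bx[i + 1, j, k] * p[ip, j, k] + bx[i, j, k] * p[im, j, k]
                       + by[i, j + 1, k] * p[i, jp, k] + by[i, j, k] * p[i, jm, k]
                       + bz[i, j, k + 1] * p[i, j, kp] + bz[i, j, k] * p[i, j, km])
                p[i, j, k] = (rhs[i, j, k] / inv_h2 + off) / diag


@njit(cache=True, fastmath=True)
def pressure_correct(u, v, w, p, bx, by, bz, px, py, pz, scale_inv_h):
    """u -= scale * beta * grad p on every face with nonzero coefficient."""
    nx, ny, nz = p.shape
    for i in range(nx + 1):
        iw = _idx(i - 1, nx, px)
        ic = _idx(i, nx, px)
        for j in range(ny):
            for k in range(nz):
                b = bx[i, j, k]
                if b != 0.0:
                    u[i, j, k] -= scale_inv_h * b * (p[ic, j, k] - p[iw, j, k])
    for i in range(nx):
        for j in range(ny + 1):
            js = _idx(j - 1, ny, py)
            jc = _idx(j, ny, py)
            for k in range(nz):
                b = by[i, j, k]
                if b != 0.0:
                    v[i, j, k] -= scale_inv_h * b * (p[i, jc, k] - p[i, js, k])
    for i in range(nx):
        for j in range(ny):
            for k in range(nz + 1):
                b = bz[i, j, k]
                if b != 0.0:
                    kb = _idx(k - 1, nz, pz)
                    kc = _idx(k, nz, pz)
                    w[i, j, k] -= scale_inv_h * b * (p[i, j, kc] - p[i, j, kb])
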