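"""Staggered (MAC) velocity/pressure fields and interpolation utilities.

Velocity components live on face lattices: ``u`` on x-faces
``(nx+1, ny, nz)``, ``v`` on y-faces, ``w`` on z-faces; pressure at cell
centers. Velocities are stored in m/s (numerically identical to mm/ms),
pressure in Pa, positions in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CartesianGrid
from . import kernels

__all__ = [
    "StaggeredField",
    "divergence",
    "interpolate_staggered",
    "cell_centered_velocity",
]


@dataclass
class StaggeredField:
    """Face-normal velocities (m/s) and cell-centered pressure (Pa)."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    t_ms: float = 0.0

    @classmethod
    def zeros(cls, grid: CartesianGrid, t_ms: float = 0.0) -> "StaggeredField":
        nx, ny, nz = grid.n
        return cls(
            u=np.zeros((nx + 1, ny, nz)),
            v=np.zeros((nx, ny + 1, nz)),
            w=np.zeros((nx, ny, nz + 1)),
            p=np.zeros((nx, ny, nz)),
            t_ms=t_ms,
        )

    def copy(self, dtype=None) -> "StaggeredField":
        cast = (lambda a: a.astype(dtype)) if dtype is not None else (lambda a: a.copy())
        return StaggeredField(cast(self.u), cast(self.v), cast(self.w),
                              cast(self.p), self.t_ms)

    def max_speed(self) -> float:
        return max(np.abs(self.u).max(), np.abs(self.v).max(), np.abs(self.w).max())

    def is_finite(self) -> bool:
        return all(np.isfinite(a).all() for a in (self.u, self.v, self.w, self.p))


def divergence(state: StaggeredField, grid: CartesianGrid) -> np.ndarray:
    """Discrete staggered divergence (1/s) at cell centers."""
    out = np.empty(grid.n)
    kernels.divergence(state.u, state.v, state.w, 1.0 / (grid.h * 1e-3), out)
    return out


def _interp_lattice(comp: np.ndarray, grid: CartesianGrid, points_mm: np.ndarray,
                    staggered_axis: int) -> np.ndarray:
    """Trilinear interpolation of one face-lattice component at points (mm).

    The component's own axis has nodes at face positions ``origin + i h``;
    the other axes at cell centers ``origin + (i + 1/2) h``. Out-of-range
    coordinates are clamped to the lattice (constant extrapolation).
    """
    pts = np.asarray(points_mm, dtype=float)
    h = grid.h
    idx = []
    frac = []
    for ax in range(3):
        x = pts[..., ax] - grid.origin[ax]
        if ax == staggered_axis:
            s = x / h
        else:
            s = x / h - 0.5
        n_nodes = comp.shape[ax]
        s = np.clip(s, 0.0, n_nodes - 1.0 - 1e-12)
        i0 = np.floor(s).astype(np.int64)
        idx.append(i0)
        frac.append(s - i0)
    out = np.zeros(pts.shape[:-1])
    for dx in (0, 1):
        wx = frac[0] if dx else 1.0 - frac[0]
        for dy in (0, 1):
            wy = frac[1] if dy else 1.0 - frac[1]
            for dz in (0, 1):
                wz = frac[2] if dz else 1.0 - frac[2]
                out += (wx * wy * wz) * comp[idx[0] + dx, idx[1] + dy, idx[2] + dz]
    return out


def interpolate_staggered(state_or_uvw, grid: CartesianGrid,
                          points_mm: np.ndarray) -> np.ndarray:
    """Velocity vector (m/s) at arbitrary points by per-component trilinear
    interpolation on each staggered lattice."""
    if isinstance(state_or_uvw, StaggeredField):
        comps = (state_or_uvw.u, state_or_uvw.v, state_or_uvw.w)
    else:
        comps = state_or_uvw
    pts = np.asarray(points_mm, dtype=float)
    out = np.empty(pts.shape)
    for ax in range(3):
        out[..., ax] = _interp_lattice(np.asarray(comps[ax], dtype=float), grid, pts, ax)
    return out


def cell_centered_velocity(state: StaggeredField) -> np.ndarray:
    """(nx, ny, nz, 3) velocity averaged from faces to cell centers."""
    u, v, w = state.u, state.v, state.w
    return np.stack(
        [
            0.5 * (u[1:, :, :] + u[:-1, :, :]),
            0.5 * (v[:, 1:, :] + v[:, :-1, :]),
            0.5 * (w[:, :, 1:] + w[:, :, :-1]),
        ],
        axis=-1,
    )
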