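"""Lagrangian postprocessing: tracer advection, pathlines, backward FTLE.

Velocity fields are linearly interpolated in space (per staggered
component) and in time between stored snapshots; tracer trajectories use
classical fourth-order Runge-Kutta. The backward finite-time Lyapunov
exponent (FTLE) on a plane is

    FTLE = ln(sigma_max) / |tau|,

where sigma_max is the largest singular value of the in-plane deformation
gradient of the flow map over the horizon tau (negative tau = backward
integration; ridges of the backward FTLE mark attracting material surfaces
separating the pulmonary-vein inflow jets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import interpolate_staggered
from .geometry import CartesianGrid

__all__ = [
    "VelocitySeries",
    "TracerSet",
    "PlaneSpec",
    "FTLEField",
    "interpolate_velocity",
    "advect_tracers",
    "compute_pathlines",
    "backward_ftle",
]

STATUS_ACTIVE = 0
STATUS_WALL = 1
STATUS_EXITED = 2


class VelocitySeries:
    """Time-ordered staggered velocity snapshots on a common grid."""

    def __init__(self, grid: CartesianGrid, times_ms, states,
                 sdf_fn=None):
        """``sdf_fn(points_mm, t_ms)`` (optional) defines the fluid domain
        for tracer termination (negative inside fluid)."""
        self.grid = grid
        self.times_ms = np.asarray(times_ms, dtype=float)
        if len(self.times_ms) < 2:
            raise ValueError("need at least two snapshots")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("snapshot times must be strictly increasing")
        self.states = list(states)
        self.sdf_fn = sdf_fn

    @classmethod
    def from_result(cls, result, use_geometry_sdf: bool = True):
        sdf_fn = None
        if use_geometry_sdf and result.surface.geometry is not None:
            geom = result.surface.geometry
            sdf_fn = lambda pts, t: geom.sdf(np.atleast_2d(pts), t)
        return cls(result.grid, result.snapshot_times_ms, result.snapshots,
                   sdf_fn=sdf_fn)

    @property
    def span_ms(self):
        return self.times_ms[0], self.times_ms[-1]

    def velocity(self, points_mm: np.ndarray, t_ms: float) -> np.ndarray:
        """Velocity (mm/ms) at points, linear in space and time."""
        t0, t1 = self.span_ms
        if not (t0 - 1e-9 <= t_ms <= t1 + 1e-9):
            raise ValueError(f"t = {t_ms} ms outside stored span [{t0}, {t1}]")
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        lo = np.asarray(self.grid.origin)
        hi = lo + np.asarray(self.grid.n) * self.grid.h
        if np.any(pts < lo - 1e-9) or np.any(pts > hi + 1e-9):
            raise ValueError("tracer position outside the grid")
        i = int(np.clip(np.searchsorted(self.times_ms, t_ms) - 1, 0,
                        len(self.times_ms) - 2))
        ta, tb = self.times_ms[i], self.times_ms[i + 1]
        wa = (tb - t_ms) / (tb - ta)
        va = interpolate_staggered(self.states[i], self.grid, pts)
        vb = interpolate_staggered(self.states[i + 1], self.grid, pts)
        return wa * va + (1.0 - wa) * vb


def interpolate_velocity(series: VelocitySeries, x_mm, t_ms: float) -> np.ndarray:
    """Velocity (mm/ms) at one or more positions; see :class:`VelocitySeries`."""
    x = np.asarray(x_mm, dtype=float)
    out = series.velocity(x, t_ms)
    return out[0] if x.ndim == 1 else out


@dataclass
class TracerSet:
    """Mass-less tracers with provenance labels and termination status."""

    positions: np.ndarray                 # (N, 3) mm
    labels: np.ndarray                    # (N,) str or int, seed provenance
    status: np.ndarray = None             # (N,) STATUS_*
    t_ms: float = 0.0

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        n = len(self.positions)
        if self.labels is None:
            self.labels = np.zeros(n, dtype=int)
        self.labels = np.asarray(self.labels)
        if self.status is None:
            self.status = np.zeros(n, dtype=np.int8)

    @property
    def active(self) -> np.ndarray:
        return self.status == STATUS_ACTIVE


def _rk4_step(series, x, t_ms, dt_ms):
    k1 = series.velocity(x, t_ms)
    k2 = series.velocity(x + 0.5 * dt_ms * k1, t_ms + 0.5 * dt_ms)
    k3 = series.velocity(x + 0.5 * dt_ms * k2, t_ms + 0.5 * dt_ms)
    k4 = series.velocity(x + dt_ms * k3, t_ms + dt_ms)
    return x + (dt_ms / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def advect_tracers(tracers: TracerSet, series: VelocitySeries, t0_ms: float,
                   t1_ms: float, dt_trace_ms: float,
                   record_every: int = 1):
    """Integrate tracers from t0 to t1 (either direction) by RK4.

    Tracers crossing into the solid (sdf >= 0, when the series carries a
    domain) are frozen with status "wall". Returns ``(tracers, trajectory)``
    where trajectory has shape (n_records, N, 3).
    """
    direction = np.sign(t1_ms - t0_ms)
    if direction == 0:
        return tracers, np.asarray([tracers.positions])
    dt = abs(dt_trace_ms) * direction
    x = tracers.positions.copy()
    t = float(t0_ms)
    traj = [x.copy()]
    nstep = 0
    while (t1_ms - t) * direction > 1e-9:
        step = dt if (t1_ms - t) * direction > abs(dt) else (t1_ms - t)
        act = tracers.active
        if np.any(act):
            x_new = _rk4_step(series, x[act], t, step)
            if series.sdf_fn is not None:
                hit = series.sdf_fn(x_new, t + step) >= 0.0
                idx = np.flatnonzero(act)
                tracers.status[idx[hit]] = STATUS_WALL
                x_new[hit] = x[act][hit]  # freeze at pre-crossing position
            x[act] = x_new
        t += step
        nstep += 1
        if nstep % record_every == 0:
            traj.append(x.copy())
    if nstep % record_every != 0:
        traj.append(x.copy())
    tracers.positions = x
    tracers.t_ms = t
    return tracers, np.asarray(traj)


def _disk_seeds(center, normal, radius, n_r=3, n_t=8, rng=None, jitter=0.0):
    from .anatomy import _orthonormal_basis

    e1, e2 = _orthonormal_basis(np.asarray(normal, dtype=float))
    rr = (np.arange(n_r) + 0.5) / n_r * radius
    tt = 2 * np.pi * np.arange(n_t) / n_t
    R, T = np.meshgrid(rr, tt, indexing="ij")
    if rng is not None and jitter > 0:
        R = R + rng.uniform(-jitter, jitter, R.shape)
        T = T + rng.uniform(-jitter, jitter, T.shape)
    pts = (center[None, :] + (R * np.cos(T)).reshape(-1, 1) * e1[None, :]
           + (R * np.sin(T)).reshape(-1, 1) * e2[None, :])
    return pts


def compute_pathlines(series: VelocitySeries, surface, t_start_ms: float,
                      t_end_ms: float, reseed_every_ms: float = 10.0,
                      dt_trace_ms: float | None = None, seed: int = 0,
                      inset_mm: float = 2.0):
    """PV-labeled pathlines seeded at the active PV port sections.

    Tracers are released at each active PV port plane (slightly inset into
    the tube) every ``reseed_every_ms`` between ``t_start_ms`` and
    ``t_end_ms`` and advected to ``t_end_ms``. Returns a list of
    ``(label, trajectory)`` with trajectory of shape (n_records, n_seeds, 3).
    """
    if dt_trace_ms is None:
        dt_ms = float(np.diff(series.times_ms).min())
        dt_trace_ms = min(2.5, dt_ms / 2.0)
    geom = surface.geometry
    rng = np.random.default_rng(seed)
    out = []
    release_times = np.arange(t_start_ms, t_end_ms - 1e-9, reseed_every_ms)
    pv_labels = [lab for lab in surface.active_ports if lab != "MV"]
    for t_release in release_times:
        # one batched advection per release across all veins
        seeds = []
        labels = []
        for lab in pv_labels:
            center, normal, area = geom.port_plane(lab, t_release)
            center = center - inset_mm * normal
            pts = _disk_seeds(center, normal, 0.75 * np.sqrt(area / np.pi),
                              rng=rng, jitter=0.05)
            seeds.append(pts)
            labels.extend([lab] * len(pts))
        tracers = TracerSet(np.concatenate(seeds), labels=np.asarray(labels))
        _, traj = advect_tracers(tracers, series, t_release, t_end_ms,
                                 dt_trace_ms, record_every=4)
        for lab in pv_labels:
            sel = tracers.labels == lab
            out.append((lab, traj[:, sel, :]))
    return out


@dataclass(frozen=True)
class PlaneSpec:
    """Sampling plane for FTLE maps."""

    center: tuple[float, float, float]
    normal: tuple[float, float, float]

    def basis(self):
        from .anatomy import _orthonormal_basis

        n = np.asarray(self.normal, dtype=float)
        n = n / np.linalg.norm(n)
        e1, e2 = _orthonormal_basis(n)
        return np.asarray(self.center, dtype=float), n, e1, e2


@dataclass
class FTLEField:
    """Scalar FTLE map (1/s) on a plane seed grid."""

    values: np.ndarray          # (M, M), NaN where indeterminate
    seeds: np.ndarray           # (M, M, 3) mm
    tau_ms: float
    t0_ms: float
    plane: PlaneSpec
    valid: np.ndarray = None    # (M, M) bool

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.isfinite(self.values)


def backward_ftle(series: VelocitySeries, plane: PlaneSpec, t0_ms: float,
                  tau_ms: float = -50.0, delta_mm: float = 1.0,
                  half_extent_mm: float = 40.0,
                  dt_trace_ms: float | None = None) -> FTLEField:
    """FTLE of the flow map over [t0, t0+tau] on a plane seed grid.

    Negative ``tau_ms`` gives the backward FTLE (attracting structures).
    Seeds outside the fluid (when the series carries a domain) and seeds
    whose finite-difference neighbors terminated are flagged invalid (NaN).
    """
    if tau_ms == 0:
        raise ValueError("tau must be nonzero")
    if dt_trace_ms is None:
        dt_ms = float(np.diff(series.times_ms).min())
        dt_trace_ms = min(1.0, dt_ms / 4.0)
    center, n, e1, e2 = plane.basis()
    m = int(2 * half_extent_mm / delta_mm) + 1
    a = np.linspace(-half_extent_mm, half_extent_mm, m)
    A, B = np.meshgrid(a, a, indexing="ij")
    seeds = (center[None, None, :] + A[..., None] * e1[None, None, :]
             + B[..., None] * e2[None, None, :])
    flat = seeds.reshape(-1, 3)
    in_fluid = np.ones(len(flat), dtype=bool)
    if series.sdf_fn is not None:
        in_fluid = series.sdf_fn(flat, t0_ms) < 0.0
    tracers = TracerSet(flat, labels=np.arange(len(flat)))
    tracers.status[~in_fluid] = STATUS_WALL
    tracers, _ = advect_tracers(tracers, series, t0_ms, t0_ms + tau_ms,
                                dt_trace_ms, record_every=10 ** 9)
    mapped = tracers.positions.reshape(m, m, 3)
    ok = (tracers.status == STATUS_ACTIVE).reshape(m, m) & in_fluid.reshape(m, m)

    values = np.full((m, m), np.nan)
    tau_s = abs(tau_ms) * 1e-3
    # central differences of the mapped positions along the two seed axes;
    # sigma_max of the 3x2 deformation gradient from the 2x2 right
    # Cauchy-Green tensor in closed form
    da = (mapped[2:, 1:-1] - mapped[:-2, 1:-1]) / (2.0 * delta_mm)
    db = (mapped[1:-1, 2:] - mapped[1:-1, :-2]) / (2.0 * delta_mm)
    c11 = np.einsum("ijk,ijk->ij", da, da)
    c22 = np.einsum("ijk,ijk->ij", db, db)
    c12 = np.einsum("ijk,ijk->ij", da, db)
    tr = c11 + c22
    disc = np.sqrt(np.maximum((c11 - c22) ** 2 + 4.0 * c12 ** 2, 0.0))
    lam_max = 0.5 * (tr + disc)
    interior_ok = (ok[1:-1, 1:-1] & ok[2:, 1:-1] & ok[:-2, 1:-1]
                   & ok[1:-1, 2:] & ok[1:-1, :-2])
    vals = 0.5 * np.log(np.maximum(lam_max, 1e-300)) / tau_s
    values[1:-1, 1:-1] = np.where(interior_ok, vals, np.nan)
    return FTLEField(values=values, seeds=seeds, tau_ms=tau_ms, t0_ms=t0_ms,
                     plane=plane)
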