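"""Idealized moving left-atrium geometries.

The synthetic anatomy is an ellipsoidal chamber with cylindrical
boundary-extension tubes stitched on for the four pulmonary veins (PVs) and
the mitral valve (MV). Wall motion is volume-driven: the chamber scales
uniformly about its centroid so that the enclosed mesh volume tracks a
prescribed periodic LA volume curve, while the tubes translate rigidly with
their attachment points. The per-phase scale factor is interpolated in time
by a Fourier series, which makes every vertex position an exact Fourier
series in time as well (positions are affine in the scale factor).

Each built surface carries an *analytic twin* (:class:`AnalyticLA`): the
exact implicit representation (ellipsoid + capped cylinders driven by the
same scale series). The flow solver evaluates signed distances and wall
velocities from the twin, which is mathematically consistent with the mesh
by construction and cheap enough to rebuild every time step.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.optimize import brentq

from . import fourier
from .config import (
    PV_LABELS,
    MV_LABEL,
    AnatomyConfig,
    GeometryConflictError,
    ResectionSpec,
    TubeSpec,
)

__all__ = [
    "MovingSurface",
    "AnalyticLA",
    "AnalyticTube",
    "build_idealized_la",
    "virtual_resect",
    "fit_fourier_displacement",
    "evaluate_volume",
    "enclosed_volume",
]


# ---------------------------------------------------------------------------
# small geometry helpers
# ---------------------------------------------------------------------------

def _orthonormal_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane orthogonal to d."""
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def enclosed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Volume enclosed by a closed, consistently oriented triangle mesh."""
    v0 = vertices[faces[:, 0]]
    v1 = vertices[faces[:, 1]]
    v2 = vertices[faces[:, 2]]
    return abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum()) / 6.0


def _polygon_radius(r: float, n: int) -> float:
    """Radius of a regular n-gon whose area equals the disk of radius r."""
    return r * np.sqrt(2.0 * np.pi / (n * np.sin(2.0 * np.pi / n)))


def _segment_distance(p1, d1, l1, p2, d2, l2) -> float:
    """Minimum distance between two line segments p + t*d, t in [0, l]."""
    # dense sampling is robust and cheap at build time
    t1 = np.linspace(0.0, l1, 64)
    t2 = np.linspace(0.0, l2, 64)
    a = p1[None, :] + t1[:, None] * d1[None, :]
    b = p2[None, :] + t2[:, None] * d2[None, :]
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


# ---------------------------------------------------------------------------
# analytic twin
# ---------------------------------------------------------------------------

@dataclass
class AnalyticTube:
    """Capped-cylinder implicit primitive for one extension tube."""

    label: str
    role: str                      # "PV" or "MV"
    direction: np.ndarray          # unit vector, chamber centroid -> outside
    radius_mm: float
    attach_mm: float               # axial distance centroid -> attachment at s=1
    length_mm: float               # fluid length beyond the attachment point
    embed_mm: float                # how deep the cylinder reaches into the chamber
    resected: bool = False

    @property
    def area_mm2(self) -> float:
        return float(np.pi * self.radius_mm ** 2)

    def axial_radial(self, points: np.ndarray, s: float):
        """Axial coordinate (from the *moving* attachment point) and radius."""
        base = (s * self.attach_mm) * self.direction
        rel = points - base
        y = rel @ self.direction
        rho = np.linalg.norm(rel - y[:, None] * self.direction[None, :], axis=1)
        return y, rho

    def sdf(self, points: np.ndarray, s: float) -> np.ndarray:
        """Exact signed distance of the finite (capped) cylinder."""
        y, rho = self.axial_radial(points, s)
        # cylinder spans axial [-embed, length]
        dx = rho - self.radius_mm
        dy = np.maximum(-(y + self.embed_mm), y - self.length_mm)
        inside = np.minimum(np.maximum(dx, dy), 0.0)
        outside = np.hypot(np.maximum(dx, 0.0), np.maximum(dy, 0.0))
        return inside + outside


@dataclass
class AnalyticLA:
    """Implicit moving geometry: ellipsoid chamber + capped-cylinder tubes.

    The scale series ``scale_coeffs`` (Fourier layout of :mod:`laflow.fourier`,
    period ``period_ms``) drives the chamber scale factor s(t); tube i
    translates by ``(s - 1) * attach_mm`` along its axis.
    """

    semi_axes: np.ndarray
    scale_coeffs: np.ndarray
    period_ms: float
    tubes: list[AnalyticTube] = field(default_factory=list)
    chamber_ref_volume_mm3: float = 0.0   # mesh chamber volume at s = 1

    def scale(self, t_ms: float) -> float:
        return float(fourier.evaluate(self.scale_coeffs, t_ms, self.period_ms))

    def scale_rate(self, t_ms: float) -> float:
        """ds/dt in 1/ms."""
        d = fourier.derivative(self.scale_coeffs, self.period_ms)
        return float(fourier.evaluate(d, t_ms, self.period_ms))

    def chamber_sdf(self, points: np.ndarray, s: float) -> np.ndarray:
        axes = s * self.semi_axes
        q = points / axes
        f = np.linalg.norm(q, axis=1)
        grad = np.linalg.norm(points / axes ** 2, axis=1)
        d = np.empty_like(f)
        near = f > 1e-9
        d[near] = (f[near] - 1.0) * f[near] / np.maximum(grad[near], 1e-30)
        d[~near] = -float(axes.min())
        return d

    def member_sdfs(self, points: np.ndarray, t_ms: float) -> np.ndarray:
        """(n_members, n_points) distances: chamber first, then tubes."""
        s = self.scale(t_ms)
        out = [self.chamber_sdf(points, s)]
        for tube in self.tubes:
            out.append(tube.sdf(points, s))
        return np.asarray(out)

    def sdf(self, points: np.ndarray, t_ms: float) -> np.ndarray:
        """Signed distance of the fluid domain (negative inside)."""
        return self.member_sdfs(points, t_ms).min(axis=0)

    def wall_velocity(self, points: np.ndarray, t_ms: float,
                      mv_normal_speed: float = 0.0,
                      mv_band_mm: float = 0.0) -> np.ndarray:
        """Prescribed wall velocity (mm/ms) at arbitrary points.

        The velocity of the nearest boundary feature: chamber points move
        radially with the scale rate, tube points translate rigidly with
        their attachment. When the mitral valve is open, points near the MV
        outlet plane (within ``mv_band_mm`` of the tube end) carry the
        uniform outlet speed ``mv_normal_speed`` (mm/ms, positive out of the
        LA) instead, which realizes the uniform-velocity MV boundary.
        """
        s = self.scale(t_ms)
        sd = self.member_sdfs(points, t_ms)
        owner = sd.argmin(axis=0)
        sr = self.scale_rate(t_ms)
        vel = np.zeros_like(points)
        chamber = owner == 0
        vel[chamber] = (sr / s) * points[chamber]
        for i, tube in enumerate(self.tubes):
            sel = owner == i + 1
            if not np.any(sel):
                continue
            vel[sel] = (sr * tube.attach_mm) * tube.direction[None, :]
            if tube.role == "MV" and mv_band_mm > 0.0 and mv_normal_speed != 0.0:
                y, _ = tube.axial_radial(points[sel], s)
                piston = y > tube.length_mm - mv_band_mm
                idx = np.flatnonzero(sel)[piston]
                vel[idx] = mv_normal_speed * tube.direction[None, :]
        return vel

    def chamber_volume_rate(self, t_ms: float) -> float:
        """d/dt of the chamber volume, mm^3/ms."""
        s = self.scale(t_ms)
        return 3.0 * self.chamber_ref_volume_mm3 * s ** 2 * self.scale_rate(t_ms)

    def tube(self, label: str) -> AnalyticTube:
        for tube in self.tubes:
            if tube.label == label:
                return tube
        raise KeyError(label)

    def port_plane(self, label: str, t_ms: float):
        """(center, outward normal, area) of a port plane at time t."""
        tube = self.tube(label)
        s = self.scale(t_ms)
        center = (s * tube.attach_mm + tube.length_mm) * tube.direction
        return center, tube.direction.copy(), tube.area_mm2

    def bounds(self, margin_mm: float = 0.0) -> np.ndarray:
        """Axis-aligned bounds covering the geometry at all phases."""
        tt = np.linspace(0.0, self.period_ms, 64, endpoint=False)
        smax = max(self.scale(t) for t in tt)
        lo = -smax * self.semi_axes - margin_mm
        hi = smax * self.semi_axes + margin_mm
        for tube in self.tubes:
            end = (smax * tube.attach_mm + tube.length_mm) * tube.direction
            lo = np.minimum(lo, end - tube.radius_mm - margin_mm)
            hi = np.maximum(hi, end + tube.radius_mm + margin_mm)
        return np.array([lo, hi])


# ---------------------------------------------------------------------------
# moving triangulated surface
# ---------------------------------------------------------------------------

class MovingSurface:
    """Closed triangulated LA surface with a Fourier-in-time vertex model.

    Attributes
    ----------
    vertices_ref : (V, 3) float — vertex positions (mm) at phase 0.
    faces : (F, 3) int — outward-oriented triangles.
    position_coeffs : (V, 3, 2K+1) float — per-vertex Fourier model of the
        absolute position x(t), period ``period_ms``.
    port_tags : dict label -> int array of cap-face indices. Resected stump
        caps are tagged ``"stump_<vein>"`` and are not active ports.
    geometry : AnalyticLA or None — analytic twin (idealized builds only).
    """

    def __init__(self, vertices_ref, faces, position_coeffs, period_ms,
                 port_tags=None, geometry=None, config=None,
                 vertex_group=None):
        self.vertices_ref = np.asarray(vertices_ref, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.position_coeffs = np.asarray(position_coeffs, dtype=float)
        self.period_ms = float(period_ms)
        self.port_tags = {} if port_tags is None else dict(port_tags)
        self.geometry = geometry
        self.config = config
        self.vertex_group = vertex_group

    # -- evaluation ---------------------------------------------------------
    def vertices_at(self, t_ms: float) -> np.ndarray:
        return fourier.evaluate(self.position_coeffs, float(t_ms), self.period_ms)

    def velocity_coeffs(self) -> np.ndarray:
        return fourier.derivative(self.position_coeffs, self.period_ms)

    def vertex_velocity_at(self, t_ms: float) -> np.ndarray:
        """Vertex velocities in mm/ms."""
        return fourier.evaluate(self.velocity_coeffs(), float(t_ms), self.period_ms)

    def mesh_at(self, t_ms: float) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices_at(t_ms), self.faces, process=False)

    def volume_at(self, t_ms: float) -> float:
        return enclosed_volume(self.vertices_at(t_ms), self.faces)

    @property
    def active_ports(self) -> list[str]:
        return [k for k in self.port_tags if not k.startswith("stump_")]

    def port_plane(self, label: str, t_ms: float = 0.0):
        """(center, outward unit normal, area) of a tagged planar port cap."""
        f = self.port_tags[label]
        verts = self.vertices_at(t_ms)
        tri = verts[self.faces[f]]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        area = 0.5 * np.linalg.norm(n.sum(axis=0))
        normal = n.sum(axis=0)
        normal /= np.linalg.norm(normal)
        center = tri.reshape(-1, 3).mean(axis=0)
        return center, normal, float(area)

    # -- checks -------------------------------------------------------------
    def is_watertight(self) -> bool:
        return self.mesh_at(0.0).is_watertight

    # -- I/O ----------------------------------------------------------------
    def export(self, basepath, phases: int | None = None, fmt: str = "stl") -> list[str]:
        """Write one surface file per phase plus a sidecar JSON.

        Returns the list of files written.
        """
        basepath = str(basepath)
        n = phases if phases is not None else (
            self.config.n_phases if self.config is not None else 20)
        written = []
        for j in range(n):
            t = j * self.period_ms / n
            path = f"{basepath}_phase{j:02d}.{fmt}"
            self.mesh_at(t).export(path)
            written.append(path)
        sidecar = {
            "period_ms": self.period_ms,
            "n_phases": n,
            "port_tags": {k: np.asarray(v).tolist() for k, v in self.port_tags.items()},
            "port_planes": {
                k: {"center": list(map(float, c)), "normal": list(map(float, nrm)),
                    "area_mm2": a}
                for k, (c, nrm, a) in
                ((k, self.port_plane(k)) for k in self.port_tags)
            },
            "position_coeffs_shape": list(self.position_coeffs.shape),
        }
        jpath = f"{basepath}_ports.json"
        with open(jpath, "w") as fjs:
            json.dump(sidecar, fjs, indent=1)
        written.append(jpath)
        return written


# ---------------------------------------------------------------------------
# standalone Fourier operations (spec-level API)
# ---------------------------------------------------------------------------

def evaluate_volume(coeffs, t_ms, period_ms: float) -> float:
    """Evaluate a Fourier volume curve (mL) at time t (ms); T-periodic."""
    if period_ms <= 0:
        raise ValueError("period must be positive")
    return fourier.evaluate(np.asarray(coeffs, dtype=float), t_ms, period_ms)


def fit_fourier_displacement(phase_positions: np.ndarray, period_ms: float,
                             order: int) -> np.ndarray:
    """Least-squares Fourier model of per-vertex motion.

    Parameters
    ----------
    phase_positions : (n_phases, V, 3) vertex positions at uniformly spaced
        phase times ``j * T / n_phases``.

    Returns
    -------
    (V, 3, 2*order+1) coefficient array (see :mod:`laflow.fourier`).
    """
    pos = np.asarray(phase_positions, dtype=float)
    n = pos.shape[0]
    t = np.arange(n) * period_ms / n
    return fourier.fit(t, pos, period_ms, order)


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def _zip_loops(loop_idx, loop_ang, ring_idx, ring_ang):
    """Triangulate the band between two closed vertex loops by angle merge."""
    nl, nr = len(loop_idx), len(ring_idx)
    order_l = np.argsort(loop_ang)
    order_r = np.argsort(ring_ang)
    la = np.asarray(loop_ang)[order_l]
    ra = np.asarray(ring_ang)[order_r]
    li = np.asarray(loop_idx)[order_l]
    ri = np.asarray(ring_idx)[order_r]
    faces = []
    i = j = 0
    while i < nl or j < nr:
        next_l = la[(i + 1) % nl] + (2 * np.pi if i + 1 >= nl else 0.0)
        next_r = ra[(j + 1) % nr] + (2 * np.pi if j + 1 >= nr else 0.0)
        if i < nl and (j >= nr or next_l <= next_r):
            faces.append((li[i % nl], li[(i + 1) % nl], ri[j % nr]))
            i += 1
        else:
            faces.append((ri[(j + 1) % nr], ri[j % nr], li[i % nl]))
            j += 1
    return faces


def _boundary_loop(faces: np.ndarray) -> np.ndarray:
    """Vertices of the single open boundary loop of a triangle soup."""
    edges = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    if len(boundary) == 0:
        raise GeometryConflictError("tube attachment produced no open boundary")
    verts = np.unique(boundary)
    return verts, boundary


@dataclass
class _TubeBuild:
    spec: TubeSpec
    role: str
    attach_mm: float


def _append_tube(verts: list, faces: list, tags: list, groups: list, tube: TubeSpec,
                 semi_axes: np.ndarray, n_sides: int, group_id: int,
                 stump_depth: float | None = None):
    """Remove a chamber patch and stitch on one tube; mutates verts/faces.

    ``verts``/``groups`` are python lists of arrays (appended to); ``faces``
    is a python list of index triples and ``tags`` a parallel list of face
    tags (0 = untagged, ``group_id`` = this tube's cap). Chamber faces must
    already be present. Returns a :class:`_TubeBuild` record.
    """
    d = np.asarray(tube.direction, dtype=float)
    e1, e2 = _orthonormal_basis(d)
    r = _polygon_radius(tube.radius_mm, n_sides)
    attach = 1.0 / np.sqrt(((d / semi_axes) ** 2).sum())

    V = np.asarray(verts[0]) if len(verts) == 1 else np.concatenate(verts)
    axial = V @ d
    perp = np.linalg.norm(V - axial[:, None] * d[None, :], axis=1)
    in_hole = (axial > 0.25 * attach) & (perp < r)
    if in_hole.sum() < 3:
        raise GeometryConflictError(
            f"{tube.label}: chamber mesh too coarse for tube radius {r:.1f} mm")

    F = np.asarray(faces, dtype=np.int64)
    remove = in_hole[F].any(axis=1)
    kept = F[~remove]
    removed = F[remove]
    # boundary loop = edges of removed patch still used by kept faces
    loop_verts, _ = _boundary_loop(removed)
    # restrict to vertices still referenced by kept faces (safety)
    used = np.zeros(len(V), dtype=bool)
    used[kept.ravel()] = True
    loop_verts = loop_verts[used[loop_verts]]
    ang_loop = np.arctan2((V[loop_verts] @ e2), (V[loop_verts] @ e1))

    kept_tags = np.asarray(tags)[~remove]
    if np.any(np.asarray(tags)[remove] != 0):
        raise GeometryConflictError(
            f"{tube.label}: attachment would cut into another tube's cap")
    faces[:] = [tuple(f) for f in kept]
    tags[:] = kept_tags.tolist()

    def push(face, tag=0):
        faces.append(face)
        tags.append(tag)

    theta = 2.0 * np.pi * np.arange(n_sides) / n_sides
    circle = np.cos(theta)[:, None] * e1[None, :] + np.sin(theta)[:, None] * e2[None, :]

    def add_ring(axial_pos, radius):
        start = sum(len(a) for a in verts)
        ring = axial_pos * d[None, :] + radius * circle
        verts.append(ring)
        groups.append(np.full(n_sides, group_id))
        return np.arange(start, start + n_sides)

    length = stump_depth if stump_depth is not None else tube.resolved_length_mm()
    if stump_depth is not None and stump_depth > tube.resolved_length_mm():
        raise ValueError(
            f"{tube.label}: stump depth {stump_depth} mm exceeds tube length "
            f"{tube.resolved_length_mm():.1f} mm")

    # rings along the tube, ~2.5 mm axial spacing
    n_seg = max(2, int(np.ceil(length / 2.5)))
    stations = np.linspace(attach, attach + length, n_seg + 1)
    rings = [add_ring(a, r) for a in stations]

    for face in _zip_loops(loop_verts, ang_loop, rings[0], theta):
        push(face)
    for ra, rb in zip(rings[:-1], rings[1:]):
        for m in range(n_sides):
            m2 = (m + 1) % n_sides
            push((ra[m], ra[m2], rb[m2]))
            push((ra[m], rb[m2], rb[m]))

    if stump_depth is None:
        # flat planar cap: center fan
        cidx = sum(len(a) for a in verts)
        verts.append(((attach + length) * d)[None, :])
        groups.append(np.array([group_id]))
        last = rings[-1]
        for m in range(n_sides):
            push((last[m], last[(m + 1) % n_sides], cidx), tag=group_id)
    else:
        # smooth bulged cap: quarter-ellipse profile of height 0.1 r, which
        # meets the cylinder wall tangentially (no sharp ridge)
        h_cap = 0.1 * r
        n_cap = 20
        last = rings[-1]
        psi = np.linspace(0.0, np.pi / 2.0, n_cap + 1)[1:]
        for p in psi[:-1]:
            ring = add_ring(attach + length + h_cap * np.sin(p), r * np.cos(p))
            for m in range(n_sides):
                m2 = (m + 1) % n_sides
                push((last[m], last[m2], ring[m2]), tag=group_id)
                push((last[m], ring[m2], ring[m]), tag=group_id)
            last = ring
        cidx = sum(len(a) for a in verts)
        verts.append(((attach + length + h_cap) * d)[None, :])
        groups.append(np.array([group_id]))
        for m in range(n_sides):
            push((last[m], last[(m + 1) % n_sides], cidx), tag=group_id)

    return _TubeBuild(spec=tube, role="MV" if tube.label == MV_LABEL else "PV",
                      attach_mm=attach)


def _check_clearances(config: AnatomyConfig, resection: ResectionSpec | None = None):
    axes = np.asarray(config.chamber_semi_axes)
    tubes = config.all_tubes
    infos = []
    for t in tubes:
        d = np.asarray(t.direction)
        attach = 1.0 / np.sqrt(((d / axes) ** 2).sum())
        infos.append((np.asarray(t.direction) * attach, np.asarray(t.direction),
                      t.resolved_length_mm(), t.radius_mm, t.label))
        if t.radius_mm > 0.6 * axes.min():
            raise GeometryConflictError(
                f"{t.label}: tube radius {t.radius_mm:.1f} mm too large for chamber")
    for i in range(len(infos)):
        for j in range(i + 1, len(infos)):
            p1, d1, l1, r1, lab1 = infos[i]
            p2, d2, l2, r2, lab2 = infos[j]
            dist = _segment_distance(p1, d1, l1, p2, d2, l2)
            if dist < r1 + r2 + 1.0:
                raise GeometryConflictError(
                    f"tubes {lab1} and {lab2} would intersect "
                    f"(axis distance {dist:.1f} mm < {r1 + r2 + 1.0:.1f} mm)")


def _solve_scale_series(config: AnatomyConfig, verts_ref: np.ndarray,
                        faces: np.ndarray, group: np.ndarray,
                        attach_by_group: dict[int, tuple[np.ndarray, float]]):
    """Per-phase chamber scale factors matching the LA volume curve."""

    def positions(s: float) -> np.ndarray:
        out = verts_ref * 1.0
        chamber = group == 0
        out[chamber] = s * verts_ref[chamber]
        for gid, (d, attach) in attach_by_group.items():
            sel = group == gid
            out[sel] = verts_ref[sel] + (s - 1.0) * attach * d[None, :]
        return out

    times = config.phase_times()
    targets_mm3 = config.la_volume(times) * 1000.0  # mL -> mm^3
    if np.any(targets_mm3 <= 0):
        raise ValueError("LA volume curve must be positive")
    scales = np.empty(len(times))
    for j, v in enumerate(targets_mm3):
        g = lambda s: enclosed_volume(positions(s), faces) - v
        try:
            scales[j] = brentq(g, 0.2, 3.0, xtol=1e-12)
        except ValueError as exc:
            raise ValueError(
                f"LA volume {v / 1000.0:.1f} mL at phase {j} is unreachable by "
                f"chamber scaling (tube volume too large or curve too extreme)"
            ) from exc
    return times, scales, positions


def build_idealized_la(config: AnatomyConfig) -> MovingSurface:
    """Build the idealized moving LA surface described by ``config``.

    The chamber is an icosphere scaled to the configured ellipsoid semi-axes;
    tubes are stitched on with a funnel blend at their attachment; the
    per-phase chamber scale factor is solved so that the enclosed mesh volume
    matches the LA volume curve at every phase, and interpolated in time by a
    Fourier series of order ``config.fourier_order``.
    """
    _check_clearances(config)
    axes = np.asarray(config.chamber_semi_axes, dtype=float)
    sphere = trimesh.creation.icosphere(subdivisions=config.mesh_subdivisions, radius=1.0)
    verts = [np.asarray(sphere.vertices) * axes[None, :]]
    faces = [tuple(f) for f in np.asarray(sphere.faces)]
    tags = [0] * len(faces)
    groups = [np.zeros(len(sphere.vertices), dtype=int)]

    builds: list[_TubeBuild] = []
    for gid, tube in enumerate(config.all_tubes, start=1):
        builds.append(_append_tube(verts, faces, tags, groups, tube, axes,
                                   config.tube_sides, gid))

    V = np.concatenate(verts)
    F = np.asarray(faces, dtype=np.int64)
    tag_arr = np.asarray(tags)
    group = np.concatenate(groups)

    mesh = trimesh.Trimesh(V, F, process=False)
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise GeometryConflictError("stitched surface is not watertight")
    F = np.asarray(mesh.faces)

    attach_by_group = {
        gid: (np.asarray(b.spec.direction, dtype=float), b.attach_mm)
        for gid, b in enumerate(builds, start=1)
    }
    times, scales, positions = _solve_scale_series(config, V, F, group, attach_by_group)

    # Fourier scale series; vertex positions are affine in s, so composing
    # with the per-vertex affine map gives the exact least-squares fit of the
    # per-vertex phase positions.
    scale_coeffs = fourier.fit(times, scales, config.period_ms, config.fourier_order)
    nc = fourier.n_coeffs(config.fourier_order)
    const = np.zeros((len(V), 3))
    slope = np.zeros((len(V), 3))
    chamber = group == 0
    slope[chamber] = V[chamber]
    for gid, (d, attach) in attach_by_group.items():
        sel = group == gid
        const[sel] = V[sel] - attach * d[None, :]
        slope[sel] = np.broadcast_to(attach * d, (sel.sum(), 3))
    coeffs = slope[:, :, None] * scale_coeffs[None, None, :]
    coeffs[:, :, 0] += const

    port_tags = {
        b.spec.label: np.flatnonzero(tag_arr == gid)
        for gid, b in enumerate(builds, start=1)
    }

    chamber_only = trimesh.creation.icosphere(
        subdivisions=config.mesh_subdivisions, radius=1.0)
    chamber_vol = enclosed_volume(
        np.asarray(chamber_only.vertices) * axes[None, :], np.asarray(chamber_only.faces))

    geometry = AnalyticLA(
        semi_axes=axes,
        scale_coeffs=scale_coeffs,
        period_ms=config.period_ms,
        tubes=[
            AnalyticTube(
                label=b.spec.label, role=b.role,
                direction=np.asarray(b.spec.direction, dtype=float),
                radius_mm=b.spec.radius_mm, attach_mm=b.attach_mm,
                length_mm=b.spec.resolved_length_mm(),
                embed_mm=0.35 * b.attach_mm)
            for b in builds
        ],
        chamber_ref_volume_mm3=chamber_vol,
    )

    ref = fourier.evaluate(coeffs, 0.0, config.period_ms)
    return MovingSurface(ref, F, coeffs, config.period_ms, port_tags=port_tags,
                         geometry=geometry, config=config, vertex_group=group)


def virtual_resect(surface: MovingSurface, spec: ResectionSpec) -> MovingSurface:
    """Cut one PV at ``stump_depth`` from the LA body and cap it smoothly.

    The resected surface is rebuilt from the stored anatomy configuration
    with the named tube shortened and closed by a tangent, bulged cap; the
    chamber scale series (and therefore the wall motion of every unrelated
    vertex) is copied from the input, so the only geometric change between
    the two surfaces is the resected vein. Passing ``vein="NONE"`` returns
    the input unchanged.
    """
    if spec.vein == "NONE":
        return surface
    if spec.vein not in surface.port_tags:
        raise ValueError(f"{spec.vein} is not a tagged port of this surface")
    if surface.config is None or surface.geometry is None:
        raise ValueError("virtual_resect requires an idealized (built) surface")
    config = surface.config
    tube_spec = next(s for s in config.pv_specs if s.label == spec.vein)
    if spec.stump_depth_mm > tube_spec.resolved_length_mm():
        raise ValueError(
            f"stump depth {spec.stump_depth_mm} mm exceeds {spec.vein} tube length")

    axes = np.asarray(config.chamber_semi_axes, dtype=float)
    sphere = trimesh.creation.icosphere(subdivisions=config.mesh_subdivisions, radius=1.0)
    verts = [np.asarray(sphere.vertices) * axes[None, :]]
    faces = [tuple(f) for f in np.asarray(sphere.faces)]
    tags = [0] * len(faces)
    groups = [np.zeros(len(sphere.vertices), dtype=int)]

    builds = []
    for gid, tube in enumerate(config.all_tubes, start=1):
        depth = spec.stump_depth_mm if tube.label == spec.vein else None
        builds.append(_append_tube(verts, faces, tags, groups, tube, axes,
                                   config.tube_sides, gid, stump_depth=depth))

    V = np.concatenate(verts)
    F = np.asarray(faces, dtype=np.int64)
    tag_arr = np.asarray(tags)
    group = np.concatenate(groups)
    mesh = trimesh.Trimesh(V, F, process=False)
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise GeometryConflictError("resected surface is not watertight")
    F = np.asarray(mesh.faces)

    scale_coeffs = surface.geometry.scale_coeffs
    const = np.zeros((len(V), 3))
    slope = np.zeros((len(V), 3))
    chamber = group == 0
    slope[chamber] = V[chamber]
    for gid, b in enumerate(builds, start=1):
        sel = group == gid
        d = np.asarray(b.spec.direction, dtype=float)
        const[sel] = V[sel] - b.attach_mm * d[None, :]
        slope[sel] = np.broadcast_to(b.attach_mm * d, (sel.sum(), 3))
    coeffs = slope[:, :, None] * scale_coeffs[None, None, :]
    coeffs[:, :, 0] += const

    port_tags = {}
    for gid, b in enumerate(builds, start=1):
        key = f"stump_{spec.vein}" if b.spec.label == spec.vein else b.spec.label
        port_tags[key] = np.flatnonzero(tag_arr == gid)

    geometry = copy.deepcopy(surface.geometry)
    gt = geometry.tube(spec.vein)
    gt.resected = True
    # bulged cap adds ~half its height of axial extent on average
    gt.length_mm = spec.stump_depth_mm + 0.05 * tube_spec.radius_mm

    ref = fourier.evaluate(coeffs, 0.0, config.period_ms)
    return MovingSurface(ref, F, coeffs, config.period_ms, port_tags=port_tags,
                         geometry=geometry, config=config, vertex_group=group)
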