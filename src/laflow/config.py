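"""Configuration types for the idealized left-atrium (LA) pipeline.

Units follow clinical/imaging convention at the API surface: lengths in mm,
areas in mm^2, times in ms, volumes in mL. The flow solver converts to SI
internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from . import fourier

PV_LABELS = ("LSPV", "LIPV", "RSPV", "RIPV")
MV_LABEL = "MV"

#: Cardiac period (ms) and PV cross-sectional areas (mm^2) of the four
#: bundled synthetic subjects, ordered (LSPV, LIPV, RSPV, RIPV). Subjects
#: 1-3 are left-dominant (LSPV among the largest veins); in subject 4 the
#: LSPV is the smallest vein, which reverses the impact of its resection.
SUBJECT_TABLE = {
    1: dict(period_ms=870.0, areas=(211.0, 97.2, 194.0, 212.0)),
    2: dict(period_ms=920.0, areas=(271.0, 225.0, 271.0, 145.0)),
    3: dict(period_ms=1000.0, areas=(180.0, 116.0, 196.0, 145.0)),
    4: dict(period_ms=984.0, areas=(95.3, 171.0, 175.0, 135.0)),
}

# Attachment directions (unit vectors from the chamber centroid) chosen to
# reproduce the textbook asymmetric inflow arrangement: the left veins enter
# nearly horizontally and aim across the chamber toward the right wall, the
# right veins aim downward toward the inferior LA, and the mitral orifice
# faces antero-inferiorly. Axes: +x left->right, +y posterior->anterior,
# +z inferior->superior.
DEFAULT_PV_DIRECTIONS = {
    "LSPV": (-0.55, -0.40, 0.74),
    "LIPV": (-0.95, -0.29, -0.12),
    "RSPV": (0.52, -0.45, 0.73),
    "RIPV": (0.93, -0.35, -0.08),
}
DEFAULT_MV_DIRECTION = (0.10, 0.45, -0.89)


class GeometryConflictError(ValueError):
    """Raised when requested tubes would intersect each other or the chamber."""


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("direction vector must be nonzero")
    return v / n


@dataclass(frozen=True)
class TubeSpec:
    """Geometry of one cylindrical boundary-extension tube (a PV or the MV)."""

    label: str
    direction: tuple[float, float, float]
    area_mm2: float
    length_mm: float | None = None  # None -> role-dependent default

    def __post_init__(self):
        if self.area_mm2 <= 0:
            raise ValueError(f"{self.label}: area must be positive, got {self.area_mm2}")
        object.__setattr__(self, "direction", tuple(_unit(self.direction)))
        if self.length_mm is not None and self.length_mm <= 0:
            raise ValueError(f"{self.label}: tube length must be positive")

    @property
    def radius_mm(self) -> float:
        return float(np.sqrt(self.area_mm2 / np.pi))

    @property
    def diameter_mm(self) -> float:
        return 2.0 * self.radius_mm

    def resolved_length_mm(self) -> float:
        """Tube length beyond the chamber attachment.

        Default: 3 diameters for PVs (pushes the artificial pressure boundary
        away from the chamber), 1.2 diameters for the MV (which only hosts the
        prescribed-velocity outlet plane).
        """
        if self.length_mm is not None:
            return float(self.length_mm)
        factor = 1.2 if self.label == MV_LABEL else 3.0
        return factor * self.diameter_mm


def _keyframe_coeffs(frac_times, values, order):
    """Fit a Fourier series (period 1) through sketch keyframes."""
    t = np.asarray(frac_times, dtype=float)
    return fourier.fit(t, np.asarray(values, dtype=float), 1.0, order)


def default_la_volume_coeffs(mean_shift_ml: float = 0.0) -> np.ndarray:
    """LA total enclosed volume curve (mL) vs cardiac phase, 3 harmonics.

    Shape: rises through ventricular systole (reservoir filling) to a
    late-systolic maximum near 0.4T, empties in early diastole (conduit),
    plateaus at diastasis and empties again with the atrial kick, reaching
    its minimum at ventricular end-diastole (t = 0). The level includes the
    cylindrical extension tubes, hence is higher than an imaging LA volume.
    """
    t = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95]
    v = [128, 136, 146, 156, 162, 152, 140, 138, 141, 133, 128]
    return _keyframe_coeffs(t, np.asarray(v) + mean_shift_ml, 3)


def default_lv_volume_coeffs() -> np.ndarray:
    """LV volume curve (mL) vs cardiac phase, 4 harmonics.

    Ejection during 0-0.35T, E-wave filling 0.4-0.6T, diastasis, A-wave
    filling near end-diastole. Only its time derivative is used (it sets the
    mitral flow rate when positive).
    """
    t = [0.0, 0.08, 0.16, 0.25, 0.32, 0.38, 0.45, 0.52, 0.6, 0.7, 0.8, 0.88, 0.95]
    v = [120, 100, 75, 57, 50, 52, 68, 88, 99, 102, 103, 110, 118]
    return _keyframe_coeffs(t, v, 4)


@dataclass(frozen=True)
class AnatomyConfig:
    """Idealized moving LA: ellipsoidal chamber + four PV tubes + MV tube."""

    chamber_semi_axes: tuple[float, float, float] = (32.0, 27.0, 26.0)
    pv_specs: tuple[TubeSpec, ...] = ()
    mv_spec: TubeSpec | None = None
    period_ms: float = 870.0
    n_phases: int = 20
    la_volume_coeffs: tuple[float, ...] = ()
    lv_volume_coeffs: tuple[float, ...] = ()
    fourier_order: int = 9
    mesh_subdivisions: int = 4
    tube_sides: int = 48

    def __post_init__(self):
        if any(a <= 0 for a in self.chamber_semi_axes):
            raise ValueError("chamber semi-axes must be positive")
        if self.period_ms <= 0:
            raise ValueError("period must be positive")
        if self.n_phases < 4:
            raise ValueError("need at least 4 phases")
        labels = [s.label for s in self.pv_specs]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate PV labels")
        for s in self.pv_specs:
            if s.label not in PV_LABELS:
                raise ValueError(f"unknown PV label {s.label}")
        dirs = [np.asarray(s.direction) for s in self.pv_specs]
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                if np.allclose(dirs[i], dirs[j]):
                    raise ValueError("PV attachment directions must be pairwise distinct")
        object.__setattr__(
            self, "la_volume_coeffs", tuple(np.asarray(self.la_volume_coeffs, dtype=float))
        )
        object.__setattr__(
            self, "lv_volume_coeffs", tuple(np.asarray(self.lv_volume_coeffs, dtype=float))
        )
        if len(self.la_volume_coeffs) == 0:
            object.__setattr__(self, "la_volume_coeffs", tuple(default_la_volume_coeffs()))
        if len(self.lv_volume_coeffs) == 0:
            object.__setattr__(self, "lv_volume_coeffs", tuple(default_lv_volume_coeffs()))
        # Volume curves are stored vs phase fraction (period 1 in t/T).
        tt = np.linspace(0.0, 1.0, 257, endpoint=False)
        if np.any(self.la_volume(tt * self.period_ms) <= 0):
            raise ValueError("LA volume curve must be positive over the whole cycle")
        if np.any(self.lv_volume(tt * self.period_ms) <= 0):
            raise ValueError("LV volume curve must be positive over the whole cycle")

    # -- volume curve evaluation (t in ms, volumes in mL) -------------------
    def la_volume(self, t_ms):
        return fourier.evaluate(np.asarray(self.la_volume_coeffs), np.asarray(t_ms) / self.period_ms, 1.0)

    def lv_volume(self, t_ms):
        return fourier.evaluate(np.asarray(self.lv_volume_coeffs), np.asarray(t_ms) / self.period_ms, 1.0)

    def lv_volume_rate(self, t_ms):
        """dV_LV/dt in mL/ms."""
        d = fourier.derivative(np.asarray(self.lv_volume_coeffs), 1.0) / self.period_ms
        return fourier.evaluate(d, np.asarray(t_ms) / self.period_ms, 1.0)

    def phase_times(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.period_ms / self.n_phases

    @property
    def all_tubes(self) -> tuple[TubeSpec, ...]:
        tubes = tuple(self.pv_specs)
        if self.mv_spec is not None:
            tubes = tubes + (self.mv_spec,)
        return tubes

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "chamber_semi_axes": list(self.chamber_semi_axes),
            "period_ms": self.period_ms,
            "n_phases": self.n_phases,
            "fourier_order": self.fourier_order,
            "mesh_subdivisions": self.mesh_subdivisions,
            "tube_sides": self.tube_sides,
            "la_volume_coeffs": [float(c) for c in self.la_volume_coeffs],
            "lv_volume_coeffs": [float(c) for c in self.lv_volume_coeffs],
            "pv_specs": [
                {"label": s.label, "direction": [float(d) for d in s.direction],
                 "area_mm2": float(s.area_mm2),
                 "length_mm": None if s.length_mm is None else float(s.length_mm)}
                for s in self.pv_specs
            ],
            "mv_spec": None if self.mv_spec is None else {
                "label": self.mv_spec.label,
                "direction": [float(d) for d in self.mv_spec.direction],
                "area_mm2": float(self.mv_spec.area_mm2),
                "length_mm": (None if self.mv_spec.length_mm is None
                              else float(self.mv_spec.length_mm)),
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnatomyConfig":
        d = dict(d)
        d["chamber_semi_axes"] = tuple(d.get("chamber_semi_axes", (32.0, 27.0, 26.0)))
        d["pv_specs"] = tuple(TubeSpec(**s) for s in d.get("pv_specs", ()))
        mv = d.get("mv_spec")
        d["mv_spec"] = None if mv is None else TubeSpec(**mv)
        d["la_volume_coeffs"] = tuple(d.get("la_volume_coeffs", ()))
        d["lv_volume_coeffs"] = tuple(d.get("lv_volume_coeffs", ()))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnatomyConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)


def subject_config(subject: int, mv_area_mm2: float = 550.0) -> AnatomyConfig:
    """Bundled synthetic subject presets (cardiac period and PV areas)."""
    if subject not in SUBJECT_TABLE:
        raise ValueError(f"unknown subject {subject}; available: {sorted(SUBJECT_TABLE)}")
    row = SUBJECT_TABLE[subject]
    pv_specs = tuple(
        TubeSpec(label=lab, direction=DEFAULT_PV_DIRECTIONS[lab], area_mm2=a)
        for lab, a in zip(PV_LABELS, row["areas"])
    )
    mv = TubeSpec(label=MV_LABEL, direction=DEFAULT_MV_DIRECTION, area_mm2=mv_area_mm2)
    return AnatomyConfig(pv_specs=pv_specs, mv_spec=mv, period_ms=row["period_ms"])


@dataclass(frozen=True)
class ResectionSpec:
    """Virtual resection of one pulmonary vein, capped as a short stump."""

    vein: str = "NONE"
    stump_depth_mm: float = 5.0

    def __post_init__(self):
        if self.vein not in PV_LABELS + ("NONE",):
            raise ValueError(f"vein must be one of {PV_LABELS} or NONE, got {self.vein}")
        if self.stump_depth_mm < 0:
            raise ValueError("stump depth must be >= 0")


@dataclass(frozen=True)
class FluidProperties:
    """Blood as an incompressible Newtonian fluid."""

    density: float = 1.05e3  # kg/m^3
    viscosity: float = 3.5e-3  # Pa s (dynamic)

    def __post_init__(self):
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity, m^2/s."""
        return self.viscosity / self.density


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters for the immersed-boundary flow solver."""

    grid_n: int = 48                  # cells per direction (cube)
    cfl: float = 0.1
    poisson_rtol: float = 1e-7
    n_cycles: int = 3
    kappa: float = 5.0                # PV resistance scale, Pa s / mm (K_i = kappa / A_i)
    domain_margin_mm: float = 6.0     # clearance between anatomy and box
    snapshots_per_cycle: int = 20
    final_cycle_snapshot_dt_ms: float = 10.0
    mv_hysteresis_ms: float = 1.0
    bdim_epsilon_cells: float = 2.0
    max_poisson_iter: int = 2000

    def __post_init__(self):
        if not (0 < self.cfl < 1):
            raise ValueError("CFL must lie in (0, 1)")
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        if self.grid_n < 8:
            raise ValueError("grid too small")
        if self.kappa <= 0:
            raise ValueError("resistance scale must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SolverConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        from dataclasses import asdict
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=True)


@dataclass(frozen=True)
class CaseSpec:
    """One run of the five-case virtual-resection experiment."""

    subject: int
    resection: ResectionSpec
    solver: SolverConfig = SolverConfig()
    outdir: str | None = None
    seed: int = 0

    @property
    def name(self) -> str:
        r = self.resection.vein
        return f"subject{self.subject}_{'pre' if r == 'NONE' else 'R' + r}"


def five_case_specs(subject: int, solver: SolverConfig | None = None,
                    outdir: str | None = None, seed: int = 0) -> list[CaseSpec]:
    """The pre-resection case plus the four single-PV resections."""
    solver = solver or SolverConfig()
    veins = ("NONE",) + PV_LABELS
    return [
        CaseSpec(subject=subject, resection=ResectionSpec(vein=v),
                 solver=solver, outdir=outdir, seed=seed)
        for v in veins
    ]
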