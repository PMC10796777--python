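"""Five-case virtual-resection experiment orchestration.

For one synthetic subject the experiment runs the pre-resection anatomy and
the four single-PV resections with an otherwise identical configuration,
then compares peak-systolic energetics and per-vein inflow across cases.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .anatomy import build_idealized_la, virtual_resect
from .config import (AnatomyConfig, CaseSpec, FluidProperties, PV_LABELS,
                     ResectionSpec, SolverConfig, five_case_specs,
                     subject_config)
from .energetics import EnergeticsSeries, energetics_timeseries
from .lagrangian import PlaneSpec, VelocitySeries, backward_ftle, compute_pathlines
from .solver import SimulationResult, run_simulation

__all__ = ["CaseBundle", "run_case", "compare_cases", "run_five_cases"]

CSV_FLOAT_FMT = "%.12g"


@dataclass
class CaseBundle:
    """All artifacts of one case run."""

    spec: CaseSpec
    anatomy: AnatomyConfig
    result: SimulationResult
    energetics: EnergeticsSeries
    ftle: dict = field(default_factory=dict)          # t0_ms -> FTLEField
    pathlines: list = field(default_factory=list)     # (label, trajectory)
    manifest: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.spec.name

    def port_series(self) -> pd.DataFrame:
        return self.result.port_series()

    def final_port_series(self) -> pd.DataFrame:
        df = self.result.port_series()
        return df[df.t_ms >= self.result.final_cycle_start_ms - 1e-6]

    def mean_pv_inflow_speed(self) -> dict:
        """Cycle-mean inflow speed (mm/s) per active PV over the final cycle."""
        df = self.final_port_series()
        out = {}
        for label, grp in df[df.role == "PV"].groupby("label"):
            t = grp.t_ms.values
            q = grp.Q_mm3_s.values
            area = next(tube.area_mm2 for tube in self.result.surface.geometry.tubes
                        if tube.label == label)
            out[label] = float(np.trapezoid(q, t) / (t[-1] - t[0]) / area)
        return out


def _config_hash(*parts) -> str:
    blob = json.dumps(parts, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def upper_la_plane(surface, t_ms: float = 0.0) -> PlaneSpec:
    """Horizontal plane through the mean of the active PV port centers."""
    centers = [surface.geometry.port_plane(lab, t_ms)[0]
               for lab in surface.active_ports if lab != "MV"]
    c = np.mean(np.asarray(centers), axis=0)
    return PlaneSpec(center=tuple(c), normal=(0.0, 0.0, 1.0))


def run_case(spec: CaseSpec, postprocess: bool = True,
             props: FluidProperties | None = None) -> CaseBundle:
    """Build the anatomy, apply the resection, run the cycles and
    postprocess (energetics always; FTLE maps at end-systole 0.35T and
    early-diastole 0.55T of the final cycle, and PV-seeded pathlines over
    0-0.35T, when ``postprocess``)."""
    anatomy = subject_config(spec.subject)
    surface = build_idealized_la(anatomy)
    surface = virtual_resect(surface, spec.resection)
    result = run_simulation(surface, spec.solver, props=props)
    energetics = energetics_timeseries(result, case=spec.name)
    bundle = CaseBundle(spec=spec, anatomy=anatomy, result=result,
                        energetics=energetics)
    bundle.manifest = dict(
        case=spec.name,
        subject=spec.subject,
        resection=spec.resection.vein,
        seed=spec.seed,
        config_hash=_config_hash(anatomy.to_dict(), vars(spec.solver),
                                 spec.resection.vein, spec.resection.stump_depth_mm),
        version=_version,
        grid_n=spec.solver.grid_n,
        cycles=spec.solver.n_cycles,
        steps=result.diagnostics.get("steps"),
        max_div_ratio=result.diagnostics.get("max_div_ratio"),
    )
    if postprocess:
        T = anatomy.period_ms
        t0f = result.final_cycle_start_ms
        series = VelocitySeries.from_result(result)
        plane = upper_la_plane(surface, t0f)
        bundle.manifest["ftle_plane"] = dict(
            center=[float(c) for c in plane.center],
            normal=[float(n) for n in plane.normal])
        delta = result.grid.h / 2.0
        for frac in (0.35, 0.55):
            t0 = t0f + frac * T
            bundle.ftle[t0] = backward_ftle(series, plane, t0, tau_ms=-50.0,
                                            delta_mm=delta)
        bundle.pathlines = compute_pathlines(
            series, surface, t0f, t0f + 0.35 * T, seed=spec.seed)
    return bundle


def write_case_outputs(bundle: CaseBundle, outdir) -> list[str]:
    """Deterministic CSV/JSON (and VTK) outputs for one case."""
    from .io_vtk import write_polylines, write_structured_points

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(df, name):
        path = outdir / name
        df.to_csv(path, index=False, float_format=CSV_FLOAT_FMT,
                  lineterminator="\n")
        written.append(str(path))

    _csv(bundle.result.port_series(), f"{bundle.name}_ports.csv")
    _csv(bundle.result.balance_series(), f"{bundle.name}_balance.csv")
    _csv(bundle.energetics.frame, f"{bundle.name}_energetics.csv")
    mpath = outdir / f"{bundle.name}_manifest.json"
    with open(mpath, "w") as f:
        json.dump(bundle.manifest, f, indent=1, sort_keys=True, default=str)
    written.append(str(mpath))

    for t0, fld in bundle.ftle.items():
        path = outdir / f"{bundle.name}_ftle_{int(round(t0))}ms.csv"
        np.savetxt(path, fld.values, fmt="%.8g", delimiter=",")
        written.append(str(path))
    if bundle.pathlines:
        lines = []
        labels = []
        order = {lab: i for i, lab in enumerate(PV_LABELS)}
        for lab, traj in bundle.pathlines:
            for p in range(traj.shape[1]):
                lines.append(traj[:, p, :])
                labels.append(order.get(lab, -1))
        path = outdir / f"{bundle.name}_pathlines.vtk"
        write_polylines(path, lines, scalars=labels)
        written.append(str(path))
    return written


def run_five_cases(subject: int, solver: SolverConfig | None = None,
                   outdir=None, seed: int = 0, postprocess: bool = True,
                   props: FluidProperties | None = None) -> list[CaseBundle]:
    """Run the pre-resection case and all four single-PV resections."""
    bundles = []
    for spec in five_case_specs(subject, solver=solver, outdir=outdir, seed=seed):
        bundle = run_case(spec, postprocess=postprocess, props=props)
        if outdir is not None:
            write_case_outputs(bundle, outdir)
        bundles.append(bundle)
    return bundles


def compare_cases(pre: CaseBundle, resections: list[CaseBundle]) -> dict:
    """Peak-systolic energetics comparison against the pre-resection case.

    Returns a report with per-case peak systolic kinetic energy and
    dissipation rate, fold-changes relative to the pre-resection case, the
    ranking of the resections by peak-systolic dissipation, and the change
    of the cycle-mean inflow speed of every remaining vein.
    """
    for b in resections:
        if b.spec.subject != pre.spec.subject:
            raise ValueError("bundles must share a subject")
        if b.result.grid.n != pre.result.grid.n:
            raise ValueError("bundles must share a grid")
    T = pre.anatomy.period_ms
    ke_pre, d_pre = pre.energetics.peak_systolic(T)
    pre_speed = pre.mean_pv_inflow_speed()
    cases = {}
    for b in [pre] + resections:
        ke, d = b.energetics.peak_systolic(T)
        speeds = b.mean_pv_inflow_speed()
        cases[b.name] = dict(
            resection=b.spec.resection.vein,
            peak_systolic_KE_mJ=ke,
            peak_systolic_D_mJ_s=d,
            KE_fold_change=ke / ke_pre if ke_pre > 0 else np.nan,
            D_fold_change=d / d_pre if d_pre > 0 else np.nan,
            mean_pv_inflow_speed_mm_s=speeds,
            inflow_speed_change={
                lab: speeds[lab] / pre_speed[lab]
                for lab in speeds if lab in pre_speed and pre_speed[lab] != 0
            },
        )
    ranking = sorted(
        (b for b in resections),
        key=lambda b: cases[b.name]["peak_systolic_D_mJ_s"], reverse=True)
    return dict(
        subject=pre.spec.subject,
        pre_case=pre.name,
        cases=cases,
        resection_ranking_by_dissipation=[
            b.spec.resection.vein for b in ranking],
    )
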