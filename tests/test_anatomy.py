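"""Idealized anatomy builder and virtual resection."""

import numpy as np
import pytest
import trimesh

from laflow.anatomy import (build_idealized_la, enclosed_volume,
                            fit_fourier_displacement, virtual_resect)
from laflow.config import (AnatomyConfig, GeometryConflictError, ResectionSpec,
                           TubeSpec, subject_config)


class TestBuildIdealizedLA:
    def test_watertight_and_tagged(self, subject1_surface):
        assert subject1_surface.is_watertight()
        assert sorted(subject1_surface.active_ports) == [
            "LIPV", "LSPV", "MV", "RIPV", "RSPV"]

    def test_port_areas_match_config(self, subject1_surface, subject1_config):
        areas = {s.label: s.area_mm2 for s in subject1_config.all_tubes}
        for label in subject1_surface.active_ports:
            _, _, a = subject1_surface.port_plane(label, t_ms=300.0)
            assert a == pytest.approx(areas[label], rel=0.01)

    def test_port_caps_planar(self, subject1_surface):
        for label in subject1_surface.active_ports:
            c, n, _ = subject1_surface.port_plane(label, t_ms=0.0)
            faces = subject1_surface.faces[subject1_surface.port_tags[label]]
            verts = subject1_surface.vertices_at(0.0)[np.unique(faces)]
            assert np.abs((verts - c) @ n).max() < 1e-6

    def test_volume_tracks_curve(self, subject1_surface, subject1_config):
        cfg = subject1_config
        for t in cfg.phase_times():
            v_mesh = subject1_surface.volume_at(t) / 1000.0  # mm^3 -> mL
            assert v_mesh == pytest.approx(cfg.la_volume(t), rel=0.01)

    def test_periodicity(self, subject1_surface):
        x0 = subject1_surface.vertices_at(0.0)
        x1 = subject1_surface.vertices_at(subject1_surface.period_ms)
        scale = np.abs(x0).max()
        assert np.abs(x1 - x0).max() < 1e-9 * scale

    def test_static_when_volume_constant(self):
        cfg = subject_config(1)
        const = (cfg.la_volume(0.0),)  # constant curve: mean term only
        cfg = AnatomyConfig(pv_specs=cfg.pv_specs, mv_spec=cfg.mv_spec,
                            period_ms=cfg.period_ms, la_volume_coeffs=const,
                            lv_volume_coeffs=cfg.lv_volume_coeffs)
        surf = build_idealized_la(cfg)
        x0 = surf.vertices_at(0.0)
        for t in (0.2, 0.55, 0.91):
            assert np.abs(surf.vertices_at(t * cfg.period_ms) - x0).max() < 1e-8

    def test_sphere_reduced_mode_volume(self):
        # no tubes, spherical chamber: enclosed volume ~ (4/3) pi r^3
        r = 20.0
        target_ml = 4.0 / 3.0 * np.pi * r ** 3 / 1000.0
        cfg = AnatomyConfig(chamber_semi_axes=(r, r, r), pv_specs=(),
                            mv_spec=None, la_volume_coeffs=(target_ml,),
                            lv_volume_coeffs=(100.0,))
        surf = build_idealized_la(cfg)
        assert surf.volume_at(0.0) / 1000.0 == pytest.approx(target_ml, rel=0.005)

    def test_tube_collision_rejected(self):
        base = subject_config(1)
        specs = list(base.pv_specs)
        # move RSPV nearly on top of RIPV
        d = np.asarray(specs[3].direction) + 1e-3
        specs[2] = TubeSpec(label="RSPV", direction=tuple(d),
                            area_mm2=specs[2].area_mm2)
        cfg = AnatomyConfig(pv_specs=tuple(specs), mv_spec=base.mv_spec,
                            period_ms=base.period_ms)
        with pytest.raises(GeometryConflictError):
            build_idealized_la(cfg)

    def test_duplicate_directions_rejected(self):
        base = subject_config(1)
        specs = list(base.pv_specs)
        specs[1] = TubeSpec(label="LIPV", direction=specs[0].direction,
                            area_mm2=specs[1].area_mm2)
        with pytest.raises(ValueError):
            AnatomyConfig(pv_specs=tuple(specs), mv_spec=base.mv_spec,
                          period_ms=base.period_ms)


class TestFitFourierDisplacement:
    def test_static_vertex(self):
        pos = np.tile(np.array([[1.0, 2.0, 3.0]]), (20, 1, 1))
        coeffs = fit_fourier_displacement(pos, 870.0, 9)
        assert np.allclose(coeffs[..., 0], [1.0, 2.0, 3.0])
        assert np.abs(coeffs[..., 1:]).max() < 1e-12

    def test_single_harmonic_recovery(self):
        T = 870.0
        t = np.arange(20) * T / 20
        pos = np.zeros((20, 1, 3))
        pos[:, 0, 0] = np.cos(2 * np.pi * t / T)
        coeffs = fit_fourier_displacement(pos, T, 9)
        assert coeffs[0, 0, 1] == pytest.approx(1.0, abs=1e-9)
        mask = np.ones_like(coeffs, dtype=bool)
        mask[0, 0, 1] = False
        assert np.abs(coeffs[mask]).max() < 1e-9

    def test_round_trip_on_built_anatomy(self, subject1_surface, subject1_config):
        cfg = subject1_config
        times = cfg.phase_times()
        phases = np.stack([subject1_surface.vertices_at(t) for t in times])
        coeffs = fit_fourier_displacement(phases, cfg.period_ms, cfg.fourier_order)
        from laflow import fourier
        back = fourier.evaluate(coeffs, times[7], cfg.period_ms)
        assert np.abs(back - phases[7]).max() < 1e-6


class TestVirtualResect:
    def test_none_is_identity(self, subject1_surface):
        out = virtual_resect(subject1_surface, ResectionSpec("NONE"))
        assert out is subject1_surface

    def test_resection_contract(self, subject1_surface, subject1_config):
        res = virtual_resect(subject1_surface, ResectionSpec("LSPV", 5.0))
        assert res.mesh_at(0.0).is_watertight
        assert sorted(res.active_ports) == ["LIPV", "MV", "RIPV", "RSPV"]
        assert "stump_LSPV" in res.port_tags
        # remaining port areas unchanged
        for label in res.active_ports:
            a_pre = subject1_surface.port_plane(label)[2]
            a_post = res.port_plane(label)[2]
            assert a_post == pytest.approx(a_pre, rel=1e-9)

    def test_volume_decreases_by_at_most_tube_segment(self, subject1_surface,
                                                      subject1_config):
        spec = ResectionSpec("LSPV", 5.0)
        res = virtual_resect(subject1_surface, spec)
        v_pre = subject1_surface.volume_at(0.0)
        v_post = res.volume_at(0.0)
        tube = next(s for s in subject1_config.pv_specs if s.label == "LSPV")
        removed_max = tube.area_mm2 * (tube.resolved_length_mm()
                                       - spec.stump_depth_mm)
        assert v_post < v_pre
        assert v_pre - v_post <= removed_max * 1.05

    def test_stump_cap_smooth(self, subject1_surface):
        res = virtual_resect(subject1_surface, ResectionSpec("LSPV", 5.0))
        mesh = res.mesh_at(0.0)
        cap = set(res.port_tags["stump_LSPV"].tolist())
        angles = [a for (f1, f2), a in zip(mesh.face_adjacency,
                                           mesh.face_adjacency_angles)
                  if f1 in cap or f2 in cap]
        assert np.degrees(max(angles)) < 60.0

    def test_displacement_model_unchanged_for_chamber(self, subject1_surface):
        res = virtual_resect(subject1_surface, ResectionSpec("RIPV", 5.0))
        n_chamber = int((subject1_surface.vertex_group == 0).sum())
        assert np.allclose(res.position_coeffs[:n_chamber],
                           subject1_surface.position_coeffs[:n_chamber])

    def test_stump_depth_exceeding_length_rejected(self, subject1_surface):
        with pytest.raises(ValueError, match="exceeds"):
            virtual_resect(subject1_surface, ResectionSpec("LIPV", 500.0))


class TestExport:
    def test_stl_round_trip_volume(self, subject1_surface, tmp_path):
        files = subject1_surface.export(tmp_path / "s1", phases=2)
        stls = [f for f in files if f.endswith(".stl")]
        assert len(stls) == 2
        mesh = trimesh.load(stls[0])
        assert mesh.is_watertight
        assert abs(mesh.volume) == pytest.approx(
            subject1_surface.volume_at(0.0), rel=1e-6)
        assert any(f.endswith("_ports.json") for f in files)
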