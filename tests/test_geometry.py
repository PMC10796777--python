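"""Immersed-geometry layer: signed distance, BDIM weights, wall velocity."""

import numpy as np
import pytest
import trimesh

from laflow.geometry import (AnalyticImmersion, CartesianGrid, bdim_kernel,
                             bdim_weights, fluid_is_connected, immerse_mesh,
                             surface_to_sdf, winding_number,
                             _point_triangle_distance)


@pytest.fixture(scope="module")
def sphere_mesh():
    return trimesh.creation.icosphere(subdivisions=3, radius=10.0)


@pytest.fixture(scope="module")
def sphere_sdf(sphere_mesh):
    grid = CartesianGrid.from_bounds([[-15.0] * 3, [15.0] * 3], 20)
    return grid, surface_to_sdf(sphere_mesh, grid)


class TestBdimKernel:
    @pytest.mark.parametrize("d,expected", [
        (-2.0, 1.0),            # deep fluid
        (0.0, 0.5),             # interface: kernel symmetry
        (2.0, 0.0),             # deep solid
        (0.5, 0.0908),          # hand-evaluated kernel value, 4 s.f.
    ])
    def test_values(self, d, expected):
        assert bdim_kernel(d, 1.0) == pytest.approx(expected, abs=5e-5)

    def test_monotone_in_distance(self):
        d = np.linspace(-3, 3, 601)
        mu = bdim_kernel(d, 1.0)
        assert np.all(np.diff(mu) <= 1e-12)

    def test_epsilon_must_be_positive(self):
        with pytest.raises(ValueError):
            bdim_kernel(0.0, 0.0)


class TestSurfaceToSdf:
    def test_sphere_center_and_outside(self, sphere_sdf):
        grid, sdf = sphere_sdf
        pts = grid.cell_centers()
        r = np.linalg.norm(pts, axis=-1)
        # center cell: sdf ~ -10 within h/2; outside point at r=15: ~ +5
        i = np.unravel_index(np.argmin(r), r.shape)
        assert abs(sdf[i] - (r[i] - 10.0)) < grid.h / 2
        j = np.unravel_index(np.argmax(r), r.shape)
        assert abs(sdf[j] - (r[j] - 10.0)) < grid.h / 2

    def test_matches_analytic_sphere_in_band(self, sphere_sdf):
        grid, sdf = sphere_sdf
        r = np.linalg.norm(grid.cell_centers(), axis=-1)
        exact = r - 10.0
        band = np.abs(exact) < 2 * grid.h
        # near the surface: exact up to the faceting of the icosphere
        assert np.abs(sdf - exact)[band].max() < 0.05

    def test_knn_pruning_matches_full_brute_force(self, sphere_mesh, rng):
        # oracle: point-triangle distance over ALL faces (no kNN pruning)
        grid = CartesianGrid.from_bounds([[-14.0] * 3, [14.0] * 3], 8)
        sdf = surface_to_sdf(sphere_mesh, grid)
        pts = grid.cell_centers().reshape(-1, 3)
        tri = np.asarray(sphere_mesh.vertices)[np.asarray(sphere_mesh.faces)]
        idx = rng.choice(len(pts), 60, replace=False)
        full = _point_triangle_distance(pts[idx], tri).min(axis=1)
        assert np.allclose(np.abs(sdf.reshape(-1)[idx]), full, atol=1e-6)

    def test_winding_number_sign(self, sphere_mesh):
        pts = np.array([[0.0, 0.0, 0.0], [3.0, -2.0, 5.0], [12.0, 0.0, 0.0],
                        [0.0, 14.0, 1.0]])
        wn = winding_number(pts, np.asarray(sphere_mesh.vertices),
                            np.asarray(sphere_mesh.faces))
        assert np.allclose(wn[:2], 1.0, atol=1e-6)
        assert np.allclose(wn[2:], 0.0, atol=1e-6)

    def test_open_surface_rejected(self, sphere_mesh):
        open_mesh = trimesh.Trimesh(np.asarray(sphere_mesh.vertices),
                                    np.asarray(sphere_mesh.faces)[:-10],
                                    process=False)
        grid = CartesianGrid.from_bounds([[-15.0] * 3, [15.0] * 3], 8)
        with pytest.raises(ValueError, match="watertight"):
            surface_to_sdf(open_mesh, grid)


class TestAnalyticImmersion:
    def test_sdf_matches_generic_evaluation(self, subject1_surface):
        geom = subject1_surface.geometry
        grid = CartesianGrid.from_bounds(geom.bounds(margin_mm=6.0), 24)
        imm = AnalyticImmersion(geom, grid, 2 * grid.h)
        pts = grid.cell_centers().reshape(-1, 3)
        direct = geom.sdf(pts, 123.0).reshape(grid.n)
        assert np.abs(imm.cell_sdf(123.0) - direct).max() < 1e-9

    def test_fluid_volume_consistency(self, subject1_surface, subject1_config):
        # >= 20 cells across the chamber: cell count tracks mesh volume to 2%
        geom = subject1_surface.geometry
        grid = CartesianGrid.from_bounds(geom.bounds(margin_mm=6.0), 48)
        imm = AnalyticImmersion(geom, grid, 2 * grid.h)
        for t in (0.0, 300.0):
            dom = imm.domain(t)
            assert dom.fluid_volume_mm3() == pytest.approx(
                subject1_surface.volume_at(t), rel=0.02)

    def test_fluid_connected(self, subject1_surface):
        geom = subject1_surface.geometry
        grid = CartesianGrid.from_bounds(geom.bounds(margin_mm=6.0), 32)
        dom = AnalyticImmersion(geom, grid, 2 * grid.h).domain(200.0)
        assert fluid_is_connected(dom.fluid_mask)

    def test_mu_monotone_in_sdf(self, subject1_surface):
        geom = subject1_surface.geometry
        grid = CartesianGrid.from_bounds(geom.bounds(margin_mm=6.0), 24)
        dom = AnalyticImmersion(geom, grid, 2 * grid.h).domain(100.0)
        from laflow.geometry import _face_sdf_from_cells
        for ax in range(3):
            fs = _face_sdf_from_cells(dom.sdf, ax).ravel()
            mu = dom.mu[ax].ravel()
            order = np.argsort(fs)
            assert np.all(np.diff(mu[order]) <= 1e-9)


class TestWallVelocity:
    def test_static_surface_zero(self):
        from laflow.config import AnatomyConfig
        from laflow.anatomy import build_idealized_la
        cfg = AnatomyConfig(chamber_semi_axes=(20.0, 20.0, 20.0), pv_specs=(),
                            mv_spec=None,
                            la_volume_coeffs=(4 / 3 * np.pi * 8.0,),
                            lv_volume_coeffs=(100.0,))
        surf = build_idealized_la(cfg)
        pts = np.array([[0.0, 0.0, 19.0], [15.0, 0.0, 0.0]])
        vel = surf.geometry.wall_velocity(pts, 100.0)
        assert np.abs(vel).max() < 1e-10

    def test_matches_finite_difference_of_motion(self, subject1_surface):
        # Richardson: (x(t+d) - x(t-d)) / 2d converges to the analytic rate
        geom = subject1_surface.geometry
        t = 150.0
        s = geom.scale(t)
        pts = s * np.array([[0.0, 0.0, 25.9], [31.9, 0.0, 0.0]])
        vel = geom.wall_velocity(pts, t)
        errs = []
        for d in (0.87, 0.435):
            sp = geom.scale(t + d)
            sm = geom.scale(t - d)
            fd = ((sp - sm) / (2 * d) / s) * pts
            errs.append(np.abs(fd - vel).max())
        assert errs[1] < errs[0] / 3.5 + 1e-12  # ~O(d^2)

    def test_surface_integral_reproduces_volume_rate(self, subject1_surface):
        # divergence theorem on the mesh: sum over faces of v . n dA ~ dV/dt
        surf = subject1_surface
        t = 200.0
        verts = surf.vertices_at(t)
        vels = surf.vertex_velocity_at(t)
        tri = surf.faces
        n = np.cross(verts[tri[:, 1]] - verts[tri[:, 0]],
                     verts[tri[:, 2]] - verts[tri[:, 0]]) / 2.0
        v_face = vels[tri].mean(axis=1)
        rate = float(np.einsum("ij,ij->", v_face, n))  # mm^3/ms
        d = 0.5
        fd = (surf.volume_at(t + d) - surf.volume_at(t - d)) / (2 * d)
        assert rate == pytest.approx(fd, rel=0.03)


class TestImmerseMesh:
    def test_sign_and_weights_on_sphere(self, sphere_mesh):
        from laflow.anatomy import MovingSurface
        import laflow.fourier as fourier
        verts = np.asarray(sphere_mesh.vertices)
        coeffs = np.zeros((len(verts), 3, 3))
        coeffs[:, :, 0] = verts
        surf = MovingSurface(verts, np.asarray(sphere_mesh.faces), coeffs, 1000.0)
        grid = CartesianGrid.from_bounds([[-15.0] * 3, [15.0] * 3], 16)
        dom = immerse_mesh(surf, grid, 0.0, epsilon_mm=2 * grid.h)
        r = np.linalg.norm(grid.cell_centers(), axis=-1)
        assert np.all((dom.sdf < 0) == (dom.fluid_mask))
        inside = r < 8.0
        outside = r > 12.5
        assert np.all(dom.sdf[inside] < 0)
        assert np.all(dom.sdf[outside] > 0)
        assert np.abs(dom.wall_velocity[0]).max() == 0.0  # static mesh
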