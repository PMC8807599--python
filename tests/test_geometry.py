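"""Geometry pipeline: STL reading, signed distances, solid fractions,
volumetric centers and wall normals, checked against analytic shapes,
Monte-Carlo volume oracles and trimesh's independent signed distance."""

import numpy as np
import pytest
import trimesh

from vlbm.fixtures import cylinder_triangle_count, make_cylinder_stl
from vlbm.geometry import (BOUNDARY, FLUID, SOLID, GridSpec, NodeField,
                           classify_cells, fluid_volume_error,
                           fluid_volumetric_center, read_stl, signed_distance,
                           solid_fraction, voxelize, wall_normal)

from .conftest import L, R
from .oracles import monte_carlo_fluid_centroid, monte_carlo_solid_fraction

V_CYL = np.pi * R**2 * L


class TestReadSTL:
    def test_unit_cube(self, tmp_path):
        box = trimesh.creation.box((1.0, 1.0, 1.0))
        p = tmp_path / "cube.stl"
        box.export(str(p))
        mesh = read_stl(p)
        assert len(mesh.faces) == 12
        assert len(np.unique(mesh.vertices.round(9), axis=0)) == 8
        assert mesh.is_watertight

    def test_fixture_cylinder_count(self, tmp_path):
        for k in (16, 64):
            p = tmp_path / f"cyl{k}.stl"
            make_cylinder_stl(R, L, facets=k, path=p)
            mesh = read_stl(p)
            assert len(mesh.faces) == cylinder_triangle_count(k)

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "empty.stl"
        p.write_text("")
        with pytest.raises(ValueError):
            read_stl(p)

    def test_non_watertight_warns(self, tmp_path):
        box = trimesh.creation.box((1, 1, 1))
        holed = trimesh.Trimesh(box.vertices, box.faces[:-1], process=False)
        p = tmp_path / "holed.stl"
        holed.export(str(p))
        with pytest.warns(UserWarning):
            mesh = read_stl(p)
        assert not mesh.is_watertight


def _grid_around(mesh, n, pad=0.1):
    lo, hi = mesh.bounds
    ext = (hi - lo).max() * (1 + 2 * pad)
    dx = ext / n
    origin = (lo + hi) / 2 - ext / 2
    return GridSpec(n, n, n, dx=dx, origin=tuple(origin))


class TestSignedDistance:
    def test_sphere_matches_analytic(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        grid = _grid_around(sphere, 24)
        phi = signed_distance(sphere, grid).phi
        xs, ys, zs = grid.vertex_axes()
        rr = np.sqrt(np.add.outer(np.add.outer(xs**2, ys**2), zs**2))
        # chord error of the icosphere bounds the deviation
        assert np.abs(phi - (rr - 1.0)).max() < 5e-3

    def test_matches_independent_oracle_on_coarse_grid(self):
        """Magnitude against a dense surface-point-cloud oracle; sign
        against trimesh's ray-based containment test."""
        from scipy.spatial import cKDTree

        mesh = make_cylinder_stl(R, L, facets=32)
        grid = _grid_around(mesh, 12)
        phi = signed_distance(mesh, grid).phi
        xs, ys, zs = grid.vertex_axes()
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

        # dense barycentric sampling of every triangle -> NN distance is an
        # upper bound exact to within the sampling spacing
        m = 24
        u, v = np.meshgrid(np.arange(m + 1), np.arange(m + 1), indexing="ij")
        keep = (u + v) <= m
        bary = np.column_stack([u[keep], v[keep], m - u[keep] - v[keep]]) / m
        tri = np.asarray(mesh.triangles)
        cloud = np.einsum("sb,tbi->tsi", bary, tri).reshape(-1, 3)
        spacing = np.sqrt(((tri[:, 1] - tri[:, 0]) ** 2).sum(-1)).max() / m
        dist_ref = cKDTree(cloud).query(pts)[0]
        assert np.abs(np.abs(phi).ravel() - dist_ref).max() < spacing

        # sign oracle: the faceted cylinder is a regular 32-gon prism —
        # inside iff below every side-facet plane and between the caps
        k = 32
        ang = (np.arange(k) + 0.5) * 2 * np.pi / k
        proj = pts[:, 0, None] * np.cos(ang) + pts[:, 1, None] * np.sin(ang)
        inside_ref = ((proj.max(axis=1) < R * np.cos(np.pi / k))
                      & (pts[:, 2] > 0) & (pts[:, 2] < L))
        on_surface = np.abs(phi.ravel()) < 1e-9  # sign ambiguous on the wall
        assert np.array_equal((phi.ravel() < 0)[~on_surface],
                              inside_ref[~on_surface])

    def test_cylinder_axis_and_on_surface_points(self):
        mesh = make_cylinder_stl(R, L, facets=256)
        nd = 16
        dx = 2 * R / nd
        z0 = L / 2 - 2 * dx
        grid = GridSpec(nd + 4, nd + 4, 4, dx=dx,
                        origin=(-R - 2 * dx, -R - 2 * dx, z0))
        phi = signed_distance(mesh, grid).phi
        xs, ys, zs = grid.vertex_axes()
        ia = int(np.argmin(np.abs(xs))); ja = int(np.argmin(np.abs(ys)))
        r_ax = np.hypot(xs[ia], ys[ja])
        assert phi[ia, ja, 1] == pytest.approx(-(R - r_ax), rel=5e-3)
        # a vertex exactly on the faceted side wall: the tangent plane x = R
        # passes through the facet vertex ring at angle 0
        i_wall = int(np.argmin(np.abs(xs - R)))
        assert abs(xs[i_wall] - R) < 1e-12
        assert abs(phi[i_wall, ja, 1]) < 1e-4 * R

    def test_eikonal_property_on_sphere(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        grid = _grid_around(sphere, 32)
        phi = signed_distance(sphere, grid).phi
        g = np.linalg.norm(np.gradient(phi, grid.dx), axis=0)
        xs, ys, zs = grid.vertex_axes()
        rr = np.sqrt(np.add.outer(np.add.outer(xs**2, ys**2), zs**2))
        away = rr > 2 * grid.dx  # exclude the medial point at the center
        inner = np.zeros_like(away)
        inner[1:-1, 1:-1, 1:-1] = True  # central differences only
        sel = away & inner
        assert g[sel].min() > 0.95 and g[sel].max() < 1.05

    def test_requires_watertight(self):
        box = trimesh.creation.box((1, 1, 1))
        holed = trimesh.Trimesh(box.vertices, box.faces[:-1], process=False)
        with pytest.raises(ValueError):
            signed_distance(holed, _grid_around(box, 8))


class TestClassification:
    def _nodes(self, corner_vals):
        phi = np.zeros((2, 2, 2))
        phi.ravel()[:] = corner_vals
        return NodeField(GridSpec(1, 1, 1, dx=1.0, origin=(0, 0, 0)), phi)

    def test_all_negative_is_fluid(self):
        assert classify_cells(self._nodes([-1] * 8))[0, 0, 0] == FLUID

    def test_all_positive_is_solid(self):
        assert classify_cells(self._nodes([1] * 8))[0, 0, 0] == SOLID

    def test_mixed_is_boundary(self):
        assert classify_cells(self._nodes([-1, -1, -1, -1, 1, 1, 1, 1]))[0, 0, 0] == BOUNDARY

    def test_zero_vertex_counts_as_fluid(self):
        assert classify_cells(self._nodes([0] * 8))[0, 0, 0] == FLUID
        assert classify_cells(self._nodes([0, 0, 0, 0, -1, -1, -1, -1]))[0, 0, 0] == FLUID


def _plane_nodes(offset, dx=1.0):
    """phi of the half-space solid x > offset on a single-cell grid."""
    grid = GridSpec(1, 1, 1, dx=dx, origin=(0, 0, 0))
    xs, ys, zs = grid.vertex_axes()
    X, _, _ = np.meshgrid(xs, ys, zs, indexing="ij")
    return NodeField(grid, X - offset)


class TestSolidFraction:
    def test_midplane_is_half(self):
        P = solid_fraction(_plane_nodes(0.5), (0, 0, 0), q=8)
        assert P == pytest.approx(0.5, abs=1 / 8)
        # symmetric sub-cell counting across the mid-plane is exact
        assert P == pytest.approx(0.5, abs=1e-12)

    def test_all_fluid_and_all_solid(self):
        assert solid_fraction(_plane_nodes(2.0), (0, 0, 0)) == 0.0
        assert solid_fraction(_plane_nodes(-2.0), (0, 0, 0)) == 1.0

    def test_cylinder_cell_against_monte_carlo(self, slab_cells, cylinder_mesh):
        g = slab_cells.grid
        nodes = signed_distance(cylinder_mesh, g)
        mc_R = R * np.cos(np.pi / 128)  # MC oracle uses the faceted radius
        for b in slab_cells.bindex[::40]:
            lo = np.asarray(g.origin) + b * g.dx
            P = solid_fraction(nodes, tuple(b), q=8)
            P_mc = monte_carlo_solid_fraction(
                lo, g.dx, lambda p: np.hypot(p[:, 0], p[:, 1]) > mc_R,
                npts=200_000)
            assert P == pytest.approx(P_mc, abs=8 ** -1.5 + 0.01)


class TestVolumetricCenter:
    def test_half_solid_cell(self):
        xb = fluid_volumetric_center(_plane_nodes(0.5), (0, 0, 0), q=8)
        assert np.allclose(xb, [0.25, 0.5, 0.5], atol=1e-12)

    def test_cylinder_cell_against_monte_carlo(self, slab_cells, cylinder_mesh):
        g = slab_cells.grid
        nodes = signed_distance(cylinder_mesh, g)
        mc_R = R * np.cos(np.pi / 128)
        for b in slab_cells.bindex[::60]:
            lo = np.asarray(g.origin) + b * g.dx
            xb = fluid_volumetric_center(nodes, tuple(b), q=8)
            xb_mc = monte_carlo_fluid_centroid(
                lo, g.dx, lambda p: np.hypot(p[:, 0], p[:, 1]) > mc_R,
                npts=200_000)
            assert np.linalg.norm(xb - xb_mc) < g.dx / 8 + 0.02 * g.dx


class TestWallNormal:
    def test_half_space_exact(self):
        nodes = _plane_nodes(0.5)
        n, d = wall_normal(nodes, (0, 0, 0), np.array([0.25, 0.5, 0.5]))
        # solid at x > 0.5, normal stored pointing into the fluid (-x)
        assert np.allclose(n, [-1.0, 0.0, 0.0], atol=1e-12)
        assert d == pytest.approx(-0.25, abs=1e-12)

    def test_unit_norm_everywhere(self, slab_cells):
        assert np.allclose(np.linalg.norm(slab_cells.normal, axis=1), 1.0,
                           atol=1e-9)

    def test_sphere_normals_radial(self):
        sphere = trimesh.creation.icosphere(subdivisions=5, radius=1.0)
        cells = voxelize(sphere, nd=64, q=4, margin=2)
        radial = cells.xb / np.linalg.norm(cells.xb, axis=1, keepdims=True)
        cosang = -(cells.normal * radial).sum(axis=1)  # inward normal
        ok = ~cells.degenerate
        assert np.degrees(np.arccos(np.clip(cosang[ok], -1, 1))).max() < 2.0


class TestVoxelize:
    def test_class_fraction_invariants(self, slab_cells):
        P, cls = slab_cells.P, slab_cells.cls
        assert np.all((cls == FLUID) == (P == 0.0))
        assert np.all((cls == SOLID) == (P == 1.0))
        b = cls == BOUNDARY
        assert np.all((P[b] > 0) & (P[b] < 1))

    def test_axial_invariance_of_slab(self, slab_cells):
        for k in range(1, slab_cells.grid.nz):
            assert np.array_equal(slab_cells.P[:, :, 0], slab_cells.P[:, :, k])

    def test_fluid_volume_error_trivial(self, slab_cells):
        assert fluid_volume_error(slab_cells, slab_cells.fluid_volume) == 0.0

    def test_volume_error_decreases_under_refinement(self, cylinder_mesh):
        errs = [fluid_volume_error(voxelize(cylinder_mesh, nd, q=4), V_CYL)
                for nd in (11, 17, 25)]
        assert errs[0] > errs[-1]

    def test_q_refinement_consistency(self, cylinder_mesh):
        """P at q and 2q differ by at most the quantization bound 3/q."""
        c4 = voxelize(cylinder_mesh, 21, q=4)
        c8 = voxelize(cylinder_mesh, 21, q=8)
        common = (c4.cls == BOUNDARY) & (c8.cls == BOUNDARY)
        dP = np.abs(c4.P - c8.P)[common]
        assert dP.max() <= 3 / 4 + 1e-12
        assert dP.mean() < 0.05
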