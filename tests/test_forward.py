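"""Forward model: geometry, meshing, plane-stress FEM and interpolation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import Delaunay

import embryoelast as ee
from embryoelast.forward import (
    AREA_OPACA,
    AREA_PELLUCIDA,
    INTERMEDIATE,
    MIDLINE,
    assemble_stiffness,
    solve_displacement,
)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

class TestGeometry:
    def test_default_four_region_morphology(self, geometry):
        assert geometry.midline_semi_axes == (0.18, 2.2)
        assert geometry.pellucida_semi_axes == (1.15, 2.8)
        assert geometry.intermediate_semi_axes == pytest.approx((0.23, 2.25))
        assert geometry.outer_radius == 5.0
        assert geometry.thicknesses == {
            MIDLINE: 84.0, INTERMEDIATE: 56.0,
            AREA_PELLUCIDA: 56.0, AREA_OPACA: 76.0,
        }

    def test_three_region_drops_intermediate(self, geometry3):
        assert geometry3.intermediate_semi_axes is None
        assert geometry3.n_regions == 3
        assert INTERMEDIATE not in geometry3.thicknesses
        assert geometry3.midline_semi_axes == (0.18, 2.2)

    def test_override_plumbing(self):
        g = ee.build_default_geometry(4, {"outer_radius": 4.0})
        assert g.outer_radius == 4.0
        g.validate()

    def test_intermediate_offset_configurable(self):
        g = ee.build_default_geometry(4, {"intermediate_offset": 0.1})
        assert g.intermediate_semi_axes == pytest.approx((0.28, 2.3))

    def test_non_nested_override_names_pair(self):
        with pytest.raises(ee.GeometryError, match="midline.*inside.*intermediate"):
            ee.build_default_geometry(4, {
                "midline_semi_axes": (0.5, 2.3),
                "intermediate_semi_axes": (0.4, 2.35),
            })

    def test_unknown_override_rejected(self):
        with pytest.raises(ee.GeometryError, match="unknown"):
            ee.build_default_geometry(4, {"radius": 1.0})

    @pytest.mark.parametrize(
        "point,region",
        [
            ((0.0, 0.0), MIDLINE),
            ((0.665, 0.0), AREA_PELLUCIDA),  # between S_a and AP_a
            ((4.0, 0.0), AREA_OPACA),
            ((0.2, 0.0), INTERMEDIATE),
            ((0.18, 0.0), MIDLINE),  # boundary belongs to the inner region
        ],
    )
    def test_region_of_point(self, geometry, point, region):
        assert ee.region_of_point(geometry, point) == region

    def test_point_outside_disc_raises(self, geometry):
        with pytest.raises(ee.OutOfDomainError):
            ee.region_of_point(geometry, (5.1, 0.0))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        r=st.floats(0.0, 0.999),
        theta=st.floats(0.0, 2 * np.pi),
    )
    def test_region_matches_bruteforce_ellipse_membership(self, r, theta):
        """The innermost containing ellipse wins, per direct membership tests."""
        geometry = ee.build_default_geometry(4)
        p = (5.0 * r * np.cos(theta), 5.0 * r * np.sin(theta))
        chain = geometry.ellipse_chain
        expected = AREA_OPACA
        for name, (a, b) in reversed(chain):
            if (p[0] / a) ** 2 + (p[1] / b) ** 2 <= 1.0:
                expected = name
        assert ee.region_of_point(geometry, p) == expected


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------

class TestMesh:
    def test_node_count_near_target(self, mesh3000):
        assert 2400 <= mesh3000.n_nodes <= 3600

    def test_all_regions_tagged(self, mesh3000):
        assert set(mesh3000.element_region) == set(ee.REGIONS_4)

    def test_positive_ccw_areas(self, mesh3000):
        assert np.all(mesh3000.element_areas() > 0)

    @pytest.mark.parametrize("region,area", [
        (MIDLINE, np.pi * 0.18 * 2.2),
        (INTERMEDIATE, np.pi * (0.23 * 2.25 - 0.18 * 2.2)),
        (AREA_PELLUCIDA, np.pi * (1.15 * 2.8 - 0.23 * 2.25)),
        (AREA_OPACA, np.pi * (25.0 - 1.15 * 2.8)),
    ])
    def test_region_area_resolved(self, mesh3000, region, area):
        assert mesh3000.region_area(region) == pytest.approx(area, rel=0.05)

    def test_boundary_nodes_on_circle(self, mesh3000):
        r = np.hypot(*mesh3000.nodes[mesh3000.boundary_nodes].T)
        assert np.all(np.abs(r - 5.0) < 1e-6)

    def test_deterministic(self, geometry):
        m1 = ee.generate_mesh(geometry, target_nodes=800, refine_points=[(0, 0)])
        m2 = ee.generate_mesh(geometry, target_nodes=800, refine_points=[(0, 0)])
        assert np.array_equal(m1.nodes, m2.nodes)
        assert np.array_equal(m1.triangles, m2.triangles)

    def test_degenerate_geometry_raises(self):
        g = ee.build_default_geometry(4, {
            "midline_semi_axes": (0.004, 2.2),
            "intermediate_semi_axes": (0.03, 2.25),
        })
        with pytest.raises(ee.MeshingError):
            ee.generate_mesh(g, target_nodes=500)

    def test_load_refinement_shrinks_local_edges(self, mesh3000):
        near = mesh3000.typical_edge_length(near=(0.0, 0.0))
        far = mesh3000.typical_edge_length(near=(3.0, 3.0))
        assert near < 0.02 < far


# ---------------------------------------------------------------------------
# plane-stress FEM
# ---------------------------------------------------------------------------

def _rect_patch():
    """Irregular triangulated rectangle for the patch test (mm)."""
    X, Y = np.meshgrid(np.linspace(0, 2.0, 5), np.linspace(0, 1.0, 4))
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    rng = np.random.default_rng(0)
    interior = (
        (nodes[:, 0] > 0) & (nodes[:, 0] < 2) & (nodes[:, 1] > 0) & (nodes[:, 1] < 1)
    )
    nodes[interior] += rng.uniform(-0.08, 0.08, (int(interior.sum()), 2))
    tris = Delaunay(nodes).simplices
    d1 = nodes[tris[:, 1]] - nodes[tris[:, 0]]
    d2 = nodes[tris[:, 2]] - nodes[tris[:, 0]]
    flip = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0] < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return nodes, tris


class TestSolver:
    def test_patch_test_machine_precision(self):
        """Uniform uniaxial traction reproduces the closed-form uniform strain."""
        nodes, tris = _rect_patch()
        E, nu, t_um, sigma = 2000.0, 0.3, 50.0, 10.0
        K = assemble_stiffness(
            nodes, tris, np.full(len(tris), E), np.full(len(tris), t_um), nu
        )
        f = np.zeros(2 * len(nodes))
        right = np.flatnonzero(np.isclose(nodes[:, 0], 2.0))
        rs = right[np.argsort(nodes[right, 1])]
        for a, b in zip(rs, rs[1:]):  # consistent nodal loads, N
            L = (nodes[b, 1] - nodes[a, 1]) * 1e-3
            f[2 * a] += sigma * t_um * 1e-6 * L / 2
            f[2 * b] += sigma * t_um * 1e-6 * L / 2
        fixed = np.concatenate([
            2 * np.flatnonzero(np.isclose(nodes[:, 0], 0.0)),
            2 * np.flatnonzero(np.isclose(nodes[:, 1], 0.0)) + 1,
        ])
        u = solve_displacement(K, f, fixed)
        expected_x = sigma / E * nodes[:, 0] * 1e-3
        expected_y = -nu * sigma / E * nodes[:, 1] * 1e-3
        assert np.allclose(u[0::2], expected_x, atol=1e-18)
        assert np.allclose(u[1::2], expected_y, atol=1e-18)

    def test_zero_force_gives_zero_field(self, mesh3000, geometry):
        load = ee.PointLoad((0.0, 0.0), (0.0, 0.0), force_min=0.0)
        op = ee.PlaneStressOperator(mesh3000, geometry, 0.3, load)
        u = op.solve_nodal(ee.DEFAULT_MODULI_PA).u
        assert np.all(u == 0.0)

    def test_force_linearity(self, geometry, mesh3000, materials):
        u1 = ee.solve_forward(mesh3000, materials, geometry, ee.midline_load(100.0)).u
        u2 = ee.solve_forward(mesh3000, materials, geometry, ee.midline_load(200.0)).u
        assert np.allclose(u2, 2.0 * u1, rtol=1e-10, atol=1e-12)

    def test_boundary_clamped(self, midline_op):
        nf = midline_op.solve_nodal(ee.DEFAULT_MODULI_PA)
        assert np.all(nf.u[midline_op.mesh.boundary_nodes] == 0.0)

    def test_force_out_of_sanity_range_rejected(self):
        with pytest.raises(ValueError, match="sanity"):
            ee.PointLoad((0.0, 0.0), (0.0, -1e-3))

    def test_single_region_disc_monotone_decay_and_refinement(self, homogeneous_disc):
        """Displacement along the force decays monotonically to the clamped rim;
        a 4x-refined solve confirms the value at r = 1 mm within 2 %."""
        geom, moduli = homogeneous_disc
        load = ee.PointLoad((0.0, 0.0), (0.0, -200e-9))
        probes = np.column_stack([
            np.zeros(8), -np.array([0.3, 0.6, 1.0, 1.5, 2.5, 3.5, 4.5, 4.99])
        ])
        values = {}
        for target in (3000, 12000):
            mesh = ee.generate_mesh(geom, target_nodes=target, refine_points=[(0, 0)])
            op = ee.PlaneStressOperator(mesh, geom, 0.3, load)
            nf = op.solve_nodal(moduli)
            values[target] = ee.interpolate_at_points(nf, mesh, probes)[:, 1]
        uy = values[3000]
        assert np.all(uy < 0)  # along the caudal force
        assert np.all(np.diff(-uy) < 0)  # monotone decay outward
        assert -uy[-1] < 0.02 * -uy[0]  # nearly zero at the rim
        assert values[3000][2] == pytest.approx(values[12000][2], rel=0.02)

    def test_mesh_convergence_at_probe_points(self, geometry, materials):
        """Probes 0.5 mm from the load move < 1 % between 3000 and 12000 nodes."""
        load = ee.midline_load(190.0)
        probes = np.array([[0.5, 0.0], [0.0, -0.5], [-0.35, 0.35]])
        out = {}
        for target in (3000, 12000):
            mesh = ee.generate_mesh(geometry, target_nodes=target,
                                    refine_points=[(0.0, 0.0)])
            nf = ee.solve_forward(mesh, materials, geometry, load)
            out[target] = ee.interpolate_at_points(nf, mesh, probes)
        mag_c = np.hypot(*out[3000].T)
        mag_f = np.hypot(*out[12000].T)
        assert np.all(np.abs(mag_c - mag_f) / mag_f < 0.01)

    def test_mirror_symmetry_on_symmetric_mesh(self, geometry, materials):
        """Midline AP force: u_y even and u_x odd under x -> -x."""
        mesh = ee.generate_mesh(geometry, target_nodes=3000,
                                refine_points=[(0.0, 0.0)], symmetric=True)
        nf = ee.solve_forward(mesh, materials, geometry, ee.midline_load(190.0))
        xs = np.linspace(0.06, 0.42, 7)
        ys = np.linspace(-0.3, 0.3, 7)
        X, Y = np.meshgrid(xs, ys)
        right = np.column_stack([X.ravel(), Y.ravel()])
        left = right * np.array([-1.0, 1.0])
        ur = ee.interpolate_at_points(nf, mesh, right)
        ul = ee.interpolate_at_points(nf, mesh, left)
        scale = np.max(np.abs(ur))
        assert np.allclose(ul[:, 1], ur[:, 1], atol=0.02 * scale)
        assert np.allclose(ul[:, 0], -ur[:, 0], atol=0.02 * scale)

    def test_thickness_modulus_degeneracy(self, geometry, mesh3000, materials):
        """Only E*t per region is constrained: scaling t by c and E by 1/c
        leaves the displacement field unchanged."""
        c = 3.7
        thick = {k: v * c for k, v in geometry.thicknesses.items()}
        geom2 = ee.RegionGeometry(
            midline_semi_axes=geometry.midline_semi_axes,
            pellucida_semi_axes=geometry.pellucida_semi_axes,
            outer_radius=geometry.outer_radius,
            thicknesses=thick,
            intermediate_semi_axes=geometry.intermediate_semi_axes,
        )
        moduli2 = {k: v / c for k, v in materials.youngs_moduli.items()}
        u1 = ee.solve_forward(mesh3000, materials, geometry, ee.midline_load(190.0)).u
        u2 = ee.solve_forward(
            mesh3000, ee.MaterialParams(moduli2, 0.3), geom2, ee.midline_load(190.0)
        ).u
        assert np.allclose(u1, u2, rtol=1e-9, atol=1e-12)

    def test_poisson_insensitivity(self, geometry, mesh3000):
        """Varying nu over [0.1, 0.4] changes the lattice field < 10 % in
        relative RMS against the nu = 0.3 baseline."""
        lat = ee.default_lattice()
        load = ee.midline_load(190.0)
        grids = {}
        for nu in (0.3, 0.1, 0.2, 0.4):
            op = ee.PlaneStressOperator(mesh3000, geometry, nu, load, lattice=lat)
            grids[nu] = op.solve_grid(ee.DEFAULT_MODULI_PA)
        base = grids[0.3]
        for nu in (0.1, 0.2, 0.4):
            diff = np.sqrt(np.mean(np.sum((grids[nu].u - base.u) ** 2, axis=-1)))
            assert diff / base.rms() < 0.10


# ---------------------------------------------------------------------------
# analytic point-force solution
# ---------------------------------------------------------------------------

class TestAnalytic:
    F = (0.0, -200e-9)
    pars = dict(E=2000.0, nu=0.3, thickness_um=50.0)

    def test_monotone_log_decay_along_force_line(self):
        r = np.geomspace(0.05, 4.0, 12)
        pts = np.column_stack([np.zeros_like(r), -r])
        u = ee.analytic_point_force_plane_stress(
            force_vector=self.F, eval_points_mm=pts, **self.pars
        )
        diffs = np.diff(u[:, 1])
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_far_field_diverges_logarithmically(self):
        r = np.array([10.0, 100.0, 1000.0, 1e5])
        pts = np.column_stack([np.zeros_like(r), -r])
        u = ee.analytic_point_force_plane_stress(
            force_vector=self.F, eval_points_mm=pts, **self.pars
        )
        # unbounded below along the force direction, linear in log r
        assert np.all(np.diff(u[:, 1]) > 0)  # -u grows
        assert u[-1, 1] > 0  # sign flips: displacement "below negative infinity" trend
        steps = np.diff(u[:, 1]) / np.diff(np.log(r))
        assert steps == pytest.approx(steps[0] * np.ones_like(steps), rel=1e-6)

    def test_transverse_antisymmetry(self):
        pts = np.array([[0.7, 0.9], [-0.7, 0.9]])
        u = ee.analytic_point_force_plane_stress(
            force_vector=self.F, eval_points_mm=pts, **self.pars
        )
        assert u[0, 0] == pytest.approx(-u[1, 0], rel=1e-12)
        assert u[0, 1] == pytest.approx(u[1, 1], rel=1e-12)

    def test_singularity_rejected(self):
        with pytest.raises(ee.OutOfDomainError):
            ee.analytic_point_force_plane_stress(
                force_vector=self.F, eval_points_mm=np.array([[0.0, 0.0]]),
                **self.pars,
            )

    def test_matches_large_domain_fem_near_load(self, homogeneous_disc):
        """Within 5 % of a clamped-disc FEM solve on a 10x larger domain."""
        regions = list(ee.REGIONS_4)
        geom = ee.RegionGeometry(
            midline_semi_axes=(0.18, 2.2), pellucida_semi_axes=(1.15, 2.8),
            outer_radius=50.0, thicknesses={r: 50.0 for r in regions},
            intermediate_semi_axes=(0.23, 2.25),
        )
        moduli = {r: 2000.0 for r in regions}
        load = ee.PointLoad((0.0, 0.0), self.F)
        mesh = ee.generate_mesh(geom, target_nodes=6000, refine_points=[(0, 0)])
        op = ee.PlaneStressOperator(mesh, geom, 0.3, load)
        nf = op.solve_nodal(moduli)
        pts = np.array([[0.0, -1.0], [0.0, -2.0], [1.0, 0.0]])
        u_fem = ee.interpolate_at_points(nf, mesh, pts)
        u_an = ee.analytic_point_force_plane_stress(
            force_vector=self.F, eval_points_mm=pts, cutoff_radius_mm=50.0,
            **self.pars,
        )
        assert np.allclose(u_fem[:, 1], u_an[:, 1], rtol=0.05)


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

class TestInterpolation:
    def test_nodal_values_exact_at_nodes(self, mesh3000, midline_op):
        nf = midline_op.solve_nodal(ee.DEFAULT_MODULI_PA)
        idx = np.array([10, 500, 1500])
        vals = ee.interpolate_at_points(nf, mesh3000, mesh3000.nodes[idx])
        assert np.allclose(vals, nf.u[idx], atol=1e-9)

    def test_constant_field_reproduced(self, mesh3000):
        nf = ee.NodalField(u=np.full((mesh3000.n_nodes, 2), 1.25))
        grid = ee.interpolate_to_grid(nf, mesh3000, ee.default_lattice())
        assert np.allclose(grid.u[grid.valid], 1.25)

    def test_affine_field_reproduced_exactly(self, mesh3000):
        """Linear elements reproduce u = a + B x at every lattice point."""
        a = np.array([0.3, -0.2])
        B = np.array([[1.2, -0.4], [0.7, 2.1]])
        nf = ee.NodalField(u=a + mesh3000.nodes @ B.T)
        lat = ee.default_lattice(center=(0.2, -0.1))
        grid = ee.interpolate_to_grid(nf, mesh3000, lat)
        expected = a + lat.points() @ B.T
        assert np.allclose(grid.u.reshape(-1, 2), expected, atol=1e-10)

    def test_outside_points_flagged_missing(self, mesh3000):
        nf = ee.NodalField(u=np.zeros((mesh3000.n_nodes, 2)))
        lat = ee.Lattice(x=np.array([0.0, 7.0]), y=np.array([0.0]))
        grid = ee.interpolate_to_grid(nf, mesh3000, lat)
        assert bool(grid.valid[0, 0]) is True
        assert bool(grid.valid[0, 1]) is False
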