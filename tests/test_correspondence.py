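"""Cuts, conformal parameterization, grid resampling, fluid registration."""

import numpy as np
import pytest
import trimesh
from conftest import open_cylinder

from tubemorph.correspondence import (GridSurface,
                                      compute_cuts, conformal_parameterize,
                                      fluid_register,
                                      quasi_conformal_dilatation,
                                      resample_to_grid)
from tubemorph.errors import AmbiguityError, ParameterError, TopologyError
from tubemorph.mesh import check_topology


class TestComputeCuts:
    def test_capped_cylinder_becomes_annulus(self, template_tube):
        om = compute_cuts(template_tube, 0.02)
        m = trimesh.Trimesh(vertices=om.vertices, faces=om.faces,
                            process=False)
        rep = check_topology(m)
        assert rep.euler == 0 and rep.n_boundary_loops == 2

    def test_sphere_raises_ambiguity(self, icosphere):
        with pytest.raises(AmbiguityError):
            compute_cuts(icosphere, 0.02)

    def test_cut_labels_follow_axis_sign(self, template_tube):
        om = compute_cuts(template_tube, 0.02)
        proj_a = om.vertices[om.anterior_loop] @ om.principal_axis
        proj_p = om.vertices[om.posterior_loop] @ om.principal_axis
        assert proj_a.mean() > proj_p.mean()

    def test_cuts_near_tube_ends(self, template_tube):
        """Both cut loops lie within the end 10% of the generating
        centerline's arclength."""
        centerline = template_tube.metadata["tube"]["centerline"]
        om = compute_cuts(template_tube, 0.02)
        seg = np.linalg.norm(np.diff(centerline, axis=0), axis=1)
        arc = np.concatenate([[0], np.cumsum(seg)])
        arc /= arc[-1]
        from scipy.spatial import cKDTree

        tree = cKDTree(centerline)
        for loop, end in ((om.posterior_loop, 0.0), (om.anterior_loop, 1.0)):
            _, nearest = tree.query(om.vertices[loop])
            assert np.abs(arc[nearest] - end).max() < 0.10

    def test_bad_fraction_rejected(self, template_tube):
        with pytest.raises(ParameterError):
            compute_cuts(template_tube, 0.7)

    def test_open_input_rejected(self):
        om = open_cylinder(8, 10)
        m = trimesh.Trimesh(vertices=om.vertices, faces=om.faces,
                            process=False)
        with pytest.raises(TopologyError):
            compute_cuts(m, 0.02)


class TestConformalParameterize:
    @pytest.fixture(scope="class")
    def cyl_param(self):
        om = open_cylinder(n_rings=40, n_around=36, radius=5.0, length=30.0)
        return om, conformal_parameterize(om)

    def test_u_matches_axial_coordinate(self, cyl_param):
        om, ps = cyl_param
        u_true = om.vertices[:, 2] / 30.0
        assert np.abs(ps.u - u_true).max() < 1e-6

    def test_u_boundary_values_exact(self, cyl_param):
        om, ps = cyl_param
        assert ps.u.min() == 0.0 and ps.u.max() == 1.0
        assert np.all(ps.u[om.posterior_loop] == 0.0)
        assert np.all(ps.u[om.anterior_loop] == 1.0)

    def test_v_matches_angle_up_to_gauge(self, cyl_param):
        om, ps = cyl_param
        theta = np.mod(np.arctan2(om.vertices[:, 1], om.vertices[:, 0])
                       / (2 * np.pi), 1.0)
        errs = []
        for sign in (1.0, -1.0):
            d = np.mod(sign * ps.v - theta, 1.0)
            d = np.mod(d - np.median(d) + 0.5, 1.0) - 0.5
            errs.append(np.abs(d).max())
        assert min(errs) < 1e-3

    def test_anchor_has_zero_v(self, cyl_param):
        _, ps = cyl_param
        assert ps.v[ps.anchor_vertex] == pytest.approx(0.0, abs=1e-12)

    def test_parameter_area_accounts_for_unit_domain(self, cyl_param):
        _, ps = cyl_param
        uv = ps.face_uv()
        e1 = uv[:, 1] - uv[:, 0]
        e2 = uv[:, 2] - uv[:, 0]
        area = 0.5 * np.abs(e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]).sum()
        assert area == pytest.approx(1.0, abs=1e-6)

    def test_template_dilatation_is_moderate(self, template_tube):
        ps = conformal_parameterize(compute_cuts(template_tube, 0.02))
        K = quasi_conformal_dilatation(ps)
        assert np.percentile(K, 95) < 1.5

    def test_conformal_factor_recovers_cylinder_area_scale(self, cyl_param):
        om, ps = cyl_param
        # total 3D area / unit parameter area = 2 pi r L
        total = 2 * np.pi * 5.0 * 30.0
        interior = (ps.u > 0.1) & (ps.u < 0.9)
        polygon_factor = np.sinc(1.0 / 36)  # 36-gon chord deficit
        assert np.median(ps.conformal_factor[interior]) == pytest.approx(
            total * polygon_factor, rel=0.02)


class TestResampleToGrid:
    def test_default_grid_size_is_15000(self):
        from tubemorph.correspondence import DEFAULT_GRID

        assert DEFAULT_GRID[0] * DEFAULT_GRID[1] == 15_000

    def test_cylinder_positions_on_surface(self):
        om = open_cylinder(n_rings=60, n_around=200, radius=5.0, length=30.0)
        ps = conformal_parameterize(om)
        grid = resample_to_grid(ps, 20, 40)
        r = np.linalg.norm(grid.positions[..., :2], axis=-1)
        assert np.abs(r - 5.0).max() < 1e-3 * 5.0

    def test_tiny_grid_inside_bbox(self, template_tube):
        ps = conformal_parameterize(compute_cuts(template_tube, 0.02))
        grid = resample_to_grid(ps, 2, 4)
        assert grid.n_vertices == 8
        lo = template_tube.bounds[0] - 1e-6
        hi = template_tube.bounds[1] + 1e-6
        pos = grid.positions.reshape(-1, 3)
        assert (pos >= lo).all() and (pos <= hi).all()

    def test_full_coverage_on_clean_tube(self, template_grid):
        assert template_grid.fallback_nodes == 0


class TestFluidRegister:
    def test_identity_gives_zero_displacement(self, template_grid):
        field = fluid_register(template_grid, template_grid)
        assert np.abs(field.forward).max() < 1e-8
        assert np.abs(field.backward).max() < 1e-8

    def test_recovers_periodic_shift_within_half_cell(self, template_grid):
        n_v = template_grid.shape[1]
        rolled = GridSurface(
            positions=np.roll(template_grid.positions, 3, axis=1),
            conformal_factor=np.roll(template_grid.conformal_factor, 3, axis=1),
            mean_curvature=np.roll(template_grid.mean_curvature, 3, axis=1))
        field = fluid_register(rolled, template_grid)
        # rolled[:, j] = template[:, j-3], so the template->source map
        # shifts the angular coordinate by +3 cells
        dv_cells = field.backward[..., 1] * n_v
        assert abs(np.median(dv_cells) - 3.0) < 0.5

    def test_inverse_consistency_on_swap(self, small_cohort, template_grid):
        from tubemorph.correspondence import (compute_cuts,
                                              conformal_parameterize)

        mesh = small_cohort.meshes[0]
        ps = conformal_parameterize(compute_cuts(mesh))
        grid = resample_to_grid(ps, *template_grid.shape)
        fwd = fluid_register(grid, template_grid)
        assert fwd.ic_p95 <= 3 * fwd.params.ic_tol
        # swapping source and target swaps the field roles (within the
        # inverse-consistency bound)
        bwd = fluid_register(template_grid, grid)
        diff = fwd.forward - bwd.backward
        n_u, n_v = template_grid.shape
        cells = np.abs(diff) * np.array([n_u - 1, n_v])
        assert np.percentile(cells, 95) < 5 * fwd.params.ic_tol

    def test_metric_decreases_monotonically(self, small_cohort,
                                            template_grid):
        from tubemorph.correspondence import (compute_cuts,
                                              conformal_parameterize)

        ps = conformal_parameterize(compute_cuts(small_cohort.meshes[1]))
        grid = resample_to_grid(ps, *template_grid.shape)
        field = fluid_register(grid, template_grid)
        for trace in (field.convergence["forward_ssd"],
                      field.convergence["backward_ssd"]):
            assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_shape_mismatch_rejected(self, template_grid):
        small = GridSurface(positions=template_grid.positions[:10],
                            conformal_factor=template_grid.conformal_factor[:10],
                            mean_curvature=template_grid.mean_curvature[:10])
        with pytest.raises(ParameterError):
            fluid_register(small, template_grid)
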