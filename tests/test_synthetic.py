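"""Synthetic tube cohorts: geometry, dose structure, reproducibility."""

import numpy as np
import pytest

from tubemorph.errors import EmptyInputError, ParameterError, TopologyError
from tubemorph.mesh import check_topology, mesh_volume
from tubemorph.synthetic import (CohortSpec, make_cohort, make_demographics,
                                 make_template_tube, rasterize_mesh)


class TestTemplateTube:
    def test_closed_genus_zero(self, template_tube):
        rep = check_topology(template_tube)
        assert rep.is_closed and rep.euler == 2 and rep.is_oriented

    def test_straight_tube_volume_vs_voxel_oracle(self):
        tube = make_template_tube(50, 30, length=40.0, radius_profile=5.0,
                                  bend=0.0, ellipticity=0.0)
        vm = mesh_volume(tube)
        # analytic: pi r^2 L times the 30-gon area deficit; fan caps add ~0
        analytic = np.pi * 25 * 40
        assert abs(vm / analytic - 1) < 0.03
        vox = rasterize_mesh(tube, voxel_size=0.2)
        assert abs(vox.volume() / vm - 1) < 0.03

    def test_determinism(self):
        a = make_template_tube(20, 12, 10.0, 2.0, seed=5, jitter=0.1)
        b = make_template_tube(20, 12, 10.0, 2.0, seed=5, jitter=0.1)
        assert np.array_equal(a.vertices, b.vertices)

    def test_invalid_dimensions_raise(self):
        with pytest.raises(ParameterError):
            make_template_tube(2, 30)
        with pytest.raises(ParameterError):
            make_template_tube(10, 10, length=-1.0)
        with pytest.raises(ParameterError):
            make_template_tube(10, 10, radius_profile=lambda t: t - 0.5)


class TestRasterizeMesh:
    def test_unit_cube_volume_within_5_percent(self):
        import trimesh

        cube = trimesh.creation.box((1.0, 1.0, 1.0))
        vol = rasterize_mesh(cube, voxel_size=0.1)
        assert abs(vol.volume() - 1.0) < 0.05

    def test_sphere_volume_within_3_percent(self):
        import trimesh

        sph = trimesh.creation.icosphere(subdivisions=4, radius=5.0)
        vol = rasterize_mesh(sph, voxel_size=0.25)
        assert abs(vol.volume() / (4 / 3 * np.pi * 125) - 1) < 0.03

    def test_empty_and_open_meshes_raise(self):
        import trimesh

        with pytest.raises(EmptyInputError):
            rasterize_mesh(trimesh.Trimesh(), 0.5)
        cube = trimesh.creation.box((1, 1, 1))
        open_mesh = trimesh.Trimesh(vertices=cube.vertices,
                                    faces=cube.faces[:-1], process=False)
        with pytest.raises(TopologyError):
            rasterize_mesh(open_mesh, 0.5)


class TestCohortSpec:
    def test_default_group_sizes_match_study(self):
        spec = CohortSpec()
        assert spec.group_sizes == {"NC": 44, "HT": 36, "HM": 37}

    def test_monotone_dose_enforced(self):
        with pytest.raises(ParameterError):
            CohortSpec(effect_magnitudes={"NC": 0.5, "HT": 0.2,
                                          "HM": 0.8}).validate()

    def test_small_group_rejected(self):
        with pytest.raises(ParameterError):
            CohortSpec(group_sizes={"NC": 1, "HT": 4, "HM": 4}).validate()


class TestMakeCohort:
    def test_meshes_closed_and_labelled(self, small_cohort):
        assert len(small_cohort.meshes) == 16
        for mesh, label in zip(small_cohort.meshes, small_cohort.labels):
            assert mesh.metadata["group"] == label
            rep = check_topology(mesh)
            assert rep.is_closed and rep.euler == 2

    def test_reproducible_from_seed(self):
        spec = CohortSpec(group_sizes={"NC": 3, "HT": 2, "HM": 2}, seed=9)
        a = make_cohort(spec)
        b = make_cohort(spec)
        for ma, mb in zip(a.meshes, b.meshes):
            assert np.array_equal(ma.vertices, mb.vertices)

    def test_null_cohort_has_empty_truth_mask(self):
        spec = CohortSpec(group_sizes={"NC": 2, "HT": 2, "HM": 2},
                          effect_magnitudes={"NC": 0, "HT": 0, "HM": 0},
                          seed=1)
        cohort = make_cohort(spec)
        assert not cohort.truth_mask.any()

    def test_truth_mask_nonempty_with_effect(self, small_cohort):
        assert small_cohort.truth_mask.sum() > 0

    def test_volume_ordering_follows_dose(self):
        spec = CohortSpec(group_sizes={"NC": 14, "HT": 14, "HM": 14},
                          effect_magnitudes={"NC": 0.0, "HT": 0.4, "HM": 0.8},
                          patch_radius=0.15, subject_variability_sd=0.15,
                          seed=4)
        cohort = make_cohort(spec)
        vols = {}
        for mesh, label in zip(cohort.meshes, cohort.labels):
            vols.setdefault(label, []).append(mesh_volume(mesh))
        means = {g: np.mean(v) for g, v in vols.items()}
        assert means["NC"] >= means["HT"] >= means["HM"]


class TestMakeDemographics:
    def test_shape_and_determinism(self):
        a = make_demographics({"NC": 5, "HT": 4, "HM": 4}, seed=3)
        b = make_demographics({"NC": 5, "HT": 4, "HM": 4}, seed=3)
        assert len(a) == 13
        assert a.equals(b)
        assert {"age", "education", "mmse", "avlt_ltm", "sex"} <= set(a.columns)

    def test_bad_sex_probabilities_raise(self):
        dists = {"age": {"NC": (50, 5), "HT": (50, 5)},
                 "sex": {"NC": {"male": 0.7, "female": 0.7},
                         "HT": {"male": 0.5, "female": 0.5}}}
        with pytest.raises(ParameterError):
            make_demographics({"NC": 4, "HT": 4}, dists, seed=0)

    def test_identical_distributions_reject_near_nominal_rate(self):
        """ANOVA on identically distributed groups rejects ~5% of the time."""
        from tubemorph.cohort import anova_from_raw

        rng_rejections = 0
        n_rep = 400
        dists = {"age": {"NC": (60, 5), "HT": (60, 5), "HM": (60, 5)}}
        for rep in range(n_rep):
            df = make_demographics({"NC": 10, "HT": 10, "HM": 10},
                                   dists, seed=rep)
            groups = [df.loc[df.group == g, "age"].values
                      for g in ("NC", "HT", "HM")]
            if anova_from_raw(groups).p < 0.05:
                rng_rejections += 1
        rate = rng_rejections / n_rep
        assert 0.02 < rate < 0.09      # binomial 99% band around 0.05

    def test_separated_means_always_detected(self):
        dists = {"age": {"NC": (50, 2), "HT": (56, 2), "HM": (62, 2)}}
        from tubemorph.cohort import anova_from_raw

        for rep in range(20):
            df = make_demographics({"NC": 10, "HT": 10, "HM": 10},
                                   dists, seed=1000 + rep)
            groups = [df.loc[df.group == g, "age"].values
                      for g in ("NC", "HT", "HM")]
            assert anova_from_raw(groups).p < 0.001
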