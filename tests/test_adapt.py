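"""Geometric adaptation: displacement, BEV transform, energy update, pattern rule."""

import numpy as np
import pytest

from arcadapt import (
    DeformationField,
    EnergyPattern,
    adapt_cluster_energies,
    bev_transform,
    default_machine_energies,
    displace_spot_bragg_positions,
    geometric_adapt,
    make_deformation_field,
    required_energies,
    switch_up_angles,
    warp_grid,
)
from arcadapt.adapt import AdaptationReport, ClusterOrderError
from arcadapt.dose import compute_influence_matrix, total_dose


def _zero_field(grid):
    return DeformationField(
        vectors=np.zeros(grid.shape + (3,), dtype=np.float32),
        spacing=grid.spacing, origin=grid.origin,
    )


class TestBevTransform:
    def test_angle_zero_posterior_point(self):
        iso = np.zeros(3)
        x, y, depth = bev_transform(np.array([0.0, 10.0, 0.0]), 0.0, iso)
        assert (x, y) == (0.0, 0.0)
        assert depth == pytest.approx(10.0)

    def test_round_trip_is_identity(self):
        rng = np.random.default_rng(3)
        iso = np.array([5.0, -2.0, 11.0])
        for _ in range(100):
            p = rng.uniform(-100, 100, 3)
            ang = float(rng.uniform(0, 360))
            bev = bev_transform(p, ang, iso)
            back = bev_transform(np.asarray(bev), ang, iso, direction="bev_to_patient")
            assert np.max(np.abs(back - p)) < 1e-9

    def test_opposed_angles_negate_depth(self):
        iso = np.zeros(3)
        p = np.array([3.0, 17.0, -4.0])
        d0 = bev_transform(p, 0.0, iso)[2]
        d180 = bev_transform(p, 180.0, iso)[2]
        assert d180 == pytest.approx(-d0)


class TestDisplacement:
    def test_zero_field_keeps_positions(self, small_phantom, small_plan):
        grid, _ = small_phantom
        pos = displace_spot_bragg_positions(small_plan, grid, _zero_field(grid))
        pos2 = displace_spot_bragg_positions(small_plan, grid, _zero_field(grid))
        for sid in pos:
            assert np.array_equal(pos[sid].xyz, pos2[sid].xyz)

    def test_constant_field_shifts_exactly(self, small_phantom, small_plan):
        grid, _ = small_phantom
        vec = np.zeros(grid.shape + (3,), dtype=np.float32)
        vec[..., 0] = 8.0
        fld = DeformationField(vectors=vec, spacing=grid.spacing, origin=grid.origin)
        p0 = displace_spot_bragg_positions(small_plan, grid, _zero_field(grid))
        p1 = displace_spot_bragg_positions(small_plan, grid, fld)
        for sid in p0:
            assert np.allclose(p1[sid].xyz - p0[sid].xyz, [8.0, 0.0, 0.0], atol=1e-5)

    def test_shrink_contracts_toward_centroid(self, small_phantom, small_plan):
        grid, structures = small_phantom
        fld = make_deformation_field(grid, "target_shrink", 0.2, structures)
        t = structures.mask("target_high")
        c = grid.index_to_world(np.argwhere(t).mean(axis=0))
        p0 = displace_spot_bragg_positions(small_plan, grid, _zero_field(grid))
        p1 = displace_spot_bragg_positions(small_plan, grid, fld)
        d0 = np.mean([np.linalg.norm(p0[s].xyz - c) for s in p0])
        d1 = np.mean([np.linalg.norm(p1[s].xyz - c) for s in p1])
        assert d1 < d0


class TestRequiredEnergies:
    def test_identity_recovers_original_energies(self, small_phantom, small_plan, model):
        grid, _ = small_phantom
        pos = displace_spot_bragg_positions(small_plan, grid, _zero_field(grid))
        energies = required_energies(pos, grid, small_plan, model)
        for s in small_plan.spots:
            assert energies[s.id] == pytest.approx(s.energy, abs=0.5)

    def test_deeper_peak_in_water(self, water_grid, model, small_plan):
        """Uniform water: pushing the peak 10 mm deeper needs the energy whose
        range is 10 mm longer."""
        from arcadapt.adapt import SpotPosition
        from arcadapt.plan import ArcPlan, ControlPoint, Spot

        e_old = 100.0
        plan = ArcPlan(
            control_points=[ControlPoint(0, 90.0, [e_old])],
            spots=[Spot(0, 0, 0.0, 0.0, e_old, 1.0, 0)],
            isocenter=np.zeros(3),
            machine_energies=default_machine_energies(),
        )
        from arcadapt import bragg_peak_position
        from arcadapt.dose import spot_ray

        o, u = spot_ray(90.0, 0.0, 0.0, np.zeros(3))
        p = bragg_peak_position(water_grid, o - 300 * u, u, e_old, model)
        pos = {0: SpotPosition(0, p + 10.0 * u, "ct2")}
        e_new = required_energies(pos, water_grid, plan, model)[0]
        expected = float(model.energy_mev(float(model.range_mm(e_old)) + 10.0))
        assert e_new == pytest.approx(expected, abs=0.5)

    def test_out_of_machine_interval_clamped_and_flagged(self, water_grid, model):
        from arcadapt.adapt import SpotPosition
        from arcadapt.plan import ArcPlan, ControlPoint, Spot

        plan = ArcPlan(
            control_points=[ControlPoint(0, 90.0, [70.0])],
            spots=[Spot(0, 0, 0.0, 0.0, 70.0, 1.0, 0)],
            isocenter=np.zeros(3),
            machine_energies=default_machine_energies(),
        )
        # displaced peak 2 mm past the entry surface: required range << R(70 MeV)
        lo = water_grid.bounding_box()[0]
        shallow = np.array([lo[0] + 2.0, 0.0, 0.0])
        report = AdaptationReport()
        e = required_energies({0: SpotPosition(0, shallow, "ct2")}, water_grid, plan,
                              model, report=report)
        assert e[0] == model.energy_min
        assert any("clamped" in f for f in report.flags[0])


class TestClusterEnergyRule:
    ME = default_machine_energies()

    def test_identity_keeps_pattern(self):
        pattern = EnergyPattern([(0, 150.0), (1, 148.0), (2, 150.0)])
        clusters = [[150.0], [148.0], [150.0]]
        updates, adapted = adapt_cluster_energies(clusters, pattern, self.ME)
        assert adapted == pattern
        assert [u.assigned_energy for u in updates] == [150.0, 148.0, 150.0]

    def test_illegal_up_switch_flattened(self):
        # initial (150, 148): no switch-up; updated medians (149, 151)
        pattern = EnergyPattern([(0, 150.0), (1, 148.0)])
        updates, adapted = adapt_cluster_energies([[149.0], [151.0]], pattern, self.ME)
        # 149 snaps down to 148 (tie toward lower); 152 > 148 is illegal -> flattened
        assert [u.assigned_energy for u in updates] == [148.0, 148.0]
        assert switch_up_angles(adapted) == set()

    def test_authorized_switch_up_kept(self):
        pattern = EnergyPattern([(0, 150.0), (1, 140.0), (2, 146.0)])  # up at index 2
        clusters = [[150.0], [140.0], [152.0]]
        updates, adapted = adapt_cluster_energies(clusters, pattern, self.ME)
        assert updates[2].assigned_energy == 152.0
        assert switch_up_angles(adapted) == {2}

    def test_chained_illegal_increases_collapse_to_plateau(self):
        pattern = EnergyPattern([(0, 150.0), (1, 148.0), (2, 146.0)])
        clusters = [[144.0], [148.0], [152.0]]
        updates, adapted = adapt_cluster_energies(clusters, pattern, self.ME)
        assert [u.assigned_energy for u in updates] == [144.0, 144.0, 144.0]

    def test_first_cluster_median_always_accepted(self):
        pattern = EnergyPattern([(0, 100.0), (1, 98.0)])
        updates, _ = adapt_cluster_energies([[130.0], [98.0]], pattern, self.ME)
        assert updates[0].assigned_energy == 130.0

    def test_lower_median_for_even_clusters(self):
        pattern = EnergyPattern([(0, 100.0)])
        updates, _ = adapt_cluster_energies([[96.0, 102.0]], pattern, self.ME)
        assert updates[0].median_energy == 96.0

    def test_cluster_count_mismatch_raises(self):
        pattern = EnergyPattern([(0, 100.0), (1, 98.0)])
        with pytest.raises(ClusterOrderError):
            adapt_cluster_energies([[100.0]], pattern, self.ME)


class TestGeometricAdapt:
    def test_identity_is_fixed_point(self, small_phantom, small_plan):
        grid, _ = small_phantom
        plan2, report = geometric_adapt(small_plan, grid, grid, _zero_field(grid))
        for a, b in zip(small_plan.spots, plan2.spots):
            assert a.energy == b.energy
            assert a.weight == b.weight
            assert abs(a.x_bev - b.x_bev) < 1e-6 and abs(a.y_bev - b.y_bev) < 1e-6
        assert plan2.energy_pattern() == small_plan.energy_pattern()

    def test_weights_never_change(self, small_phantom, small_plan):
        grid, structures = small_phantom
        fld = make_deformation_field(grid, "target_shift", 6.0, structures, seed=3)
        grid2 = warp_grid(grid, fld)
        plan2, _ = geometric_adapt(small_plan, grid, grid2, fld)
        assert np.array_equal(plan2.weights(), small_plan.weights())

    def test_cluster_cohesion(self, small_phantom, small_plan):
        grid, structures = small_phantom
        fld = make_deformation_field(grid, "target_shift", 6.0, structures, seed=5)
        plan2, _ = geometric_adapt(small_plan, grid, warp_grid(grid, fld), fld)
        for spots in plan2.spots_by_cluster().values():
            assert len({s.energy for s in spots}) == 1

    def test_rigid_shift_translation_equivariance(self, model):
        """A global 8 mm translation with the matching synthetic CT2: the
        adapted plan's dose equals the original dose translated by 8 mm."""
        from arcadapt import PhantomConfig, make_initial_plan, make_phantom

        grid, structures = make_phantom(PhantomConfig(
            shape=(48, 48, 48), spacing=(2.0, 2.0, 2.0), target_high_radius_mm=12.0,
            target_low_semiaxes_mm=None, oar_offset_mm=22.0, oar_halflength_mm=30.0,
            rsp_noise_sd=0.0, center_jitter_mm=0.0, seed=0,
        ))
        shift_vox = 4  # 8 mm in x
        vec = np.zeros(grid.shape + (3,), dtype=np.float32)
        vec[..., 0] = 8.0
        fld = DeformationField(vectors=vec, spacing=grid.spacing, origin=grid.origin)
        grid2 = warp_grid(grid, fld)
        plan1 = make_initial_plan(structures, grid, n_control_points=8,
                                  lateral_spacing_mm=8.0, margin_mm=2.0,
                                  max_switch_ups=2)
        plan2, _ = geometric_adapt(plan1, grid, grid2, fld)
        w = np.ones(len(plan1.spots))
        d1 = total_dose(compute_influence_matrix(plan1, grid, model=model), w)
        d2 = total_dose(compute_influence_matrix(plan2, grid2, model=model), w)
        d1_shifted = np.roll(d1, shift_vox, axis=0)
        t = structures.mask("target_high")
        t_shifted = np.roll(t, shift_vox, axis=0)
        num = np.abs(d2[t_shifted] - d1_shifted[t_shifted])
        assert np.median(num / d1_shifted[t_shifted]) < 0.02
        assert np.percentile(num / d1_shifted[t_shifted], 95) < 0.05

    @pytest.mark.parametrize("seed", range(6))
    def test_pattern_preservation_random_fields(self, small_phantom, small_plan, seed):
        grid, structures = small_phantom
        kind = ["target_shift", "rigid_shift", "target_shrink"][seed % 3]
        mag = 0.15 if kind == "target_shrink" else 7.0
        fld = make_deformation_field(grid, kind, mag, structures, seed=seed)
        plan2, _ = geometric_adapt(small_plan, grid, warp_grid(grid, fld), fld)
        assert switch_up_angles(plan2.energy_pattern()) <= switch_up_angles(
            small_plan.energy_pattern()
        )
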