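"""Objective, gradient, two-criteria selection and restricted re-optimization."""

import numpy as np
import pytest
from scipy import sparse

from arcadapt import (
    ObjectiveSpec,
    ObjectiveTerm,
    ScenarioSet,
    SelectionConfig,
    full_optimize,
    objective_gradient,
    objective_value,
    reoptimize_weights,
    select_by_gradient,
    select_by_weight,
    select_spots,
)
from arcadapt.dose import DoseInfluenceMatrix
from arcadapt.optimize import (
    ObjectiveSpecError,
    ObjectiveWorkspace,
    SelectionError,
    SelectionResult,
)
from arcadapt.phantom import StructureSet


def _toy_matrix(D: np.ndarray, scenario_id: int = 0) -> DoseInfluenceMatrix:
    """Dense (n_spots, n_vox) array -> influence matrix on a fake 1-D lattice."""
    n_spots, n_vox = D.shape
    side = int(np.ceil(n_vox ** (1 / 3))) + 1
    shape = (max(side, 8),) * 3
    full = np.zeros((n_spots, int(np.prod(shape))))
    full[:, :n_vox] = D
    return DoseInfluenceMatrix(
        spot_ids=np.arange(n_spots), matrix=sparse.csr_matrix(full),
        grid_shape=shape, spacing=np.ones(3), origin=np.zeros(3),
        scenario_id=scenario_id,
    )


def _toy_structures(shape, rois):
    masks = {}
    for name, idx in rois.items():
        m = np.zeros(int(np.prod(shape)), dtype=bool)
        m[list(idx)] = True
        masks[name] = m.reshape(shape)
    return StructureSet(masks=masks, roles={}, spacing=np.ones(3), origin=np.zeros(3))


def _random_instance(rng, n_spots=20, n_vox=30, n_scen=3, robust=True):
    mats = {
        s: _toy_matrix(rng.uniform(0, 1, (n_spots, n_vox)) * (rng.uniform(0, 1, (n_spots, n_vox)) > 0.4), s)
        for s in range(n_scen)
    }
    shape = mats[0].grid_shape
    rois = {
        "t": rng.choice(n_vox, 12, replace=False),
        "o": rng.choice(n_vox, 8, replace=False),
    }
    structures = _toy_structures(shape, rois)
    spec = ObjectiveSpec([
        ObjectiveTerm("t", "min_dose", 10.0, 1.5, robust),
        ObjectiveTerm("t", "max_dose", 11.0, 1.0, robust),
        ObjectiveTerm("o", "max_dose", 3.0, 2.0, robust),
        ObjectiveTerm("o", "mean_dose", 2.0, 0.5, False),
    ])
    w = rng.uniform(0, 3, n_spots)
    return w, mats, structures, spec


class TestObjective:
    def test_zero_when_all_constraints_met(self):
        D = np.eye(3)
        mats = {0: _toy_matrix(D)}
        structures = _toy_structures(mats[0].grid_shape, {"t": [0, 1, 2]})
        spec = ObjectiveSpec([ObjectiveTerm("t", "max_dose", 10.0, 1.0)])
        assert objective_value(np.ones(3), mats, structures, spec) == 0.0

    def test_single_voxel_hand_value(self):
        # one spot delivering 12 Gy to a one-voxel ROI with max_dose limit 10
        D = np.array([[12.0]])
        mats = {0: _toy_matrix(D)}
        structures = _toy_structures(mats[0].grid_shape, {"t": [0]})
        spec = ObjectiveSpec([ObjectiveTerm("t", "max_dose", 10.0, 1.0)])
        assert objective_value(np.ones(1), mats, structures, spec) == pytest.approx(4.0)

    def test_identical_scenarios_robust_equals_nominal(self):
        rng = np.random.default_rng(0)
        D = rng.uniform(0, 2, (5, 10))
        mats_same = {s: _toy_matrix(D, s) for s in range(3)}
        structures = _toy_structures(mats_same[0].grid_shape, {"t": range(10)})
        w = rng.uniform(0, 1, 5)
        spec_r = ObjectiveSpec([ObjectiveTerm("t", "min_dose", 5.0, 1.0, robust=True)])
        spec_n = ObjectiveSpec([ObjectiveTerm("t", "min_dose", 5.0, 1.0, robust=False)])
        assert objective_value(w, mats_same, structures, spec_r) == pytest.approx(
            objective_value(w, {0: mats_same[0]}, structures, spec_n)
        )

    def test_empty_roi_rejected(self):
        mats = {0: _toy_matrix(np.ones((2, 4)))}
        structures = _toy_structures(mats[0].grid_shape, {"t": []})
        spec = ObjectiveSpec([ObjectiveTerm("t", "max_dose", 1.0, 1.0)])
        with pytest.raises(ObjectiveSpecError):
            objective_value(np.ones(2), mats, structures, spec)


class TestGradient:
    def test_zero_when_penalties_inactive(self):
        D = np.full((4, 6), 0.1)
        mats = {0: _toy_matrix(D)}
        structures = _toy_structures(mats[0].grid_shape, {"t": range(6)})
        spec = ObjectiveSpec([ObjectiveTerm("t", "max_dose", 100.0, 1.0)])
        g = objective_gradient(np.ones(4), mats, structures, spec)
        assert np.all(g == 0)

    def test_matches_finite_differences(self):
        """Analytic gradient vs central differences on random robust instances."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            w, mats, structures, spec = _random_instance(rng)
            g = objective_gradient(w, mats, structures, spec)
            h = 1e-5
            g_fd = np.empty_like(g)
            for i in range(w.size):
                wp, wm = w.copy(), w.copy()
                wp[i] += h
                wm[i] = max(wm[i] - h, 0.0)
                g_fd[i] = (
                    objective_value(wp, mats, structures, spec)
                    - objective_value(wm, mats, structures, spec)
                ) / (wp[i] - wm[i])
            denom = max(np.abs(g).max(), 1e-12)
            assert np.abs(g - g_fd).max() / denom < 1e-4

    def test_max_dose_violation_gives_nonnegative_components(self):
        rng = np.random.default_rng(1)
        D = rng.uniform(0, 1, (6, 8))
        mats = {0: _toy_matrix(D)}
        structures = _toy_structures(mats[0].grid_shape, {"t": range(8)})
        spec = ObjectiveSpec([ObjectiveTerm("t", "max_dose", 0.5, 1.0)])
        g = objective_gradient(np.ones(6), mats, structures, spec)
        assert np.all(g >= 0)


class TestSelectByWeight:
    def test_hand_example(self):
        sel = select_by_weight(np.array([5.0, 3.0, 1.0, 1.0]), 0.65)
        assert set(sel) == {0, 1}

    def test_p_one_selects_all_positive(self):
        sel = select_by_weight(np.array([2.0, 0.0, 1.0, 0.0]), 1.0)
        assert set(sel) == {0, 2}

    def test_equal_weights_ceiling(self):
        sel = select_by_weight(np.ones(10), 0.65)
        assert sel.size == 7

    def test_all_zero_rejected(self):
        with pytest.raises(SelectionError):
            select_by_weight(np.zeros(4), 0.65)

    def test_minimality_against_exhaustive_enumeration(self):
        """For n <= 15 the greedy prefix is a minimum-cardinality feasible set."""
        rng = np.random.default_rng(123)
        for trial in range(200):
            n = int(rng.integers(2, 16))
            w = rng.uniform(0.0, 1.0, n)
            if w.sum() == 0:
                continue
            p = [0.5, 0.65, 0.9][trial % 3]
            sel = select_by_weight(w, p)
            bits = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(bool)
            masses = bits @ w
            feasible = masses >= p * w.sum() - 1e-12 * w.sum()
            min_card = bits[feasible].sum(axis=1).min()
            assert sel.size == min_card
            assert w[sel].sum() >= p * w.sum() - 1e-9


class TestSelectByGradient:
    def test_zero_gradient_empty(self):
        out = select_by_gradient(np.arange(3), np.zeros(3), 3.0)
        assert out.size == 0

    def test_documented_modes(self):
        g = np.array([5.0, -4.0, 2.0])
        cands = np.arange(3)
        assert set(select_by_gradient(cands, g, 3.0, "magnitude")) == {0, 1}
        assert set(select_by_gradient(cands, g, 3.0, "signed")) == {0}

    def test_defaults_are_study_values(self):
        cfg = SelectionConfig()
        assert cfg.p_weight_fraction == 0.65
        assert cfg.t_gradient_threshold == 3.0

    def test_second_criterion_restricted_to_first(self):
        w = np.array([5.0, 3.0, 1.0, 1.0])
        g = np.array([10.0, 0.0, 10.0, 10.0])
        res = select_spots(w, g, SelectionConfig(0.65, 3.0, "magnitude"))
        # spots 2,3 pass the gradient test but failed the weight criterion
        assert set(res.selected) == {0}
        assert set(res.audit["after_weight_criterion"]) == {0, 1}


def _quadratic_toy():
    """2 spots, 2 voxels, min+max at the same level = least squares to b."""
    D = np.array([[1.0, 0.2], [0.3, 1.0]])
    mats = {0: _toy_matrix(D)}
    structures = _toy_structures(mats[0].grid_shape, {"t": [0, 1]})
    level = 10.0
    spec = ObjectiveSpec([
        ObjectiveTerm("t", "min_dose", level, 1.0),
        ObjectiveTerm("t", "max_dose", level, 1.0),
    ])
    return D, mats, structures, spec, level


class TestReoptimize:
    def test_two_spot_toy_matches_nnls(self, small_plan):
        from scipy.optimize import nnls

        D, mats, structures, spec, level = _quadratic_toy()
        from arcadapt.plan import ArcPlan, ControlPoint, Spot

        plan = ArcPlan(
            control_points=[ControlPoint(0, 0.0, [100.0])],
            spots=[Spot(i, 0, 0.0, 0.0, 100.0, 0.1, 0) for i in range(2)],
            isocenter=np.zeros(3),
            machine_energies=np.array([100.0]),
        )
        sel = SelectionResult(selected=np.array([0, 1]), discarded=np.array([], dtype=int))
        w, trace = reoptimize_weights(plan, mats, structures, spec, sel,
                                      max_iter=2000, tol=0.0)
        w_ref, _ = nnls(D.T, np.full(2, level))
        assert np.abs(w - w_ref).max() < 1e-6

    def test_discarded_weights_bit_identical(self):
        rng = np.random.default_rng(5)
        D = rng.uniform(0, 1, (10, 12))
        mats = {0: _toy_matrix(D)}
        structures = _toy_structures(mats[0].grid_shape, {"t": range(12)})
        spec = ObjectiveSpec([ObjectiveTerm("t", "min_dose", 5.0, 1.0)])
        from arcadapt.plan import ArcPlan, ControlPoint, Spot

        w0 = rng.uniform(0.1, 1.0, 10)
        plan = ArcPlan(
            control_points=[ControlPoint(0, 0.0, [100.0])],
            spots=[Spot(i, 0, 0.0, 0.0, 100.0, float(w0[i]), 0) for i in range(10)],
            isocenter=np.zeros(3), machine_energies=np.array([100.0]),
        )
        sel = SelectionResult(selected=np.array([1, 4, 7]),
                              discarded=np.setdiff1d(np.arange(10), [1, 4, 7]))
        w, _ = reoptimize_weights(plan, mats, structures, spec, sel)
        for i in sel.discarded:
            assert w[i] == w0[i]  # bit identical, not approximately

    def test_background_plus_selected_equals_total(self):
        """Eq-2 split: total dose == frozen background + selected contribution."""
        rng = np.random.default_rng(9)
        D = rng.uniform(0, 1, (10, 12)) * (rng.uniform(0, 1, (10, 12)) > 0.3)
        mats = {0: _toy_matrix(D)}
        structures = _toy_structures(mats[0].grid_shape, {"t": range(12)})
        spec = ObjectiveSpec([ObjectiveTerm("t", "min_dose", 5.0, 1.0)])
        from arcadapt.dose import total_dose
        from arcadapt.plan import ArcPlan, ControlPoint, Spot

        w0 = rng.uniform(0.1, 1.0, 10)
        plan = ArcPlan(
            control_points=[ControlPoint(0, 0.0, [100.0])],
            spots=[Spot(i, 0, 0.0, 0.0, 100.0, float(w0[i]), 0) for i in range(10)],
            isocenter=np.zeros(3), machine_energies=np.array([100.0]),
        )
        sel_ids = np.array([0, 2, 3, 8])
        sel = SelectionResult(selected=sel_ids,
                              discarded=np.setdiff1d(np.arange(10), sel_ids))
        w, _ = reoptimize_weights(plan, mats, structures, spec, sel)
        total = total_dose(mats[0], w)
        w_bg = w.copy()
        w_bg[sel_ids] = 0.0
        w_sel = w - w_bg
        split = total_dose(mats[0], w_bg) + total_dose(mats[0], w_sel)
        assert np.abs(split - total).max() <= 1e-10 * max(total.max(), 1.0)

    def test_empty_selection_keeps_weights(self):
        rng = np.random.default_rng(2)
        D = rng.uniform(0, 1, (6, 8))
        mats = {0: _toy_matrix(D)}
        structures = _toy_structures(mats[0].grid_shape, {"t": range(8)})
        spec = ObjectiveSpec([ObjectiveTerm("t", "min_dose", 5.0, 1.0)])
        from arcadapt.plan import ArcPlan, ControlPoint, Spot

        w0 = rng.uniform(0.1, 1.0, 6)
        plan = ArcPlan(
            control_points=[ControlPoint(0, 0.0, [100.0])],
            spots=[Spot(i, 0, 0.0, 0.0, 100.0, float(w0[i]), 0) for i in range(6)],
            isocenter=np.zeros(3), machine_energies=np.array([100.0]),
        )
        sel = SelectionResult(selected=np.array([], dtype=int), discarded=np.arange(6))
        w, _ = reoptimize_weights(plan, mats, structures, spec, sel)
        assert np.array_equal(w, w0)

    def test_full_selection_equals_full_optimize(self):
        rng = np.random.default_rng(11)
        D = rng.uniform(0, 1, (8, 10))
        mats = {0: _toy_matrix(D)}
        structures = _toy_structures(mats[0].grid_shape, {"t": range(10)})
        spec = ObjectiveSpec([ObjectiveTerm("t", "min_dose", 5.0, 1.0)])
        from arcadapt.plan import ArcPlan, ControlPoint, Spot

        w0 = rng.uniform(0.1, 1.0, 8)
        plan = ArcPlan(
            control_points=[ControlPoint(0, 0.0, [100.0])],
            spots=[Spot(i, 0, 0.0, 0.0, 100.0, float(w0[i]), 0) for i in range(8)],
            isocenter=np.zeros(3), machine_energies=np.array([100.0]),
        )
        sel = SelectionResult(selected=np.arange(8), discarded=np.array([], dtype=int))
        w_a, tr_a = reoptimize_weights(plan, mats, structures, spec, sel, max_iter=300)
        w_b, tr_b = full_optimize(plan, mats, structures, spec, init="given", max_iter=300)
        assert np.array_equal(w_a, w_b)
        assert tr_a.objective == tr_b.objective


class TestOptimizerSoundness:
    def test_trace_monotone_nonincreasing(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            w, mats, structures, spec = _random_instance(rng, n_spots=15, n_vox=20)
            from arcadapt.plan import ArcPlan, ControlPoint, Spot

            plan = ArcPlan(
                control_points=[ControlPoint(0, 0.0, [100.0])],
                spots=[Spot(i, 0, 0.0, 0.0, 100.0, float(w[i]), 0) for i in range(15)],
                isocenter=np.zeros(3), machine_energies=np.array([100.0]),
            )
            _, trace = full_optimize(plan, mats, structures, spec, init="given",
                                     max_iter=150)
            f = np.asarray(trace.objective)
            assert np.all(np.diff(f) <= 1e-12 * np.maximum(f[:-1], 1.0))

    def test_deterministic_rerun(self):
        rng = np.random.default_rng(33)
        w, mats, structures, spec = _random_instance(rng, n_spots=10, n_vox=15)
        from arcadapt.plan import ArcPlan, ControlPoint, Spot

        plan = ArcPlan(
            control_points=[ControlPoint(0, 0.0, [100.0])],
            spots=[Spot(i, 0, 0.0, 0.0, 100.0, float(w[i]), 0) for i in range(10)],
            isocenter=np.zeros(3), machine_energies=np.array([100.0]),
        )
        w1, t1 = full_optimize(plan, mats, structures, spec, init="uniform", max_iter=100)
        w2, t2 = full_optimize(plan, mats, structures, spec, init="uniform", max_iter=100)
        assert np.array_equal(w1, w2)
        assert t1.objective == t2.objective

    def test_final_not_above_initial(self):
        rng = np.random.default_rng(44)
        w, mats, structures, spec = _random_instance(rng, n_spots=12, n_vox=18)
        from arcadapt.plan import ArcPlan, ControlPoint, Spot

        plan = ArcPlan(
            control_points=[ControlPoint(0, 0.0, [100.0])],
            spots=[Spot(i, 0, 0.0, 0.0, 100.0, float(w[i]), 0) for i in range(12)],
            isocenter=np.zeros(3), machine_energies=np.array([100.0]),
        )
        _, trace = full_optimize(plan, mats, structures, spec, init="given", max_iter=50)
        assert trace.objective[-1] <= trace.objective[0]


class TestScenarioSet:
    def test_nominal_must_be_first(self):
        with pytest.raises(ValueError):
            ScenarioSet([((1.0, 0.0, 0.0), 1.0)])

    def test_default_robust_has_nine(self):
        s = ScenarioSet.default_robust()
        assert len(s) == 9
        shifts = np.array([sh for sh, _ in s.scenarios])
        scales = np.array([sc for _, sc in s.scenarios])
        assert np.abs(shifts).max() == 4.0
        assert scales.max() == pytest.approx(1.026)
        assert scales.min() == pytest.approx(0.974)

    def test_nominal_only_scenario_reproduces_nonrobust_trace(self):
        """Robust optimization over {nominal} is bit-identical to non-robust."""
        rng = np.random.default_rng(55)
        D = rng.uniform(0, 1, (8, 10))
        mats = {0: _toy_matrix(D)}
        structures = _toy_structures(mats[0].grid_shape, {"t": range(10)})
        from arcadapt.plan import ArcPlan, ControlPoint, Spot

        plan = ArcPlan(
            control_points=[ControlPoint(0, 0.0, [100.0])],
            spots=[Spot(i, 0, 0.0, 0.0, 100.0, 1.0, 0) for i in range(8)],
            isocenter=np.zeros(3), machine_energies=np.array([100.0]),
        )
        spec_r = ObjectiveSpec([ObjectiveTerm("t", "min_dose", 5.0, 1.0, robust=True)])
        spec_n = ObjectiveSpec([ObjectiveTerm("t", "min_dose", 5.0, 1.0, robust=False)])
        w_r, t_r = full_optimize(plan, mats, structures, spec_r, init="uniform", max_iter=100)
        w_n, t_n = full_optimize(plan, mats, structures, spec_n, init="uniform", max_iter=100)
        assert np.array_equal(w_r, w_n)
        assert t_r.objective == t_n.objective
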