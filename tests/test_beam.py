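import numpy as np
import pytest

from spacerdose.beam import (
    DepthDoseModel,
    bragg_range,
    build_sobp,
    compute_dose,
    energy_for_range,
    optimize_plan,
    sobp_dose_at,
    wepl_trace,
)
from spacerdose.core import ImageGrid, Ray

MODEL = DepthDoseModel()


class TestBraggKleeman:
    def test_closed_form_range(self):
        # R = 0.0022 * 198.3^1.77 cm, evaluated independently
        expected = 0.0022 * 198.3**1.77
        assert bragg_range(198.3, MODEL) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(25.6, abs=0.1)

    def test_power_law_energy_scaling(self):
        assert bragg_range(200.0, MODEL) / bragg_range(100.0, MODEL) == pytest.approx(
            2.0**MODEL.p
        )

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(ValueError):
            bragg_range(0.0, MODEL)

    def test_inverse_relation(self):
        assert energy_for_range(10 * bragg_range(150.0, MODEL), MODEL) == pytest.approx(150.0)


class TestWEPL:
    def test_uniform_water_matches_geometric_depth(self):
        spr = ImageGrid(np.ones((60, 20, 20)), (2.0, 2.0, 2.0), unit="SPR")
        ray = Ray((-10.0, 20.0, 20.0), (1.0, 0.0, 0.0), step=1.0)
        t, wepl = wepl_trace(spr, ray)
        total_at_100 = np.interp(100.0, t, wepl)
        assert total_at_100 == pytest.approx(100.0, abs=0.5)

    def test_dense_slab_adds_excess_wepl(self):
        vals = np.ones((60, 20, 20))
        vals[20:25] = 2.0  # 10 mm slab of SPR 2 at 2 mm voxels
        spr = ImageGrid(vals, (2.0, 2.0, 2.0), unit="SPR")
        ray = Ray((-1.0, 20.0, 20.0), (1.0, 0.0, 0.0), step=1.0)
        t, wepl = wepl_trace(spr, ray)
        geometric = t[-1] - t[0] + 1.0
        assert wepl[-1] == pytest.approx(geometric + 10.0, abs=0.5)

    def test_oblique_ray_matches_fine_step_oracle(self):
        rng = np.random.default_rng(4)
        vals = 0.8 + 0.6 * rng.random((40, 40, 40))
        vals = np.repeat(vals, 1, axis=0)  # layered random medium
        spr = ImageGrid(vals, (2.0, 2.0, 2.0), unit="SPR")
        d = np.array([1.0, 0.6, 0.3])
        d /= np.linalg.norm(d)
        coarse = Ray((-5.0, 5.0, 5.0), tuple(d), step=1.0)
        fine = Ray((-5.0, 5.0, 5.0), tuple(d), step=0.1)
        _, w_coarse = wepl_trace(spr, coarse)
        _, w_fine = wepl_trace(spr, fine)
        assert w_coarse[-1] == pytest.approx(w_fine[-1], rel=0.005)

    def test_missing_ray_returns_empty_profile(self):
        spr = ImageGrid(np.ones((10, 10, 10)), (2.0, 2.0, 2.0), unit="SPR")
        t, wepl = wepl_trace(spr, Ray((1000.0, 1000.0, 0.0), (0.0, 0.0, 1.0), 1.0))
        assert t.size == 0 and wepl.size == 0

    def test_oversized_step_rejected(self):
        spr = ImageGrid(np.ones((10, 10, 10)), (2.0, 2.0, 2.0), unit="SPR")
        with pytest.raises(ValueError, match="step"):
            wepl_trace(spr, Ray((0, 0, 0), (1.0, 0, 0), step=1.5))


class TestSOBP:
    @pytest.mark.parametrize("interval", [(150.0, 200.0), (80.0, 130.0), (30.0, 60.0)])
    def test_plateau_flat_within_three_percent_of_mean(self, interval):
        d_prox, d_dist = interval
        layers = build_sobp(d_prox, d_dist, MODEL)
        depths = np.arange(d_prox, d_dist + 1e-9, 0.25)
        dose = sobp_dose_at(depths, layers, MODEL)
        assert np.abs(dose - dose.mean()).max() / dose.mean() <= 0.03

    @pytest.mark.parametrize("interval", [(150.0, 200.0), (80.0, 130.0)])
    def test_distal_falloff_below_ten_percent_within_8mm(self, interval):
        d_prox, d_dist = interval
        layers = build_sobp(d_prox, d_dist, MODEL)
        plateau = sobp_dose_at(np.arange(d_prox, d_dist, 0.5), layers, MODEL).mean()
        tail = sobp_dose_at(np.array([d_dist + 8.0]), layers, MODEL)[0]
        assert tail < 0.10 * plateau

    def test_degenerate_interval_gives_single_peak(self):
        layers = build_sobp(120.0, 120.0, MODEL)
        assert layers == [(120.0, 1.0)]

    def test_interval_beyond_deliverable_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            build_sobp(100.0, MODEL.max_range_mm + 50.0, MODEL)


class TestPlanning:
    def test_water_box_meets_coverage_objective(self, water_box):
        spr, rois = water_box
        plan = optimize_plan(spr, rois, 7000.0, MODEL)
        dose = compute_dose(plan, spr, MODEL)
        ctv_doses = dose.values[rois["ctv"]]
        d95 = np.sort(ctv_doses)[int(np.floor(0.05 * ctv_doses.size))]
        assert d95 == pytest.approx(7000.0, rel=0.01)
        assert (ctv_doses >= 7000.0).mean() >= 0.95

    def test_dose_linear_in_prescription(self, water_box):
        spr, rois = water_box
        p1 = optimize_plan(spr, rois, 7000.0, MODEL)
        p2 = optimize_plan(spr, rois, 14000.0, MODEL)
        d1 = compute_dose(p1, spr, MODEL)
        d2 = compute_dose(p2, spr, MODEL)
        np.testing.assert_allclose(d2.values, 2.0 * d1.values, rtol=1e-9, atol=1e-9)

    def test_recalculation_reproduces_optimization_dose(self, water_box):
        spr, rois = water_box
        plan = optimize_plan(spr, rois, 7000.0, MODEL)
        a = compute_dose(plan, spr, MODEL)
        b = compute_dose(plan, spr, MODEL)
        np.testing.assert_array_equal(a.values, b.values)

    def test_single_voxel_ctv_plans(self):
        from spacerdose.core import ROISet
        spr = ImageGrid(np.ones((60, 40, 40)), (2.0, 2.0, 2.0), unit="SPR")
        ctv = np.zeros(spr.shape, dtype=bool)
        ctv[30, 20, 20] = True
        plan = optimize_plan(spr, ROISet(spr, {"ctv": ctv}), 7000.0, MODEL)
        dose = compute_dose(plan, spr, MODEL)
        assert dose.values[30, 20, 20] >= 7000.0
        assert len(plan.beams) == 2

    def test_zero_weights_give_zero_dose(self, water_box):
        spr, rois = water_box
        plan = optimize_plan(spr, rois, 7000.0, MODEL)
        for beam in plan.beams:
            for ray in beam.rays:
                ray.layers = [(r, 0.0) for r, _ in ray.layers]
        dose = compute_dose(plan, spr, MODEL)
        assert np.all(dose.values == 0.0)

    def test_dose_nonnegative_everywhere(self, water_box):
        spr, rois = water_box
        plan = optimize_plan(spr, rois, 7000.0, MODEL)
        assert np.all(compute_dose(plan, spr, MODEL).values >= 0.0)

    def test_denser_spacer_pulls_dose_back(self, water_box):
        # raising SPR upstream of the target shifts the distal edge proximally,
        # lowering target dose — the core material-error mechanism
        spr, rois = water_box
        plan = optimize_plan(spr, rois, 7000.0, MODEL)
        base = compute_dose(plan, spr, MODEL)
        denser = spr.like(spr.values.copy())
        denser.values[10:15] = 1.3  # slab crossing both beam paths
        shifted = compute_dose(plan, denser, MODEL)
        assert shifted.values[rois["ctv"]].mean() < base.values[rois["ctv"]].mean()

    def test_plan_round_trip_serialization(self, water_box, tmp_path):
        spr, rois = water_box
        plan = optimize_plan(spr, rois, 7000.0, MODEL)
        plan.save(tmp_path / "plan.json")
        from spacerdose.beam import Plan
        back = Plan.load(tmp_path / "plan.json")
        np.testing.assert_array_equal(
            compute_dose(back, spr, MODEL).values, compute_dose(plan, spr, MODEL).values
        )

    def test_misaligned_grid_rejected(self, water_box):
        from spacerdose.core import AlignmentError
        spr, rois = water_box
        plan = optimize_plan(spr, rois, 7000.0, MODEL)
        other = ImageGrid(np.ones((50, 50, 50)), (2.0, 2.0, 2.0), unit="SPR")
        with pytest.raises(AlignmentError):
            compute_dose(plan, other, MODEL)
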