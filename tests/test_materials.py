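import numpy as np
import pytest

from spacerdose.core import ImageGrid, ROISet
from spacerdose.materials import (
    HUCurve,
    MaterialSpec,
    Scenario,
    build_spr_grid,
    compute_spr,
    effective_z,
    hu_to_spr,
    material_from_components,
    spacer_material,
    WATER,
)


class TestComposition:
    def test_water_elemental_fractions(self):
        # H2O: 2*1.008 / 18.015 and 15.999 / 18.015
        m = material_from_components({"water": 1.0}, 1.0)
        assert m.weight_fractions["H"] == pytest.approx(0.1119, abs=1e-3)
        assert m.weight_fractions["O"] == pytest.approx(0.8881, abs=1e-3)

    def test_spacer_recipe_keeps_iodine_weight(self):
        sp = spacer_material()
        assert sp.weight_fractions["I"] == pytest.approx(0.012, abs=1e-6)
        assert sum(sp.weight_fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert sp.density == pytest.approx(1.03)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            material_from_components({"water": 0.9}, 1.0)

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            material_from_components({"kryptonite": 1.0}, 1.0)


class TestStoppingPower:
    def test_water_self_ratio_is_exactly_one(self):
        for e in (10.0, 70.0, 198.3, 250.0):
            assert compute_spr(WATER, e) == pytest.approx(1.0, abs=1e-12)

    def test_density_scaling_at_fixed_composition(self):
        heavy_water = MaterialSpec("dense_water", WATER.weight_fractions, 1.10)
        assert compute_spr(heavy_water, 150.0) == pytest.approx(1.10, abs=1e-6)

    def test_spacer_spr_near_measured_value(self):
        # theoretical SPR of the hydrogel composition vs the 1.03 benchmark
        assert compute_spr(spacer_material(), 198.3) == pytest.approx(1.03, abs=0.01)

    def test_monotone_and_continuous_in_density(self):
        densities = np.linspace(0.9, 1.2, 31)
        sprs = [compute_spr(MaterialSpec("w", WATER.weight_fractions, d), 100.0)
                for d in densities]
        assert np.all(np.diff(sprs) > 0)
        assert np.max(np.abs(np.diff(sprs))) < 0.02  # no jumps

    def test_energy_band_enforced(self):
        with pytest.raises(ValueError, match="energy"):
            compute_spr(WATER, 0.5)


class TestEffectiveZ:
    def test_single_element_is_its_z(self):
        oxygen = MaterialSpec("O", {"O": 1.0}, 1.0)
        for m in (1.0, 2.94, 3.5, 5.0):
            assert effective_z(oxygen, m) == pytest.approx(8.0)

    def test_water_matches_two_term_hand_sum(self):
        # electron fractions H 0.2, O 0.8: (0.2*1 + 0.8*8^3.5)^(1/3.5)
        expected = (0.2 * 1.0 + 0.8 * 8.0**3.5) ** (1 / 3.5)
        assert effective_z(WATER, 3.5) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(7.5, abs=0.01)

    def test_spacer_effective_z_near_reported(self):
        assert effective_z(spacer_material(), 3.5) == pytest.approx(14.47, rel=0.02)

    def test_positive_exponent_required(self):
        with pytest.raises(ValueError):
            effective_z(WATER, 0.0)


class TestHUCurve:
    def test_fixed_points(self):
        curve = HUCurve()
        assert hu_to_spr(0.0, curve) == pytest.approx(1.0)
        assert hu_to_spr(-1000.0, curve) == pytest.approx(0.001)
        assert hu_to_spr(-2000.0, curve) == pytest.approx(0.001)  # clamped
        # linear interpolation between the (100, 1.10) and (1600, 1.85) knots
        assert hu_to_spr(120.0, curve) == pytest.approx(1.11, abs=1e-6)

    def test_curve_validation(self):
        with pytest.raises(ValueError, match="knots"):
            HUCurve(((0.0, 1.0),))
        with pytest.raises(ValueError, match="increasing"):
            HUCurve(((0.0, 1.0), (0.0, 1.1)))
        with pytest.raises(ValueError, match="water"):
            HUCurve(((-100.0, 0.9), (100.0, 1.3)))

    def test_vectorizes_over_image_grid(self):
        g = ImageGrid(np.full((4, 4, 4), 120.0), (1, 1, 1), unit="HU")
        out = hu_to_spr(g)
        assert out.unit == "SPR"
        np.testing.assert_allclose(out.values, 1.11)


@pytest.fixture()
def iodinated_uniform_grid():
    """Tiny grid: spacer voxels at 120 HU, everything else at 0 HU."""
    shape = (8, 8, 8)
    spacer = np.zeros(shape, dtype=bool)
    spacer[2:6, 2:6, 2:6] = True
    hu = np.where(spacer, 120.0, 0.0)
    grid = ImageGrid(hu, (2, 2, 2), unit="HU")
    return grid, ROISet(grid, {"spacer": spacer})


class TestScenarios:
    def test_tm_overrides_spacer_with_theoretical_spr(self, iodinated_uniform_grid):
        grid, rois = iodinated_uniform_grid
        spr = build_spr_grid(grid, rois, "TM")
        np.testing.assert_allclose(spr.values[rois["spacer"]], 1.03, atol=0.01)

    def test_wm_forces_spacer_to_water(self, iodinated_uniform_grid):
        grid, rois = iodinated_uniform_grid
        spr = build_spr_grid(grid, rois, "WM")
        assert np.all(spr.values[rois["spacer"]] == 1.0)

    def test_nm_reads_spacer_off_the_curve(self, iodinated_uniform_grid):
        grid, rois = iodinated_uniform_grid
        spr = build_spr_grid(grid, rois, "NM")
        np.testing.assert_allclose(spr.values[rois["spacer"]], 1.11, atol=1e-6)

    def test_scenarios_differ_only_inside_spacer(self, iodinated_uniform_grid):
        grid, rois = iodinated_uniform_grid
        outside = ~rois["spacer"]
        grids = {sc: build_spr_grid(grid, rois, sc) for sc in ("NM", "WM", "TM")}
        np.testing.assert_array_equal(grids["NM"].values[outside], grids["WM"].values[outside])
        np.testing.assert_array_equal(grids["NM"].values[outside], grids["TM"].values[outside])

    def test_override_ordering_drives_the_range_error(self, iodinated_uniform_grid):
        # the error mechanism: curve(120 HU) > true hydrogel SPR > water
        grid, rois = iodinated_uniform_grid
        nm = build_spr_grid(grid, rois, "NM").values[rois["spacer"]].mean()
        tm = build_spr_grid(grid, rois, "TM").values[rois["spacer"]].mean()
        wm = build_spr_grid(grid, rois, "WM").values[rois["spacer"]].mean()
        assert nm > tm > wm

    def test_missing_spacer_roi_rejected(self, iodinated_uniform_grid):
        grid, rois = iodinated_uniform_grid
        bare = ROISet(grid, {"ctv": rois["spacer"]})
        with pytest.raises(ValueError, match="spacer"):
            build_spr_grid(grid, bare, "TM")

    def test_invalid_scenario_name_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            Scenario("XX")
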