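import itertools

import numpy as np
import pytest

from spacerdose.core import ImageGrid
from spacerdose.gamma import GammaCriteria, STANDARD_CRITERIA, gamma_map, passing_ratio


def _grid(values, spacing=(2.0, 2.0, 2.0)):
    return ImageGrid(np.asarray(values, dtype=float), spacing, unit="cGy")


def brute_force_gamma(ref: ImageGrid, evl: ImageGrid, criteria: GammaCriteria) -> np.ndarray:
    """Independent exhaustive gamma: explicit offsets, hand-rolled trilinear
    interpolation, full minimization per voxel — no early termination."""
    step = criteria.interp_step * criteria.dta_mm
    cap = criteria.search_cap * criteria.dta_mm
    n = int(np.floor(cap / step))
    axis = np.arange(-n, n + 1) * step
    offsets = [np.array(o) for o in itertools.product(axis, axis, axis)
               if np.linalg.norm(o) <= cap]
    dd_abs = criteria.dose_pct / 100.0 * ref.values.max()
    spacing = np.asarray(ref.spacing)
    shape = np.asarray(ref.shape)

    def trilinear(vol, p):
        if np.any(p < 0) or np.any(p > shape - 1):
            return None  # outside the evaluated grid: not searchable
        i0 = np.floor(p).astype(int)
        i1 = np.minimum(i0 + 1, shape - 1)
        f = p - i0
        acc = 0.0
        for ci, wi in ((i0[0], 1 - f[0]), (i1[0], f[0])):
            for cj, wj in ((i0[1], 1 - f[1]), (i1[1], f[1])):
                for ck, wk in ((i0[2], 1 - f[2]), (i1[2], f[2])):
                    acc += wi * wj * wk * vol[ci, cj, ck]
        return acc

    out = np.empty(ref.shape)
    for idx in np.ndindex(ref.shape):
        best = np.inf
        for off in offsets:
            val = trilinear(evl.values, np.asarray(idx) + off / spacing)
            if val is None:
                continue
            g2 = (off @ off) / criteria.dta_mm**2 + ((val - ref.values[idx]) / dd_abs) ** 2
            best = min(best, g2)
        out[idx] = np.sqrt(best)
    return out


class TestGammaMap:
    def test_identity_gives_zero_gamma(self):
        rng = np.random.default_rng(0)
        ref = _grid(100.0 * rng.random((10, 10, 10)) + 1.0)
        gmap = gamma_map(ref, ref, GammaCriteria(3.0, 3.0))
        np.testing.assert_allclose(gmap.values, 0.0, atol=1e-12)

    def test_uniform_two_percent_offset_is_two_thirds(self):
        # distance cannot help on a spatially uniform field
        ref = _grid(np.full((8, 8, 8), 1000.0))
        evl = _grid(np.full((8, 8, 8), 1020.0))
        gmap = gamma_map(ref, evl, GammaCriteria(3.0, 3.0))
        np.testing.assert_allclose(gmap.values, 2.0 / 3.0, atol=1e-9)

    def test_matches_brute_force_oracle_on_random_grids(self):
        rng = np.random.default_rng(7)
        crit = GammaCriteria(3.0, 3.0, search_cap=1.5, interp_step=0.5)
        for trial in range(3):
            base = rng.random((6, 6, 6))
            ref_small = 1000.0 * (0.2 + rng.random((16, 16, 16)))
            evl_small = ref_small * (1.0 + 0.05 * (rng.random((16, 16, 16)) - 0.5))
            ref = _grid(ref_small)
            evl = _grid(evl_small)
            ours = gamma_map(ref, evl, crit)
            oracle = brute_force_gamma(ref, evl, crit)
            np.testing.assert_allclose(ours.values, oracle, atol=1e-3)

    def test_invariant_under_common_rescaling(self):
        rng = np.random.default_rng(3)
        ref = _grid(1000.0 * (0.1 + rng.random((10, 10, 10))))
        evl = _grid(ref.values * (1.0 + 0.02 * rng.random((10, 10, 10))))
        crit = GammaCriteria(2.0, 2.0)
        a = gamma_map(ref, evl, crit).values
        b = gamma_map(_grid(5.0 * ref.values), _grid(5.0 * evl.values), crit).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_where_mask_restricts_computation(self):
        ref = _grid(np.full((6, 6, 6), 1000.0))
        evl = _grid(np.full((6, 6, 6), 1040.0))
        where = np.zeros((6, 6, 6), dtype=bool)
        where[0] = True
        gmap = gamma_map(ref, evl, GammaCriteria(3.0, 3.0), where=where)
        assert np.all(gmap.values[0] > 1.0)
        assert np.all(gmap.values[1:] == -1.0)  # excluded sentinel

    def test_zero_reference_rejected(self):
        z = _grid(np.zeros((5, 5, 5)))
        with pytest.raises(ValueError, match="positive"):
            gamma_map(z, z, GammaCriteria(3.0, 3.0))


class TestPassingRatio:
    def test_identity_passes_everywhere_for_all_criteria(self):
        rng = np.random.default_rng(1)
        ref = _grid(1000.0 * (0.2 + rng.random((8, 8, 8))))
        for crit in STANDARD_CRITERIA:
            gmap = gamma_map(ref, ref, crit)
            assert passing_ratio(gmap, ref, crit) == 1.0

    @pytest.mark.parametrize("offset, expected", [(1.02, 1.0), (1.04, 0.0)])
    def test_uniform_offsets_analytic(self, offset, expected):
        # 2% offset: gamma = 2/3 < 1 passes; 4%: gamma = 4/3 >= 1 fails
        ref = _grid(np.full((8, 8, 8), 1000.0))
        evl = _grid(offset * ref.values)
        crit = GammaCriteria(3.0, 3.0)
        gmap = gamma_map(ref, evl, crit)
        assert passing_ratio(gmap, ref, crit) == expected

    def test_low_dose_voxels_excluded(self):
        # corrupt the evaluated dose only where the reference is below 10%
        # of its maximum: the passing ratio must not see those voxels
        vals = np.full((8, 8, 8), 50.0)
        vals[4:, :, :] = 1000.0
        ref = _grid(vals)
        corrupted = vals.copy()
        corrupted[:4, :, :] = 0.0
        evl = _grid(corrupted)
        crit = GammaCriteria(3.0, 3.0)
        gmap = gamma_map(ref, evl, crit)
        assert passing_ratio(gmap, ref, crit) == 1.0
        # without the threshold the corrupted half would fail
        loose = GammaCriteria(3.0, 3.0, low_dose_threshold=0.0)
        gmap2 = gamma_map(ref, evl, loose)
        assert passing_ratio(gmap2, ref, loose) < 1.0

    def test_empty_denominator_signalled_as_nan(self):
        ref = _grid(np.full((6, 6, 6), 1000.0))
        gmap = gamma_map(ref, ref, GammaCriteria(3.0, 3.0))
        empty_roi = np.zeros((6, 6, 6), dtype=bool)
        empty_roi[0, 0, 0] = True
        ref2 = _grid(np.where(np.arange(6)[:, None, None] == 0, 10.0, 1000.0) * np.ones((6, 6, 6)))
        assert np.isnan(passing_ratio(gmap, ref2, GammaCriteria(3.0, 3.0), roi=empty_roi))

    def test_criteria_loosening_never_lowers_passing(self):
        # PR(1%/1mm) <= PR(2%/2mm) <= PR(3%/3mm) on arbitrary smooth fields
        from scipy import ndimage
        rng = np.random.default_rng(9)
        ref = _grid(ndimage.gaussian_filter(1000.0 * rng.random((14, 14, 14)), 2.0) + 200.0)
        evl = _grid(ref.values * (1.0 + 0.03 * np.sin(np.arange(14) / 2.0))[:, None, None])
        prs = []
        for crit in STANDARD_CRITERIA:
            gmap = gamma_map(ref, evl, crit)
            prs.append(passing_ratio(gmap, ref, crit))
        assert prs[0] <= prs[1] <= prs[2]

    def test_boundary_gamma_equal_one_fails_strictly(self):
        ref = _grid(np.full((6, 6, 6), 1000.0))
        evl = _grid(np.full((6, 6, 6), 1030.0))  # exactly 3% -> gamma = 1
        crit = GammaCriteria(3.0, 3.0)
        gmap = gamma_map(ref, evl, crit)
        np.testing.assert_allclose(gmap.values, 1.0, atol=1e-12)
        assert passing_ratio(gmap, ref, crit) == 0.0
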