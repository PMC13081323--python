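import numpy as np
import pytest
from hypothesis import given, strategies as st

from lungwater import (
    CTVolume,
    DEFAULT_WINDOW,
    HUWindow,
    LungMask,
    PatientAnthro,
    dice_coefficient,
    evlwi_ct,
    expected_lung_weight,
    ideal_body_weight,
    lung_weight,
    quantify_scan,
    select_edema_voxels,
)
from lungwater.errors import (
    AlignmentError,
    EmptySelectionError,
    NumericError,
    ValidationError,
)

from conftest import flat_volume, make_mask, make_volume


class TestTypes:
    def test_volume_requires_rank_3(self):
        with pytest.raises(ValidationError, match="rank"):
            CTVolume(np.zeros((4, 4)), (1, 1, 1))

    def test_volume_rejects_nonfinite(self):
        arr = np.zeros((2, 2, 2))
        arr[0, 0, 0] = np.nan
        with pytest.raises(ValidationError, match="finite"):
            CTVolume(arr, (1, 1, 1))

    def test_volume_rejects_bad_spacing(self):
        with pytest.raises(ValidationError, match="spacing"):
            CTVolume(np.zeros((2, 2, 2)), (1, 0, 1))

    def test_voxel_volume_ml(self):
        v = CTVolume(np.zeros((2, 2, 2)), (2.5, 1.5, 1.5))
        assert v.voxel_volume_ml == pytest.approx(2.5 * 1.5 * 1.5 / 1000.0)

    def test_mask_rejects_nonbinary(self):
        with pytest.raises(ValidationError, match="binary"):
            LungMask(np.full((2, 2, 2), 3), (1, 1, 1))

    def test_window_ordering(self):
        with pytest.raises(ValidationError):
            HUWindow(200, -700)

    def test_anthro_sex_validated(self):
        with pytest.raises(ValidationError):
            PatientAnthro(height=1.77, sex="other")

    def test_anthro_warns_outside_range(self):
        with pytest.warns(UserWarning, match="plausible"):
            PatientAnthro(height=2.5, sex="male")


class TestSelectEdemaVoxels:
    def test_inclusive_boundaries(self):
        vals = [-900, -750, -700, -500, 0, 150, 200, 201, 300, 1000]
        volume, mask = flat_volume(vals)
        sel = select_edema_voxels(volume, mask, DEFAULT_WINDOW)
        assert sorted(sel) == [-700, -500, 0, 150, 200]

    def test_all_below_window(self):
        volume, mask = flat_volume([-1000.0] * 8)
        assert select_edema_voxels(volume, mask).size == 0

    def test_contrast_excluded_by_count(self):
        vals = np.full(4120, -400.0)
        vals[:120] = 350.0
        volume, mask = flat_volume(vals)
        sel = select_edema_voxels(volume, mask)
        assert sel.size == 4000
        assert np.all(sel == -400.0)

    def test_shape_mismatch(self):
        volume = make_volume(np.zeros((2, 2, 2)))
        mask = make_mask(np.ones((2, 2, 3), dtype=bool))
        with pytest.raises(AlignmentError):
            select_edema_voxels(volume, mask)

    def test_spacing_mismatch(self):
        volume = make_volume(np.zeros((2, 2, 2)), spacing=(1, 1, 1))
        mask = make_mask(np.ones((2, 2, 2), dtype=bool), spacing=(1, 1, 2))
        with pytest.raises(AlignmentError):
            select_edema_voxels(volume, mask)

    def test_empty_mask_is_an_error(self):
        volume = make_volume(np.zeros((2, 2, 2)))
        mask = make_mask(np.zeros((2, 2, 2), dtype=bool))
        with pytest.raises(EmptySelectionError):
            select_edema_voxels(volume, mask)


class TestLungWeight:
    def test_pure_gas_voxel(self):
        assert lung_weight([-1000.0], 1.0) == pytest.approx(0.0)

    def test_water_voxel(self):
        assert lung_weight([0.0], 1.0) == pytest.approx(1.0)

    def test_thousand_cubic_mm_voxels(self):
        # 1000 voxels of 1 mm^3 at -500 HU -> 0.5 g
        assert lung_weight([-500.0] * 1000, 0.001) == pytest.approx(0.5)

    def test_empty_selection_error(self):
        with pytest.raises(EmptySelectionError):
            lung_weight([], 1.0)

    def test_bad_voxel_volume(self):
        with pytest.raises(ValidationError):
            lung_weight([0.0], 0.0)

    @given(
        st.lists(st.floats(min_value=-1000, max_value=200), min_size=1, max_size=200),
        st.floats(min_value=1e-3, max_value=10.0),
    )
    def test_sum_equals_mean_hu_closed_form(self, vals, vv):
        # per-voxel sum == (1 - meanHU/(-1000)) * total volume
        arr = np.asarray(vals)
        direct = lung_weight(arr, vv)
        closed = (1.0 - arr.mean() / -1000.0) * (arr.size * vv)
        assert direct == pytest.approx(closed, rel=1e-12, abs=1e-12)

    def test_monotone_in_hu(self, rng):
        vals = rng.uniform(-700, 199, size=50)
        w0 = lung_weight(vals, 1.0)
        vals[7] += 1.0
        assert lung_weight(vals, 1.0) > w0


class TestExpectedLungWeight:
    @pytest.mark.parametrize(
        "height, expected",
        [(1.77, -1806.1 + 1633.7 * 1.77), (2.00, -1806.1 + 1633.7 * 2.00)],
    )
    def test_printed_coefficients(self, height, expected):
        assert expected_lung_weight(PatientAnthro(height, "male")) == pytest.approx(expected)

    def test_near_root_is_error(self):
        with pytest.warns(UserWarning):
            anthro = PatientAnthro(1.10, "male")
        with pytest.raises(ValidationError, match="not valid"):
            expected_lung_weight(anthro)

    def test_strictly_increasing_in_height(self):
        heights = np.linspace(1.3, 2.1, 9)
        w = [expected_lung_weight(PatientAnthro(h, "male")) for h in heights]
        assert np.all(np.diff(w) > 0)


class TestIdealBodyWeight:
    def test_male_reference(self):
        assert ideal_body_weight(PatientAnthro(1.77, "male")) == pytest.approx(50 + 0.91 * 24.6)

    def test_base_cases(self):
        assert ideal_body_weight(PatientAnthro(1.524, "female")) == pytest.approx(45.5)
        assert ideal_body_weight(PatientAnthro(1.524, "male")) == pytest.approx(50.0)

    def test_warns_below_base_height(self):
        with pytest.warns(UserWarning, match="below"):
            ideal_body_weight(PatientAnthro(1.40, "male"))

    def test_unknown_rule(self):
        with pytest.raises(ValidationError, match="unknown IBW rule"):
            ideal_body_weight(PatientAnthro(1.77, "male"), rule="nope")


class TestEvlwiCt:
    def test_excess_500g(self):
        ibw = 50 + 0.91 * 24.6
        assert evlwi_ct(1585.549, 1085.549, ibw) == pytest.approx(500.0 / ibw)

    def test_zero_excess(self):
        assert evlwi_ct(1085.5, 1085.5, 72.39) == 0.0

    def test_negative_allowed(self):
        assert evlwi_ct(1000.0, 1085.5, 72.39) == pytest.approx(-85.5 / 72.39)

    def test_ibw_must_be_positive(self):
        with pytest.raises(ValidationError):
            evlwi_ct(1000.0, 900.0, 0.0)


def _homogeneous_phantom(n_ml=2000, hu=-300.0):
    # n_ml voxels of exactly 1 ml (10 mm cubes)
    vals = np.full((10, 10, n_ml // 100), hu).reshape(10, 10, -1)
    volume = make_volume(vals, spacing=(10.0, 10.0, 10.0))
    mask = make_mask(np.ones_like(vals, dtype=bool), spacing=(10.0, 10.0, 10.0))
    return volume, mask


class TestQuantifyScan:
    def test_homogeneous_phantom(self, anthro):
        volume, mask = _homogeneous_phantom()
        res = quantify_scan(volume, mask, anthro)
        assert res.lung_volume == pytest.approx(2000.0)
        assert res.lung_weight == pytest.approx(0.7 * 2000.0, rel=1e-12)
        expected_evlwi = (1400.0 - (-1806.1 + 1633.7 * 1.77)) / (50 + 0.91 * 24.6)
        assert res.evlwi_ct == pytest.approx(expected_evlwi, rel=1e-12)
        assert res.evlwi_ct == pytest.approx(4.34, abs=0.01)

    def test_contrast_invariance(self, anthro):
        volume, mask = _homogeneous_phantom()
        baseline = quantify_scan(volume, mask, anthro)
        hu = volume.hu.copy()
        hu.flat[:150] = 400.0  # contrast-like, outside the window
        perturbed = quantify_scan(make_volume(hu, (10.0, 10.0, 10.0)), mask, anthro)
        assert perturbed.lung_weight == pytest.approx(
            (1.0 + -300.0 / 1000.0) * (2000 - 150), rel=1e-12
        )
        # result over retained voxels is unchanged per-voxel
        assert perturbed.mean_hu == baseline.mean_hu

    def test_window_invariance_outside_mask(self, anthro):
        # enlarging the mask onto out-of-window voxels changes nothing
        vals = np.full((10, 10, 20), -300.0)
        vals[:, :, 15:] = 999.0
        volume = make_volume(vals, (10.0, 10.0, 10.0))
        small = make_mask(vals < 0, (10.0, 10.0, 10.0))
        full = make_mask(np.ones_like(vals, dtype=bool), (10.0, 10.0, 10.0))
        r_small = quantify_scan(volume, small, anthro)
        r_full = quantify_scan(volume, full, anthro)
        assert r_small == r_full

    def test_mean_hu_inside_window(self, anthro, rng):
        vals = rng.uniform(-900, 400, size=(8, 8, 8))
        volume = make_volume(vals)
        mask = make_mask(np.ones_like(vals, dtype=bool))
        res = quantify_scan(volume, mask, anthro)
        assert DEFAULT_WINDOW.lower <= res.mean_hu <= DEFAULT_WINDOW.upper

    def test_full_mask_volume_option(self, anthro):
        vals = np.full((10, 10, 20), -300.0)
        vals[:, :, 15:] = 999.0
        volume = make_volume(vals, (10.0, 10.0, 10.0))
        mask = make_mask(np.ones_like(vals, dtype=bool), (10.0, 10.0, 10.0))
        windowed = quantify_scan(volume, mask, anthro)
        full = quantify_scan(volume, mask, anthro, window_only=False)
        assert windowed.lung_volume == pytest.approx(1500.0)
        assert full.lung_volume == pytest.approx(2000.0)
        assert full.lung_weight == windowed.lung_weight

    def test_evlwi_decreasing_in_height(self):
        volume, mask = _homogeneous_phantom()
        r_short = quantify_scan(volume, mask, PatientAnthro(1.60, "male"))
        r_tall = quantify_scan(volume, mask, PatientAnthro(1.90, "male"))
        assert r_tall.evlwi_ct < r_short.evlwi_ct

    def test_empty_mask(self, anthro):
        volume = make_volume(np.zeros((2, 2, 2)))
        mask = make_mask(np.zeros((2, 2, 2), dtype=bool))
        with pytest.raises(EmptySelectionError):
            quantify_scan(volume, mask, anthro)

    def test_result_invariant_consistency(self, anthro, rng):
        vals = rng.uniform(-700, 200, size=(6, 6, 6))
        res = quantify_scan(make_volume(vals), make_mask(np.ones_like(vals, dtype=bool)), anthro)
        assert res.evlwi_ct == pytest.approx(
            (res.lung_weight - res.expected_lung_weight) / res.ibw, rel=1e-12
        )


class TestDice:
    def test_identical(self):
        m = make_mask(np.ones((3, 3, 3), dtype=bool))
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((2, 2, 2), dtype=bool)
        b = np.zeros((2, 2, 2), dtype=bool)
        a[0, 0, 0] = True
        b[1, 1, 1] = True
        assert dice_coefficient(make_mask(a), make_mask(b)) == 0.0

    def test_subset_two_thirds(self):
        b = np.zeros((5, 5, 5), dtype=bool)
        b.flat[:100] = True
        a = np.zeros((5, 5, 5), dtype=bool)
        a.flat[:50] = True
        assert dice_coefficient(make_mask(a), make_mask(b)) == pytest.approx(2 * 50 / 150)

    def test_symmetry(self, rng):
        a = make_mask(rng.random((4, 4, 4)) > 0.5)
        b = make_mask(rng.random((4, 4, 4)) > 0.5)
        assert dice_coefficient(a, b) == dice_coefficient(b, a)

    def test_one_iff_equal(self, rng):
        a = rng.random((4, 4, 4)) > 0.5
        b = a.copy()
        b[0, 0, 0] = ~b[0, 0, 0]
        assert dice_coefficient(make_mask(a), make_mask(b)) < 1.0

    def test_both_empty(self):
        e = make_mask(np.zeros((2, 2, 2), dtype=bool))
        with pytest.raises(NumericError):
            dice_coefficient(e, e)

    def test_shape_mismatch(self):
        a = make_mask(np.ones((2, 2, 2), dtype=bool))
        b = make_mask(np.ones((3, 3, 3), dtype=bool))
        with pytest.raises(AlignmentError):
            dice_coefficient(a, b)
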