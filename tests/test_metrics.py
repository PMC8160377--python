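"""DVH metrics, constraints, overlap and distance metrics."""

import numpy as np
import pytest

from planrbe import (
    Constraint,
    DoseGrid,
    Geometry,
    PlanCase,
    Role,
    StructureMask,
    StructureSet,
    check_constraints,
    cumulative_dvh,
    dose_at_volume,
    min_distance,
    overlap_metrics,
)

from conftest import uniform_dose


def brute_force_dx(doses, percent):
    """Largest level with at least percent% of voxels >= level."""
    candidates = np.unique(doses)[::-1]
    for level in candidates:
        if (doses >= level).mean() * 100 >= percent:
            return level
    return doses.min()


class TestDoseAtVolume:
    def test_uniform_dose_all_quantiles_equal(self, small_geo, full_mask):
        dose = uniform_dose(small_geo, 70.0)
        for pct in (98, 50, 2):
            assert dose_at_volume(dose, full_mask, pct) == 70.0

    def test_1_to_100_gy_d50_is_51(self):
        geo = Geometry((0, 0, 0), (1, 1, 1), (100, 1, 1))
        dose = DoseGrid(geo, np.arange(1.0, 101.0).reshape(100, 1, 1), 20)
        mask = StructureMask("m", Role.OTHER, geo, np.ones(geo.dims, bool))
        assert dose_at_volume(dose, mask, 50) == 51.0
        assert dose_at_volume(dose, mask, 100) == 1.0
        assert dose_at_volume(dose, mask, 0) == 100.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_grids(self, seed, small_geo, full_mask):
        rng = np.random.default_rng(seed)
        dose = DoseGrid(small_geo, rng.uniform(0, 80, small_geo.dims), 20)
        d = dose.values[full_mask.occupancy]
        for pct in (98, 50, 37, 2):
            assert dose_at_volume(dose, full_mask, pct) == pytest.approx(
                brute_force_dx(d, pct)
            )

    def test_order_property(self, small_geo, full_mask):
        rng = np.random.default_rng(8)
        dose = DoseGrid(small_geo, rng.uniform(0, 80, small_geo.dims), 20)
        d98 = dose_at_volume(dose, full_mask, 98)
        d50 = dose_at_volume(dose, full_mask, 50)
        d2 = dose_at_volume(dose, full_mask, 2)
        assert d98 <= d50 <= d2


class TestCumulativeDvh:
    def test_two_level_field(self, small_geo, full_mask):
        values = np.full(small_geo.dims, 60.0)
        values[:5] = 70.0
        dose = DoseGrid(small_geo, values, 20)
        curve = cumulative_dvh(dose, full_mask, bin_width=1.0)
        at = lambda lv: curve.volume_pct[curve.dose_gy == lv].iloc[0]
        assert at(0.0) == 100.0 and at(60.0) == 100.0
        assert at(61.0) == 50.0 and at(70.0) == 50.0
        assert at(71.0) == 0.0
        assert np.all(np.diff(curve.volume_pct) <= 0)

    def test_consistent_with_dx(self, small_geo, full_mask):
        rng = np.random.default_rng(3)
        dose = DoseGrid(small_geo, rng.uniform(0, 80, small_geo.dims), 20)
        curve = cumulative_dvh(dose, full_mask, bin_width=0.1)
        d30 = dose_at_volume(dose, full_mask, 30)
        below = curve[curve.dose_gy <= d30]
        assert below.volume_pct.iloc[-1] >= 30.0


class TestConstraints:
    def _case(self, geo, urethra_dose):
        values = np.full(geo.dims, urethra_dose)
        dose = DoseGrid(geo, values, 20)
        mask = StructureMask("urethra", Role.URETHRA, geo, np.ones(geo.dims, bool))
        return PlanCase("c", "plan1", dose, StructureSet([mask]))

    def test_uniform_60_passes_62p4(self, small_geo):
        case = self._case(small_geo, 60.0)
        table = check_constraints(
            case, [Constraint(Role.URETHRA, "D2%", "<=", 62.4)]
        )
        assert list(table.status) == ["pass"]

    def test_uniform_65_fails_62p4(self, small_geo):
        case = self._case(small_geo, 65.0)
        table = check_constraints(
            case, [Constraint(Role.URETHRA, "D2%", "<=", 62.4)]
        )
        assert list(table.status) == ["fail"]

    def test_boost_coverage_passes(self, small_geo):
        values = np.full(small_geo.dims, 70.0)
        dose = DoseGrid(small_geo, values, 20)
        mask = StructureMask("ptv3_1", Role.PTV3_1, small_geo,
                             np.ones(small_geo.dims, bool))
        case = PlanCase("c", "plan1", dose, StructureSet([mask]))
        table = check_constraints(case, [Constraint(Role.PTV3_1, "D98%", ">=", 68.6)])
        assert list(table.status) == ["pass"]

    def test_missing_structure_not_evaluable(self, small_geo):
        case = self._case(small_geo, 60.0)
        table = check_constraints(
            case, [Constraint(Role.BLADDER, "D2%", "<=", 70.0)]
        )
        assert list(table.status) == ["not-evaluable"]
        assert np.isnan(table.measured.iloc[0])


class TestOverlap:
    def test_identical_masks(self, full_mask):
        m = overlap_metrics(full_mask, full_mask)
        assert m["dice"] == 1.0 and m["coverage_of_a_by_b_pct"] == 100.0

    def test_disjoint_masks(self, small_geo):
        a = np.zeros(small_geo.dims, bool)
        b = np.zeros(small_geo.dims, bool)
        a[0], b[9] = True, True
        m = overlap_metrics(
            StructureMask("a", Role.OTHER, small_geo, a),
            StructureMask("b", Role.OTHER, small_geo, b),
        )
        assert m["dice"] == 0.0 and m["intersection_cm3"] == 0.0

    def test_counting_example(self, small_geo):
        # |A| = 100, |B| = 60, |A∩B| = 50 at 1 mm3 voxels
        a = np.zeros(small_geo.dims, bool)
        b = np.zeros(small_geo.dims, bool)
        a.ravel()[:100] = True
        b.ravel()[50:110] = True
        m = overlap_metrics(
            StructureMask("a", Role.OTHER, small_geo, a),
            StructureMask("b", Role.OTHER, small_geo, b),
        )
        assert m["dice"] == pytest.approx(2 * 50 / 160)
        assert m["intersection_cm3"] == pytest.approx(0.05)
        assert m["coverage_of_a_by_b_pct"] == pytest.approx(50.0)

    def test_both_empty_warns(self, small_geo):
        e = StructureMask("e", Role.OTHER, small_geo, np.zeros(small_geo.dims, bool))
        with pytest.warns(UserWarning, match="empty"):
            m = overlap_metrics(e, e)
        assert m["dice"] == 0.0


class TestMinDistance:
    def test_overlapping_masks_zero(self, full_mask):
        assert min_distance(full_mask, full_mask) == 0.0

    def test_single_voxels_along_anisotropic_axis(self):
        geo = Geometry((0, 0, 0), (1.0, 1.0, 1.5), (8, 8, 8))
        a = np.zeros(geo.dims, bool)
        b = np.zeros(geo.dims, bool)
        a[2, 2, 1] = True
        b[2, 2, 4] = True  # 3 voxels apart along the 1.5 mm axis
        d = min_distance(
            StructureMask("a", Role.OTHER, geo, a),
            StructureMask("b", Role.OTHER, geo, b),
        )
        assert d == pytest.approx(4.5)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_all_pairs_brute_force(self, seed):
        geo = Geometry((0, 0, 0), (1.5, 1.0, 2.0), (8, 8, 8))
        rng = np.random.default_rng(seed)
        a = rng.random(geo.dims) > 0.95
        b = rng.random(geo.dims) > 0.95
        if not (a.any() and b.any()):
            return
        ma = StructureMask("a", Role.OTHER, geo, a)
        mb = StructureMask("b", Role.OTHER, geo, b)
        pa = np.argwhere(a) * geo.spacing
        pb = np.argwhere(b) * geo.spacing
        brute = min(np.linalg.norm(x - y) for x in pa for y in pb)
        assert min_distance(ma, mb) == pytest.approx(brute, abs=1e-9)
        assert min_distance(mb, ma) == pytest.approx(brute, abs=1e-9)

    def test_per_slice_minima_bound_3d_minimum(self):
        geo = Geometry((0, 0, 0), (1, 1, 1), (10, 10, 10))
        rng = np.random.default_rng(1)
        a = rng.random(geo.dims) > 0.9
        b = rng.random(geo.dims) > 0.9
        ma = StructureMask("a", Role.OTHER, geo, a)
        mb = StructureMask("b", Role.OTHER, geo, b)
        per_slice, overall = min_distance(ma, mb, mode="per_axial_slice")
        assert all(v >= min_distance(ma, mb) - 1e-12 for v in per_slice.values())
        assert overall == min(per_slice.values())

    def test_empty_operand_rejected(self, small_geo, full_mask):
        empty = StructureMask("e", Role.OTHER, small_geo,
                              np.zeros(small_geo.dims, bool))
        with pytest.raises(ValueError, match="non-empty"):
            min_distance(full_mask, empty)
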