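"""Isoeffect conversion and the three dose-response models.

Expected values are frozen from independent closed-form evaluation:
EQD0(60 Gy, 3 Gy/fx, a/b 1.6) = 60 * (1 + 3/1.6) = 172.5;
TCP(uniform) = exp(-rho V exp(-alpha EQD0)); gEUD by direct power mean;
the LKB probit via scipy's normal CDF on the independently computed gEUD;
the seriality product form by a brute-force per-compartment oracle.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from planrbe import (
    DoseGrid,
    Geometry,
    LKBParams,
    LQParams,
    Role,
    SerialityParams,
    StructureMask,
    calibrate_alpha,
    eqd,
    geud,
    ntcp_lkb,
    ntcp_relative_seriality,
    seriality_response,
    tcp_poisson,
    tcp_uniform,
    voxel_eqd,
)

from conftest import uniform_dose

LQ = LQParams(rho_cl=2.8e8, alpha=0.12050, ab_ratio=1.6)
LKB = LKBParams(d50=116.7, m=0.23, n=0.3, ab_ratio=5.0)
BLADDER = SerialityParams(d50=80.0, gamma=2.59, s=1.3, ab_ratio=3.0)


def brute_force_seriality(doses_eqd2, dv, params):
    """Independent product-form oracle over explicit compartments."""
    prod = 1.0
    for d, v in zip(doses_eqd2, dv):
        p = 2.0 ** (-np.exp(np.e * params.gamma * (1.0 - d / params.d50)))
        prod *= (1.0 - p**params.s) ** v
    return (1.0 - prod) ** (1.0 / params.s)


class TestEqd:
    @pytest.mark.parametrize(
        "D,d,ab,x,expected",
        [
            (60.0, 3.0, 1.6, 0.0, 172.5),
            (70.0, 3.5, 1.6, 2.0, 99.1666667),  # boost schedule near 100 Gy EQD2
            (50.0, 2.0, 3.0, 2.0, 50.0),  # d = x is the identity
        ],
    )
    def test_worked_examples(self, D, d, ab, x, expected):
        assert eqd(D, d, ab, x) == pytest.approx(expected, rel=1e-9)

    def test_rejects_negative_dose(self):
        with pytest.raises(ValueError):
            eqd(-1.0, 1.0, 1.6)

    def test_voxelwise_matches_scalar(self, small_geo):
        rng = np.random.default_rng(5)
        dose = DoseGrid(small_geo, rng.uniform(0, 80, small_geo.dims), 20)
        out = voxel_eqd(dose, 1.6, 0.0)
        per_voxel = eqd(dose.values, dose.values / 20, 1.6, 0.0)
        assert np.allclose(out.values, per_voxel, rtol=0, atol=0)
        assert out.values[dose.values == 0].sum() == 0.0

    def test_uniform_60gy_20fx(self, small_geo):
        out = voxel_eqd(uniform_dose(small_geo, 60.0, 20), 1.6, 0.0)
        assert np.allclose(out.values, 172.5)


class TestTcp:
    def test_uniform_matches_closed_form_to_1e10(self, small_geo, full_mask):
        eqd0 = uniform_dose(small_geo, 172.5)
        v = full_mask.volume_cm3
        expected = tcp_uniform(172.5, v, LQ)
        assert tcp_poisson(eqd0, full_mask, LQ) == pytest.approx(expected, rel=1e-10)

    def test_median_histo_volume_worked_example(self):
        # 4.5 cm^3 at uniform EQD0 172.5 Gy -> TCP ~= 0.306
        assert tcp_uniform(172.5, 4.5, LQ) == pytest.approx(0.3063, abs=5e-4)

    def test_zero_dose_gives_zero_control(self, small_geo, full_mask):
        assert tcp_poisson(uniform_dose(small_geo, 0.0), full_mask, LQ) < 1e-300

    def test_saturates_to_one(self, small_geo, full_mask):
        assert tcp_poisson(uniform_dose(small_geo, 500.0), full_mask, LQ) > 0.999

    def test_empty_target_rejected(self, small_geo):
        empty = StructureMask("e", Role.GTV_HISTO, small_geo,
                              np.zeros(small_geo.dims, bool))
        with pytest.raises(ValueError, match="empty"):
            tcp_poisson(uniform_dose(small_geo, 60.0), empty, LQ)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.5, 10.0))
    def test_monotone_under_voxelwise_increase(self, seed, bump):
        geo = Geometry((0, 0, 0), (2.0, 2.0, 2.0), (5, 5, 5))
        rng = np.random.default_rng(seed)
        base = rng.uniform(0, 120, geo.dims)
        mask = StructureMask("t", Role.GTV_HISTO, geo, rng.random(geo.dims) > 0.3)
        if mask.is_empty():
            return
        lo = tcp_poisson(DoseGrid(geo, base, 20), mask, LQ)
        hi = tcp_poisson(DoseGrid(geo, base + bump, 20), mask, LQ)
        assert 0.0 <= lo <= hi <= 1.0


class TestGeud:
    def test_n1_is_arithmetic_mean(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0, 80, 200)
        assert geud(d, 1.0) == pytest.approx(d.mean(), rel=1e-12)

    def test_uniform_dose_any_exponent(self):
        for n in (0.1, 0.3, 1.0):
            assert geud(np.full(50, 63.0), n) == pytest.approx(63.0, rel=1e-12)

    def test_two_halves_worked_example(self):
        assert geud(np.array([100.0, 120.0]), 0.3) == pytest.approx(111.05, abs=0.05)

    def test_bounded_by_min_and_max(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(10, 90, 500)
        g = geud(d, 0.3)
        assert d.min() <= g <= d.max()

    def test_fractional_volumes_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            geud(np.array([1.0, 2.0]), 0.5, np.array([0.3, 0.3]))


class TestLkb:
    def test_half_probability_at_uniform_d50_eqd2(self, small_geo, full_mask):
        # physical dose whose EQD2 (a/b = 5) equals D50 = 116.7 Gy
        # EQD2 = D (1 + d/5) / 1.4 with d = D/20 -> solve quadratic
        coeffs = [1 / 100.0, 1.0, -116.7 * 1.4]
        D = max(np.roots(coeffs))
        ntcp = ntcp_lkb(uniform_dose(small_geo, D, 20), full_mask, LKB)
        assert ntcp == pytest.approx(0.5, abs=1e-9)

    def test_two_compartment_worked_example(self):
        # EQD2 doses 100/120 in equal halves: gEUD ~111.05, NTCP ~0.417.
        # Build a physical grid whose EQD2 equals those values.
        geo = Geometry((0, 0, 0), (1, 1, 1), (2, 1, 1))

        def phys(eqd2):
            return max(np.roots([1 / (5.0 * 20), 1.0, -eqd2 * 1.4]))

        dose = DoseGrid(geo, np.array([phys(100.0), phys(120.0)]).reshape(2, 1, 1), 20)
        mask = StructureMask("o", Role.URETHRA, geo, np.ones(geo.dims, bool))
        assert ntcp_lkb(dose, mask, LKB) == pytest.approx(0.4165, abs=5e-4)

    def test_zero_dose_limit(self, small_geo, full_mask):
        ntcp = ntcp_lkb(uniform_dose(small_geo, 0.0, 20), full_mask, LKB)
        from scipy.special import ndtr

        assert ntcp == pytest.approx(float(ndtr(-1 / 0.23)), rel=1e-9)
        assert ntcp < 1e-5

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_and_in_range(self, seed):
        geo = Geometry((0, 0, 0), (2, 2, 2), (4, 4, 4))
        rng = np.random.default_rng(seed)
        base = rng.uniform(0, 150, geo.dims)
        mask = StructureMask("o", Role.URETHRA, geo, np.ones(geo.dims, bool))
        lo = ntcp_lkb(DoseGrid(geo, base, 20), mask, LKB)
        hi = ntcp_lkb(DoseGrid(geo, base + 5.0, 20), mask, LKB)
        assert 0.0 < lo < hi < 1.0


class TestSeriality:
    def test_uniform_d50_with_s1_is_half(self, small_geo, full_mask):
        params = SerialityParams(d50=80.0, gamma=2.59, s=1.0, ab_ratio=3.0)
        # 80 Gy in 40 fx gives d = 2 Gy, so EQD2 equals the physical dose
        ntcp = ntcp_relative_seriality(
            uniform_dose(small_geo, 80.0, 40), full_mask, params
        )
        assert ntcp == pytest.approx(seriality_response(80.0, 80.0, 2.59), abs=1e-12)
        assert ntcp == pytest.approx(0.5, abs=1e-12)

    def test_zero_dose_is_negligible(self, small_geo, full_mask):
        ntcp = ntcp_relative_seriality(
            uniform_dose(small_geo, 0.0, 20), full_mask, BLADDER
        )
        assert ntcp < 1e-200

    def test_half_volume_at_d50_worked_example(self):
        # half the organ at EQD2 = D50, half at 0, s = 1.3 -> ~0.322
        assert brute_force_seriality([80.0, 0.0], [0.5, 0.5], BLADDER) == pytest.approx(
            0.3222, abs=5e-4
        )
        geo = Geometry((0, 0, 0), (1, 1, 1), (2, 1, 1))
        coeffs = [1 / (3.0 * 20), 1.0, -80.0 * (1 + 2 / 3.0)]
        D = max(np.roots(coeffs))
        dose = DoseGrid(geo, np.array([D, 0.0]).reshape(2, 1, 1), 20)
        mask = StructureMask("o", Role.BLADDER, geo, np.ones(geo.dims, bool))
        assert ntcp_relative_seriality(dose, mask, BLADDER) == pytest.approx(
            0.3222, abs=5e-4
        )

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 10))
    def test_matches_brute_force_on_random_compartments(self, seed, k):
        rng = np.random.default_rng(seed)
        eqd2 = rng.uniform(0, 120, k)
        dv = np.full(k, 1.0 / k)
        # grid route: one voxel per compartment, physical dose from EQD2
        phys = np.array(
            [max(np.roots([1 / (3.0 * 20), 1.0, -e * (1 + 2 / 3.0)])) if e > 0 else 0.0
             for e in eqd2]
        )
        geo = Geometry((0, 0, 0), (1, 1, 1), (k, 1, 1))
        dose = DoseGrid(geo, phys.reshape(k, 1, 1), 20)
        mask = StructureMask("o", Role.BLADDER, geo, np.ones(geo.dims, bool))
        got = ntcp_relative_seriality(dose, mask, BLADDER)
        want = brute_force_seriality(eqd2, dv, BLADDER)
        assert got == pytest.approx(want, abs=1e-9)

    def test_extreme_dose_stays_in_unit_interval(self, small_geo, full_mask):
        hot = ntcp_relative_seriality(
            uniform_dose(small_geo, 1000.0, 20), full_mask, BLADDER
        )
        assert 0.0 <= hot <= 1.0 and np.isfinite(hot)


class TestCalibrateAlpha:
    def test_single_volume_matches_closed_form(self):
        alpha = calibrate_alpha([1.0], (60.0, 3.0), 1.6, 2.8e8, 0.70)
        closed = np.log(2.8e8 * 1.0 / (-np.log(0.70))) / 172.5
        assert alpha == pytest.approx(closed, abs=1e-8)
        assert alpha == pytest.approx(0.11873, abs=1e-5)

    def test_round_trip_reproduces_target(self):
        alpha = calibrate_alpha([2.0, 4.0, 6.0], (60.0, 3.0), 1.6, 2.8e8, 0.5)
        eqd0 = 172.5
        tcps = [np.exp(-2.8e8 * v * np.exp(-alpha * eqd0)) for v in (2.0, 4.0, 6.0)]
        assert np.mean(tcps) == pytest.approx(0.5, abs=1e-7)

    def test_recovers_planted_alpha(self):
        rng = np.random.default_rng(11)
        volumes = rng.uniform(1.5, 7.0, 10)
        alpha_true = 0.1205
        eqd0 = 172.5
        target = float(
            np.mean([np.exp(-2.8e8 * v * np.exp(-alpha_true * eqd0)) for v in volumes])
        )
        alpha_hat = calibrate_alpha(volumes, (60.0, 3.0), 1.6, 2.8e8, target)
        assert abs(alpha_hat - alpha_true) < 1e-6

    def test_per_volume_aggregation(self):
        a = calibrate_alpha([1.0, 1.0], (60.0, 3.0), 1.6, 2.8e8, 0.7,
                            aggregation="per-volume")
        assert a == pytest.approx(0.11873, abs=1e-5)

    def test_rejects_degenerate_target(self):
        with pytest.raises(ValueError):
            calibrate_alpha([1.0], (60.0, 3.0), 1.6, 2.8e8, 1.0)
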