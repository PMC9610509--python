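"""Fatigue curves, SWT criterion, life maps: arithmetic oracles and
inverse-function properties."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rcdlife import (basquin_cycles, basquin_stress, calibrate_sigma_L,
                     cycles_to_years, life_field, swt_cycles, swt_equivalent)
from rcdlife.fatigue import FatigueParams
from rcdlife.fem import StressField


PARAMS = FatigueParams(sigma_yield=60.0, sigma_fatigue=20.0, beta=0.1)


def uniform_field(voigt, n_nodes=5):
    nodal = np.tile(np.asarray(voigt, dtype=float), (n_nodes, 1))
    return StressField(nodal=nodal, element=nodal[:1])


class TestSigmaLCalibration:
    def test_zero_exponent_reduces_to_difference(self):
        assert calibrate_sigma_L(60.0, 20.0, 0.0) == pytest.approx(40.0)

    def test_arithmetic_oracle(self):
        # 10**0.3 * 40
        assert calibrate_sigma_L(60.0, 20.0, 0.1) \
            == pytest.approx(79.81049259875518, rel=1e-12)

    @given(st.floats(25.0, 200.0), st.floats(1.0, 20.0), st.floats(0.01, 0.5))
    def test_curve_passes_through_yield_at_1e3(self, sy, sf, beta):
        p = FatigueParams(sigma_yield=sy, sigma_fatigue=sf, beta=beta)
        assert basquin_stress(1e3, p) == pytest.approx(sy, rel=1e-12)

    def test_invalid_material_rejected(self):
        with pytest.raises(ValueError, match="yield point"):
            calibrate_sigma_L(20.0, 60.0, 0.1)


class TestBasquin:
    def test_single_cycle_stress(self):
        assert basquin_stress(1.0, PARAMS) \
            == pytest.approx(PARAMS.sigma_fatigue + PARAMS.sigma_L)

    def test_megacycle_oracle(self):
        # 20 + 79.81047...*10**-0.6
        assert basquin_stress(1e6, PARAMS) == pytest.approx(40.04748934509089, rel=1e-9)

    def test_strictly_decreasing(self):
        n = np.logspace(0, 9, 40)
        s = basquin_stress(n, PARAMS)
        assert np.all(np.diff(s) < 0)

    def test_yield_maps_to_1000_cycles(self):
        assert basquin_cycles(60.0, PARAMS) == pytest.approx(1e3, rel=1e-12)

    def test_fatigue_limit_maps_to_cap(self):
        assert basquin_cycles(PARAMS.sigma_fatigue, PARAMS) == PARAMS.n_max
        assert basquin_cycles(0.0, PARAMS) == PARAMS.n_max

    def test_peak_stress_maps_to_one_cycle(self):
        assert basquin_cycles(PARAMS.sigma_fatigue + PARAMS.sigma_L, PARAMS) \
            == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [10.0, 1e3, 1e6])
    def test_round_trip(self, n):
        assert basquin_cycles(basquin_stress(n, PARAMS), PARAMS) \
            == pytest.approx(n, rel=1e-6)


class TestSWT:
    def test_compression_gated_to_zero(self):
        assert swt_equivalent(-5.0, 10.0) == 0.0
        assert swt_equivalent(0.0, 10.0) == 0.0

    def test_fully_reversed_reduces_to_amplitude(self):
        sa = 12.0
        assert swt_equivalent(sa, 2 * sa) == pytest.approx(sa)

    def test_pulsating_oracle(self):
        s = 9.0
        assert swt_equivalent(s, s) == pytest.approx(s / np.sqrt(2))

    def test_below_endurance_term_caps(self):
        su, sv, b = PARAMS.swt
        assert swt_cycles(su, PARAMS) == PARAMS.n_max

    def test_peak_maps_to_one_cycle(self):
        su, sv, b = PARAMS.swt
        assert swt_cycles(su + sv, PARAMS) == pytest.approx(1.0)

    def test_round_trip_at_1e4(self):
        su, sv, b = PARAMS.swt
        sigma = su + sv * 1e4 ** (-b)
        assert swt_cycles(sigma, PARAMS) == pytest.approx(1e4, rel=1e-6)


class TestCyclesToYears:
    def test_zero_cycles_zero_years(self):
        assert cycles_to_years(0.0) == 0.0

    def test_default_schedule_megacycle_oracle(self):
        # 3 meals x 1000 chews x 365 days = 1.095e6 cycles per year
        assert cycles_to_years(1.095e6, 3.0, 1000.0) == pytest.approx(1.0)

    def test_linear_in_cycles(self):
        assert cycles_to_years(2e5) == pytest.approx(2 * cycles_to_years(1e5))

    def test_invalid_schedule(self):
        with pytest.raises(ValueError):
            cycles_to_years(1e6, meals_per_day=0.0)


class TestLifeField:
    def test_uniform_yield_stress_is_red_everywhere(self):
        field = uniform_field([60.0, 0, 0, 0, 0, 0])
        life = life_field(field, PARAMS, criterion="basquin-mises")
        assert np.allclose(life.cycles, 1e3, rtol=1e-9)
        assert np.all(life.hazard == 2)

    def test_below_fatigue_limit_non_hazardous(self):
        field = uniform_field([5.0, 0, 0, 0, 0, 0])
        life = life_field(field, PARAMS, criterion="basquin-mises")
        assert np.all(life.cycles == PARAMS.n_max)
        assert np.all(life.hazard == 0)

    def test_monotone_in_stress(self):
        nodal = np.zeros((2, 6))
        nodal[0, 0], nodal[1, 0] = 50.0, 30.0
        life = life_field(StressField(nodal=nodal, element=nodal),
                          PARAMS, criterion="swt-principal")
        assert life.cycles[0] <= life.cycles[1]

    def test_pure_compression_never_fails_under_swt(self):
        """Macaulay gating: all principal stresses <= 0 -> N_max everywhere."""
        field = uniform_field([-80.0, -50.0, -90.0, 0, 0, 0])
        life = life_field(field, PARAMS, criterion="swt-principal")
        assert np.all(life.cycles == PARAMS.n_max)
        assert np.all(life.hazard == 0)

    @given(st.floats(0.0, 3.0), st.floats(0.0, 3.0))
    def test_life_non_increasing_under_stress_scaling(self, a, b):
        lo, hi = sorted([a, b])
        base = np.array([[40.0, 10.0, -5.0, 8.0, 0.0, 3.0]])
        for criterion in ("basquin-mises", "swt-principal"):
            n_lo = life_field(StressField(lo * base, lo * base), PARAMS,
                              criterion=criterion).cycles[0]
            n_hi = life_field(StressField(hi * base, hi * base), PARAMS,
                              criterion=criterion).cycles[0]
            assert n_hi <= n_lo

    def test_years_consistent_with_schedule(self):
        field = uniform_field([45.0, 0, 0, 0, 0, 0])
        life = life_field(field, PARAMS, criterion="basquin-mises",
                          meals_per_day=3.0, chews_per_meal=1000.0)
        assert life.years[0] == pytest.approx(life.cycles[0] / 1.095e6)

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError, match="criterion"):
            life_field(uniform_field([1.0, 0, 0, 0, 0, 0]), PARAMS,
                       criterion="nope")
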