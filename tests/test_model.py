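"""Closed-form ROD model: worked examples, inversions, and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gabarod as g
from gabarod.model import InconsistentMeasurementError


@pytest.fixture(scope="module")
def benchmark_params():
    return g.reference_parameters()


class TestGamma:
    def test_zero_agonist_gives_unity(self, benchmark_params):
        assert g.gamma(0.0, benchmark_params) == 1.0

    def test_published_kd_values_at_1mm(self):
        # K_C = 78.5 uM, K_O = 120 nM, N = 2 at 1 mM agonist
        p = g.GatingParameters(L=1.0, k_c=78.5e-6, k_o=0.12e-6, n_sites=2)
        expected = ((1 + 1e-3 / 78.5e-6) / (1 + 1e-3 / 0.12e-6)) ** 2
        assert g.gamma(1e-3, p) == pytest.approx(expected, rel=1e-12)
        assert g.gamma(1e-3, p) == pytest.approx(2.72e-6, rel=5e-3)

    def test_saturating_limit(self, benchmark_params):
        p = benchmark_params
        limit = (p.k_o / p.k_c) ** p.n_sites
        assert g.gamma(10.0, p) == pytest.approx(limit, rel=1e-3)

    def test_strictly_decreasing(self, benchmark_params):
        xs = np.geomspace(1e-9, 1e-2, 50)
        vals = g.gamma(xs, benchmark_params)
        assert np.all(np.diff(vals) < 0)

    def test_negative_concentration_rejected(self, benchmark_params):
        with pytest.raises(ValueError):
            g.gamma(-1e-9, benchmark_params)


class TestForwardEquations:
    @pytest.mark.parametrize(
        "l_gamma,expected",
        [(0.0, 1.0), (1.0, 0.5), (1 / 0.71 - 1, 0.71)],
    )
    def test_popen_peak(self, l_gamma, expected):
        assert g.popen_peak(l_gamma) == pytest.approx(expected, rel=1e-12)

    def test_popen_peak_rejects_negative(self):
        with pytest.raises(ValueError):
            g.popen_peak(-0.1)

    def test_popen_steady_state_examples(self):
        assert g.popen_steady_state(0.4085, 0.1459) == pytest.approx(0.121, abs=5e-4)
        assert g.popen_steady_state(1.0, math.inf) == pytest.approx(0.5)
        assert g.popen_steady_state(0.0, 1.0) == pytest.approx(0.5)

    def test_steady_state_below_peak(self):
        for lg in (0.1, 1.0, 10.0):
            for q in (0.01, 1.0, 100.0):
                assert g.popen_steady_state(lg, q) <= g.popen_peak(lg)

    def test_p_desensitized_published_values(self):
        lg = 1 / 0.71 - 1
        q = g.q_from_steady_state(0.121, lg)
        q_star = g.q_from_steady_state(0.077, lg)
        assert g.p_desensitized(lg, q) == pytest.approx(0.829, abs=1e-3)
        assert g.p_desensitized(lg, q_star) == pytest.approx(0.892, abs=1e-3)

    def test_p_desensitized_vanishes_without_desensitization(self):
        assert g.p_desensitized(0.4085, 1e12) == pytest.approx(0.0, abs=1e-11)


class TestInversions:
    @pytest.mark.parametrize(
        "p_peak,expected",
        [(1.0, 0.0), (0.71, 1 / 0.71 - 1), (0.012, 1 / 0.012 - 1)],
    )
    def test_lgamma_from_peak(self, p_peak, expected):
        assert g.lgamma_from_peak(p_peak) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.01])
    def test_lgamma_from_peak_domain(self, bad):
        with pytest.raises(ValueError):
            g.lgamma_from_peak(bad)

    def test_q_from_steady_state_values(self):
        lg = 1 / 0.71 - 1
        assert g.q_from_steady_state(0.121, lg) == pytest.approx(0.1459, abs=1e-4)
        assert g.q_from_steady_state(0.077, lg) == pytest.approx(0.0864, abs=1e-4)

    def test_q_sentinel_at_peak(self):
        lg = 1.0
        assert g.q_from_steady_state(0.5, lg) == math.inf

    def test_inconsistent_measurement_names_values(self):
        with pytest.raises(InconsistentMeasurementError, match="0.6"):
            g.q_from_steady_state(0.6, 1.0)


class TestOccupancy:
    def test_high_gaba_worked_example(self):
        occ = g.occupancy_from_measurements(g.MeasuredResponse(1e-3, 0.71, 0.121))
        assert occ.p_open == pytest.approx(0.121)
        assert occ.p_desensitized == pytest.approx(0.829, abs=1e-3)
        assert occ.p_resting == pytest.approx(0.049, abs=1e-3)
        assert g.high_affinity_fraction(occ) == pytest.approx(0.95, abs=5e-3)

    def test_high_gaba_with_steroid(self):
        occ = g.occupancy_from_measurements(g.MeasuredResponse(1e-3, 0.71, 0.077))
        assert occ.p_desensitized == pytest.approx(0.892, abs=1e-3)
        assert g.high_affinity_fraction(occ) == pytest.approx(0.97, abs=5e-3)

    def test_no_sag_means_no_desensitization(self):
        occ = g.occupancy_from_measurements(g.MeasuredResponse(1e-3, 0.4, 0.4))
        assert occ.p_desensitized == pytest.approx(0.0, abs=1e-12)
        assert occ.p_resting + occ.p_open == pytest.approx(1.0, abs=1e-12)

    def test_predict_low_agonist_transferred_q(self):
        lg = 1 / 0.71 - 1
        q = g.q_from_steady_state(0.121, lg)
        occ = g.predict_low_agonist(q, 0.012)
        assert occ.p_open == pytest.approx(0.0111, abs=2e-4)

    def test_predict_low_agonist_limits(self):
        occ = g.predict_low_agonist(1e15, 0.012)
        assert occ.p_desensitized == pytest.approx(0.0, abs=1e-10)
        assert occ.p_open == pytest.approx(0.012, rel=1e-6)
        occ = g.predict_low_agonist(1.0, 1.0)
        assert (occ.p_resting, occ.p_open, occ.p_desensitized) == pytest.approx(
            (0.0, 0.5, 0.5), abs=1e-12
        )

    def test_all_resting_has_zero_high_affinity(self):
        occ = g.StateOccupancy(1.0, 0.0, 0.0)
        assert g.high_affinity_fraction(occ) == 0.0


class TestBindingFoldChange:
    def test_identical_occupancies(self):
        occ = g.occupancy_from_measurements(g.MeasuredResponse(1e-3, 0.71, 0.121))
        assert g.binding_fold_change(occ, occ) == pytest.approx(1.0)

    def test_saturating_gaba_small_change(self):
        c = g.occupancy_from_measurements(g.MeasuredResponse(1e-3, 0.71, 0.121))
        t = g.occupancy_from_measurements(g.MeasuredResponse(1e-3, 0.71, 0.077))
        assert g.binding_fold_change(c, t) == pytest.approx(1.02, abs=0.01)

    def test_low_muscimol_rounded_inputs_give_2_to_3_fold(self):
        c = g.occupancy_from_measurements(g.MeasuredResponse(20e-9, 0.012, 0.011))
        t = g.occupancy_from_measurements(g.MeasuredResponse(20e-9, 0.012, 0.009))
        assert 2.0 <= g.binding_fold_change(c, t) <= 3.0

    def test_zero_control_fraction_rejected(self):
        occ0 = g.StateOccupancy(1.0, 0.0, 0.0)
        occ1 = g.StateOccupancy(0.5, 0.25, 0.25)
        with pytest.raises(ZeroDivisionError):
            g.binding_fold_change(occ0, occ1)


log_grid = st.floats(min_value=1e-3, max_value=1e3)


class TestProperties:
    @settings(max_examples=200, derandomize=True)
    @given(l_gamma=log_grid, q=log_grid)
    def test_conservation(self, l_gamma, q):
        p_open = g.popen_steady_state(l_gamma, q)
        p_des = g.p_desensitized(l_gamma, q)
        p_rest = l_gamma * p_open
        assert p_rest + p_open + p_des == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(l_gamma=log_grid, q=log_grid)
    def test_round_trip_q(self, l_gamma, q):
        p_ss = g.popen_steady_state(l_gamma, q)
        assert g.q_from_steady_state(p_ss, l_gamma) == pytest.approx(q, rel=1e-9)

    @settings(max_examples=200, derandomize=True)
    @given(l_gamma=log_grid, q=log_grid)
    def test_steady_state_ratio_is_inverse_q(self, l_gamma, q):
        p_open = g.popen_steady_state(l_gamma, q)
        p_des = g.p_desensitized(l_gamma, q)
        assert p_des / p_open == pytest.approx(1.0 / q, rel=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(l_gamma=log_grid)
    def test_infinite_q_reduces_to_two_state(self, l_gamma):
        assert g.popen_steady_state(l_gamma, math.inf) == pytest.approx(
            g.popen_peak(l_gamma), rel=1e-12
        )

    def test_popen_peak_monotone_in_lgamma(self):
        lg = np.geomspace(1e-3, 1e3, 100)
        assert np.all(np.diff(g.popen_peak(lg)) < 0)

    def test_popen_steady_state_monotone_in_q(self):
        qs = np.geomspace(1e-3, 1e3, 100)
        vals = g.popen_steady_state(1.0, qs)
        assert np.all(np.diff(vals) > 0)


class TestGatingParameters:
    def test_affinity_ordering_enforced(self):
        with pytest.raises(ValueError):
            g.GatingParameters(L=1.0, k_c=1e-7, k_o=1e-6)

    def test_reference_parameters_reproduce_benchmark(self):
        p = g.reference_parameters()
        assert g.popen_peak(p.lgamma(1e-3)) == pytest.approx(0.71, rel=1e-9)
        assert g.popen_steady_state(p.lgamma(1e-3), p.q) == pytest.approx(0.121, abs=5e-4)
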