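"""Unit and property tests for the relaxation-kinetics operations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poreblock.constants import DEFAULT_CONSTANTS
from poreblock.relaxation import (
    RelaxationPoint,
    TracePair,
    average_then_solve,
    average_trace_pairs,
    fit_block_phase,
    fit_monoexponential,
    fit_voltage_dependence,
    rates_from_on_off,
    rates_from_relaxation,
    relaxation_from_pair,
    solve_then_average,
    trace_ratio,
)

VT = DEFAULT_CONSTANTS.thermal_voltage_mv


class TestMonoexponentialFit:
    def test_exact_recovery_of_generating_function(self):
        t = np.arange(0.0, 300.1, 3.0)
        y = 1.0 - 0.7 * (1.0 - np.exp(-t / 30.0))
        fit = fit_monoexponential(t, y)
        assert not fit.no_relaxation
        assert fit.tau == pytest.approx(30.0, rel=1e-6)
        assert fit.baseline == pytest.approx(0.3, abs=1e-8)
        assert fit.amplitude == pytest.approx(0.7, abs=1e-8)
        assert fit.rss < 1e-16

    def test_constant_series_is_flagged_not_crashed(self):
        t = np.arange(0.0, 60.0, 3.0)
        fit = fit_monoexponential(t, np.ones_like(t))
        assert fit.no_relaxation
        assert math.isnan(fit.tau)

    def test_noisy_amplitude_below_3_mad_is_flagged(self, rng):
        t = np.arange(0.0, 300.0, 3.0)
        y = 1.0 + rng.normal(0.0, 0.05, t.size)
        fit = fit_monoexponential(t, y)
        assert fit.no_relaxation

    def test_too_few_samples_raises(self):
        with pytest.raises(ValueError, match="at least 5"):
            fit_monoexponential([0, 1, 2, 3], [1, 2, 3, 4])

    def test_window_outside_span_raises(self):
        t = np.arange(0.0, 30.0, 3.0)
        with pytest.raises(ValueError, match="window"):
            fit_monoexponential(t, np.exp(-t / 5), window=(-10.0, 20.0))

    def test_recovers_generator_output_tau_161s_with_noise(self):
        # wash-out phase of a seeded synthetic time course, sd 0.01
        from poreblock.synthetic import GeneratorConfig, gen_block_timecourse, simple_wash_schedule

        config = GeneratorConfig(seed=42, noise_sd=0.01)
        course = gen_block_timecourse(
            config, 73.0, 1.0 / 161.3, 2.5e-4,
            simple_wash_schedule(1000.0, 30.0, 300.0, 2.5e-4),
        )
        fit = fit_block_phase(course, "off")
        assert fit.tau == pytest.approx(161.3, rel=0.05)

    def test_deterministic_given_identical_input(self):
        t = np.arange(0.0, 200.0, 3.0)
        y = 0.3 + 0.6 * np.exp(-t / 40.0) + 0.01 * np.sin(t)
        f1 = fit_monoexponential(t, y)
        f2 = fit_monoexponential(t, y)
        assert f1.tau == f2.tau and f1.amplitude == f2.amplitude


class TestRatesFromOnOff:
    def test_roundtrip_through_reference_rates(self):
        # tau values forward-computed from k_on = 73 uM^-1 s^-1,
        # k_off = 0.0062 s^-1 at 0.25 nM blocker
        rates = rates_from_on_off(tau_on=40.90, tau_off=161.3, toxin_conc=2.5e-4)
        assert rates.k_on == pytest.approx(73.0, rel=1e-3)
        assert rates.k_off == pytest.approx(0.0062, rel=1e-3)
        assert rates.k_d == pytest.approx(0.085, abs=0.001)

    def test_irreversible_block_limit(self):
        rates = rates_from_on_off(tau_on=40.0, tau_off=1e9, toxin_conc=1e-3)
        assert rates.k_off == pytest.approx(0.0, abs=1e-8)
        assert rates.k_on == pytest.approx(1.0 / (40.0 * 1e-3), rel=1e-6)

    def test_equal_time_constants_rejected(self):
        with pytest.raises(ValueError, match="slower"):
            rates_from_on_off(100.0, 100.0, 1e-3)

    def test_zero_toxin_rejected(self):
        with pytest.raises(ValueError, match="toxin"):
            rates_from_on_off(40.0, 160.0, 0.0)

    @given(
        k_on=st.floats(1.0, 5000.0),
        k_off=st.floats(1e-4, 100.0),
        tx=st.floats(1e-6, 1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_forward_inverse_roundtrip_to_ten_digits(self, k_on, k_off, tx):
        from hypothesis import assume

        # a measurable on-relaxation requires non-negligible equilibrium block
        assume(k_on * tx >= 1e-4 * k_off)
        tau_off = 1.0 / k_off
        tau_on = 1.0 / (k_on * tx + k_off)
        rates = rates_from_on_off(tau_on, tau_off, tx)
        assert rates.k_on == pytest.approx(k_on, rel=1e-10)
        assert rates.k_off == pytest.approx(k_off, rel=1e-10)


def _make_pair(t_ms, ctrl, tox, v=0.0):
    return TracePair(
        times=t_ms, control_current=ctrl, toxin_current=tox,
        step_voltage=v, holding_voltage=-120.0, toxin_conc=0.005,
    )


class TestTraceRatio:
    def test_proportional_traces_give_constant_ratio(self):
        t = np.arange(0.0, 100.0, 0.5)
        ctrl = (1.0 - np.exp(-t / 3.0)) ** 4
        _, ratio = trace_ratio(_make_pair(t, ctrl, 0.5 * ctrl))
        assert np.allclose(ratio, 0.5)

    def test_ratio_equals_analytic_relaxation(self):
        # block relaxing 0.3 -> 0.43 with tau = 141 ms over a 2-ms activation
        t = np.arange(0.0, 500.0, 0.5)
        ctrl = 1.0 - np.exp(-t / 2.0)
        u = 0.43 - 0.13 * np.exp(-t / 141.0)
        times, ratio = trace_ratio(_make_pair(t, ctrl, ctrl * u))
        expected = 0.43 - 0.13 * np.exp(-times / 141.0)
        assert np.allclose(ratio, expected, rtol=1e-12)
        fit = fit_monoexponential(times, ratio)
        assert fit.tau == pytest.approx(141.0, rel=1e-6)
        assert fit.baseline == pytest.approx(0.43, rel=1e-6)

    def test_zero_control_rejected(self):
        t = np.arange(0.0, 10.0, 0.5)
        with pytest.raises(ValueError, match="no analyzable window"):
            trace_ratio(_make_pair(t, np.zeros_like(t), np.zeros_like(t)))

    def test_bad_guard_fraction_rejected(self):
        t = np.arange(0.0, 10.0, 0.5)
        ctrl = np.ones_like(t)
        with pytest.raises(ValueError, match="guard_fraction"):
            trace_ratio(_make_pair(t, ctrl, ctrl), guard_fraction=1.5)

    def test_guard_masks_early_activation(self):
        t = np.arange(0.0, 100.0, 0.5)
        ctrl = 1.0 - np.exp(-t / 5.0)
        times, _ = trace_ratio(_make_pair(t, ctrl, 0.5 * ctrl), guard_fraction=0.5)
        assert times[0] > 0.0
        assert np.abs(ctrl[np.searchsorted(t, times[0])]) >= 0.5 * ctrl[-20:].mean()


class TestRatesFromRelaxation:
    def test_reference_voltage_zero_solution(self):
        # tau and asymptote forward-evaluated from k_off = 3.02 s^-1 and
        # k_on = 812 uM^-1 s^-1 at 5 nM blocker
        point = RelaxationPoint(voltage=0.0, tau=0.1412, asymptote=0.4266)
        k_on, k_off = rates_from_relaxation(point, 0.005)
        assert k_off == pytest.approx(3.02, rel=0.01)
        assert k_on == pytest.approx(812.0, rel=0.01)

    def test_asymptote_bounds_named_in_errors(self):
        with pytest.raises(ValueError, match="upper bound"):
            rates_from_relaxation(RelaxationPoint(0.0, 0.1, 1.0), 0.005)
        with pytest.raises(ValueError, match="lower bound"):
            rates_from_relaxation(RelaxationPoint(0.0, 0.1, 0.0), 0.005)

    def test_doubling_toxin_halves_k_on_only(self):
        point = RelaxationPoint(voltage=0.0, tau=0.1, asymptote=0.4)
        k_on1, k_off1 = rates_from_relaxation(point, 0.005)
        k_on2, k_off2 = rates_from_relaxation(point, 0.010)
        assert k_on2 == pytest.approx(k_on1 / 2.0, rel=1e-12)
        assert k_off2 == k_off1

    @given(
        k_on=st.floats(10.0, 1e4),
        k_off=st.floats(0.01, 100.0),
        tx=st.floats(1e-4, 0.1),
    )
    @settings(max_examples=200, deadline=None)
    def test_forward_inverse_roundtrip_to_ten_digits(self, k_on, k_off, tx):
        rate = k_on * tx + k_off
        point = RelaxationPoint(voltage=0.0, tau=1.0 / rate, asymptote=k_off / rate)
        got_on, got_off = rates_from_relaxation(point, tx)
        assert got_on == pytest.approx(k_on, rel=1e-10)
        assert got_off == pytest.approx(k_off, rel=1e-10)


class TestVoltageDependence:
    def test_two_point_fit_is_exact(self):
        k0, z = 3.02, 0.47
        points = [(0.0, k0), (50.0, k0 * math.exp(z * 50.0 / VT))]
        fit = fit_voltage_dependence(points)
        assert fit.k_at_zero == pytest.approx(k0, rel=1e-12)
        assert fit.z_delta == pytest.approx(z, rel=1e-12)

    def test_voltage_independent_rates_give_zero_valence(self):
        fit = fit_voltage_dependence([(-50.0, 2.0), (0.0, 2.0), (50.0, 2.0)])
        assert fit.z_delta == pytest.approx(0.0, abs=1e-12)

    def test_e_fold_per_50mV_is_about_half_a_charge(self):
        voltages = np.arange(-50.0, 75.0, 25.0)
        points = [(v, math.exp(v / 50.0)) for v in voltages]
        fit = fit_voltage_dependence(points)
        assert fit.z_delta == pytest.approx(VT / 50.0, rel=1e-9)
        assert 0.45 < fit.z_delta < 0.55

    def test_noiseless_exact_at_any_number_of_voltages(self):
        k0, z = 812.0, 0.106
        voltages = [-30.0, 0.0, 10.0, 45.0, 60.0]
        points = [(v, k0 * math.exp(z * v / VT)) for v in voltages]
        fit = fit_voltage_dependence(points)
        assert fit.k_at_zero == pytest.approx(k0, rel=1e-9)
        assert fit.z_delta == pytest.approx(z, rel=1e-9)

    def test_single_voltage_rejected(self):
        with pytest.raises(ValueError, match="distinct voltages"):
            fit_voltage_dependence([(0.0, 1.0), (0.0, 2.0)])

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_voltage_dependence([(0.0, 1.0), (50.0, -2.0)])


class TestMultiCellAggregation:
    def test_identical_replicates_match_single_solve(self):
        point = RelaxationPoint(voltage=50.0, tau=0.04, asymptote=0.37)
        group = [RelaxationPoint(50.0, 0.04, 0.37) for _ in range(5)]
        expected = rates_from_relaxation(point, 0.005)
        got = average_then_solve(group, 0.005)[50.0]
        assert (got.k_on, got.k_off) == pytest.approx(expected, rel=1e-12)
        assert got.n_cells == 5

    def test_average_first_then_solve_at_the_means(self):
        group = [
            RelaxationPoint(0.0, 0.14, 0.42),
            RelaxationPoint(0.0, 0.15, 0.44),
        ]
        got = average_then_solve(group, 0.005)[0.0]
        # hand-computed means: tau 0.145 s, asymptote 0.43
        assert got.k_off == pytest.approx(0.43 / 0.145, rel=1e-12)
        assert got.k_on == pytest.approx((1 - 0.43) / (0.145 * 0.005), rel=1e-12)

    def test_mixed_toxin_concentrations_rejected(self):
        group = [RelaxationPoint(0.0, 0.14, 0.42), RelaxationPoint(0.0, 0.15, 0.44)]
        with pytest.raises(ValueError, match="mixed toxin"):
            average_then_solve(group, [0.005, 0.010])

    def test_solve_then_average_agrees_for_identical_cells(self):
        group = [RelaxationPoint(20.0, 0.05, 0.35) for _ in range(3)]
        a = average_then_solve(group, 0.005)[20.0]
        b = solve_then_average(group, 0.005)[20.0]
        assert a.k_on == pytest.approx(b.k_on, rel=1e-12)
        assert a.k_off == pytest.approx(b.k_off, rel=1e-12)

    def test_average_trace_pairs_requires_common_grid(self):
        t = np.arange(0.0, 10.0, 0.5)
        p1 = _make_pair(t, np.ones_like(t), np.ones_like(t))
        p2 = _make_pair(t + 0.1, np.ones_like(t), np.ones_like(t))
        with pytest.raises(ValueError, match="time grid"):
            average_trace_pairs([p1, p2])

    def test_average_trace_pairs_averages_pointwise(self):
        t = np.arange(0.0, 10.0, 0.5)
        p1 = _make_pair(t, np.full_like(t, 1.0), np.full_like(t, 0.2))
        p2 = _make_pair(t, np.full_like(t, 3.0), np.full_like(t, 0.6))
        avg = average_trace_pairs([p1, p2])
        assert np.allclose(avg.control_current, 2.0)
        assert np.allclose(avg.toxin_current, 0.4)
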