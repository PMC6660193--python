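"""Generator round trips: noiseless output composed with a fitter is identity."""

import numpy as np
import pytest

from poreblock.relaxation import (
    fit_block_phase,
    fit_monoexponential,
    relaxation_from_pair,
    trace_ratio,
)
from poreblock.state_model import SchemeParams, unblocked_fraction
from poreblock.synthetic import (
    GeneratorConfig,
    ScheduleSegment,
    gen_block_timecourse,
    gen_titration_table,
    gen_tonic_table,
    gen_trace_family,
    simple_wash_schedule,
)
from poreblock.titration import LangmuirParams, langmuir_eval

NOISELESS = GeneratorConfig(noise_sd=0.0, table_noise_sd=0.0)


class TestBlockTimecourse:
    def test_noiseless_equilibrium_and_on_tau(self):
        # k_on = 73, k_off = 0.0062, 0.25 nM: equilibrium unblocked fraction
        # k_off/(k_on[Tx]+k_off) = 0.254 and on-phase tau = 40.9 s
        course = gen_block_timecourse(
            NOISELESS, 73.0, 0.0062, 2.5e-4,
            simple_wash_schedule(1200.0, 60.0, 460.0, 2.5e-4),
        )
        fit_on = fit_block_phase(course, "on")
        fit_off = fit_block_phase(course, "off")
        assert fit_on.tau == pytest.approx(40.90, abs=0.05)
        assert fit_on.baseline == pytest.approx(0.2536, abs=1e-3)
        assert fit_off.tau == pytest.approx(1.0 / 0.0062, rel=1e-6)

    def test_zero_toxin_gives_flat_unity(self):
        course = gen_block_timecourse(
            NOISELESS, 73.0, 0.0062, 0.0,
            [ScheduleSegment(0.0, 300.0, 0.0)],
        )
        assert np.allclose(course.amplitudes, 1.0)

    def test_on_off_phases_are_exactly_monoexponential(self):
        course = gen_block_timecourse(
            NOISELESS, 73.0, 0.0062, 2.5e-4,
            simple_wash_schedule(1200.0, 60.0, 460.0, 2.5e-4),
        )
        assert fit_block_phase(course, "on").rss < 1e-18
        assert fit_block_phase(course, "off").rss < 1e-18

    def test_overlapping_schedule_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            gen_block_timecourse(
                NOISELESS, 73.0, 0.0062, 1e-3,
                [ScheduleSegment(0.0, 100.0, 1e-3), ScheduleSegment(50.0, 150.0, 0.0)],
            )

    def test_recovery_rate_follows_perfused_condition(self):
        # alternating-solution wash-out: the off rate switches with the
        # solution currently flowing, with no memory of the blocking one
        koff_na, koff_k = 0.0062, 0.013
        schedule = [
            ScheduleSegment(0.0, 200.0, 2.5e-4, label="block"),
            ScheduleSegment(200.0, 400.0, 0.0, k_off=koff_na, label="high-Na"),
            ScheduleSegment(400.0, 700.0, 0.0, k_off=koff_k, label="high-K"),
        ]
        course = gen_block_timecourse(NOISELESS, 73.0, 0.013, 2.5e-4, schedule)
        t, y = course.times, course.amplitudes
        blocked = 1.0 - y
        # instantaneous log-slope of the blocked fraction in each segment
        for (t0, t1), expected in [((210.0, 390.0), koff_na), ((410.0, 690.0), koff_k)]:
            sel = (t >= t0) & (t <= t1)
            slope = np.polyfit(t[sel], np.log(blocked[sel]), 1)[0]
            assert -slope == pytest.approx(expected, rel=1e-6)

    def test_perfusion_lag_slows_onset_but_keeps_equilibrium(self):
        sched = simple_wash_schedule(900.0, 30.0, 600.0, 2.5e-4)
        instant = gen_block_timecourse(NOISELESS, 73.0, 0.0062, 2.5e-4, sched)
        lagged = gen_block_timecourse(
            GeneratorConfig(noise_sd=0.0, perfusion_tau=10.0),
            73.0, 0.0062, 2.5e-4, sched,
        )
        i_mid = np.searchsorted(instant.times, 90.0)
        assert lagged.amplitudes[i_mid] > instant.amplitudes[i_mid]
        assert lagged.amplitudes[np.searchsorted(lagged.times, 590.0)] == pytest.approx(
            instant.amplitudes[np.searchsorted(instant.times, 590.0)], abs=1e-3
        )

    def test_noise_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            gen_block_timecourse(
                GeneratorConfig(noise_sd=0.01), 73.0, 0.0062, 2.5e-4,
                simple_wash_schedule(100.0, 10.0, 50.0, 2.5e-4),
            )

    def test_bit_reproducible_under_fixed_seed(self):
        sched = simple_wash_schedule(300.0, 30.0, 150.0, 2.5e-4)
        a = gen_block_timecourse(GeneratorConfig(seed=9, noise_sd=0.01),
                                 73.0, 0.0062, 2.5e-4, sched)
        b = gen_block_timecourse(GeneratorConfig(seed=9, noise_sd=0.01),
                                 73.0, 0.0062, 2.5e-4, sched)
        assert np.array_equal(a.amplitudes, b.amplitudes)


class TestTraceFamily:
    def test_noiseless_ratio_fit_recovers_tau_and_asymptote(self, scheme_10k, constants):
        pair = gen_trace_family(NOISELESS, scheme_10k, 5.6, 2.0, [50.0])[0]
        point = relaxation_from_pair(pair)
        koff_v = 5.6 * constants.boltzmann_factor(0.29, 50.0)
        k_on = 1e3 * 5.6 / 1.7
        tau_true = 1.0 / (k_on * 0.005 + koff_v)
        u_inf = 1.0 / (1.0 + 5.0 / (1.7 * constants.boltzmann_factor(0.29, 50.0)))
        assert point.tau == pytest.approx(tau_true, rel=1e-6)
        assert point.asymptote == pytest.approx(u_inf, rel=1e-6)

    def test_zero_toxin_ratio_is_unity(self):
        scheme = SchemeParams(1.84, 1.7, 0.29, 3.9, -66.0, toxin_conc=0.0)
        pair = gen_trace_family(NOISELESS, scheme, 5.6, 2.0, [40.0])[0]
        _, ratio = trace_ratio(pair)
        assert np.allclose(ratio, 1.0, atol=1e-12)

    def test_holding_voltage_changes_start_not_open_kinetics(self, scheme_10k):
        rest = gen_trace_family(NOISELESS, scheme_10k, 5.6, 2.0, [50.0],
                                holding_voltage=-120.0)[0]
        depol = gen_trace_family(NOISELESS, scheme_10k, 5.6, 2.0, [50.0],
                                 holding_voltage=-60.0)[0]
        p_rest = relaxation_from_pair(rest)
        p_depol = relaxation_from_pair(depol)
        assert p_rest.tau == pytest.approx(p_depol.tau, rel=1e-6)
        assert p_rest.asymptote == pytest.approx(p_depol.asymptote, rel=1e-6)
        u0_rest = float(unblocked_fraction(-120.0, scheme_10k))
        u0_depol = float(unblocked_fraction(-60.0, scheme_10k))
        assert abs(u0_rest - u0_depol) > 0.01

    def test_ratio_analysis_insensitive_to_activation_shape(self, scheme_10k):
        p4 = gen_trace_family(NOISELESS, scheme_10k, 5.6, 2.0, [50.0])[0]
        cfg1 = GeneratorConfig(noise_sd=0.0, activation_power=1)
        p1 = gen_trace_family(cfg1, scheme_10k, 5.6, 2.0, [50.0])[0]
        a = relaxation_from_pair(p4)
        b = relaxation_from_pair(p1)
        assert a.tau == pytest.approx(b.tau, rel=1e-6)
        assert a.asymptote == pytest.approx(b.asymptote, rel=1e-6)

    def test_inactivation_scale_cancels_in_the_ratio(self, scheme_10k):
        cfg = GeneratorConfig(noise_sd=0.0, inactivation_scale=0.9)
        scaled = gen_trace_family(cfg, scheme_10k, 5.6, 2.0, [50.0],
                                  holding_voltage=-60.0)[0]
        plain = gen_trace_family(NOISELESS, scheme_10k, 5.6, 2.0, [50.0],
                                 holding_voltage=-60.0)[0]
        assert scaled.control_current.max() < plain.control_current.max()
        a = relaxation_from_pair(scaled)
        b = relaxation_from_pair(plain)
        assert a.tau == pytest.approx(b.tau, rel=1e-9)
        assert a.asymptote == pytest.approx(b.asymptote, rel=1e-9)


class TestTitrationTable:
    def test_noiseless_single_replicate_is_exact_model(self):
        params = LangmuirParams(120.0, 56.0, 0.56, kind="k_on")
        points = gen_titration_table(NOISELESS, params)
        for p in points:
            assert p.value == pytest.approx(langmuir_eval(params, p.k_conc), rel=1e-12)

    def test_seeded_noise_reproducible_bit_for_bit(self):
        params = LangmuirParams(0.0061, 0.022, 135.0)
        a = gen_titration_table(GeneratorConfig(seed=4), params, replicates=3)
        b = gen_titration_table(GeneratorConfig(seed=4), params, replicates=3)
        assert [p.value for p in a] == [p.value for p in b]
        c = gen_titration_table(GeneratorConfig(seed=5), params, replicates=3)
        assert [p.value for p in a] != [p.value for p in c]


class TestTonicTable:
    def test_noiseless_curve_is_exact_model(self, scheme_10k):
        points = gen_tonic_table(NOISELESS, scheme_10k, [-120.0, -80.0], [-20.0, 40.0])
        for p in points:
            assert p.inhibition_ratio == pytest.approx(
                float(unblocked_fraction(p.voltage, scheme_10k)), rel=1e-12
            )

    def test_open_probability_negligible_at_deep_holding(self, scheme_10k):
        # at -120 mV the open-state pathway contributes < 1e-3 to I/Io
        u = float(unblocked_fraction(-120.0, scheme_10k))
        resting = 1.0 / (1.0 + 5.0 / 1.84)
        assert abs(u - resting) < 1e-3

    def test_regime_labels(self, scheme_10k):
        points = gen_tonic_table(NOISELESS, scheme_10k, [-120.0], [0.0])
        assert points[0].regime == "resting" and points[1].regime == "open"
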