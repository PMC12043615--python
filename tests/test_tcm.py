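"""Tests of the three-component (PCr-LA-O2) model."""
import numpy as np
import pytest
from scipy.integrate import quad

from metpower import synth, tcm
from metpower.types import (
    AthleteProfile,
    BreathSeries,
    EpocFit,
    LactateSamples,
)


def _const_series(vo2_ml_min, duration_s, dt=2.0):
    t = np.arange(0.0, duration_s + dt, dt)
    return BreathSeries(t=t, vo2=np.full(t.size, float(vo2_ml_min)))


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        s = tcm.moving_average_breaths(_const_series(2000, 100), 10)
        assert np.allclose(s.vo2, 2000.0)

    def test_single_spike_attenuated_by_window(self):
        y = np.full(50, 100.0)
        y[25] = 200.0
        s = BreathSeries(t=np.arange(50.0), vo2=y)
        sm = tcm.moving_average_breaths(s, 10)
        assert sm.vo2[25] == pytest.approx(100.0 + 100.0 / 10)

    def test_n1_is_identity(self):
        rng = np.random.default_rng(0)
        s = BreathSeries(t=np.arange(30.0), vo2=rng.uniform(100, 200, 30))
        assert np.allclose(tcm.moving_average_breaths(s, 1).vo2, s.vo2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tcm.moving_average_breaths(_const_series(100, 10), 0)


class TestNetAerobic:
    def test_arithmetic_example(self):
        # accumulated gross 25 L over 10 min, rest 0.3 L/min:
        # net = 25 - 3 = 22 L -> 22 * 20.9 = 459.8 kJ
        s = _const_series(2500.0, 600.0)
        w, net = tcm.net_aerobic_supply(s, 300.0, (0.0, 600.0),
                                        tcm.fixed_equivalent())
        assert net == pytest.approx(22.0, rel=1e-9)
        assert w == pytest.approx(459.8, rel=1e-9)

    def test_resting_exercise_yields_zero(self):
        s = _const_series(300.0, 600.0)
        w, net = tcm.net_aerobic_supply(s, 300.0, (0.0, 600.0),
                                        tcm.fixed_equivalent())
        assert w == pytest.approx(0.0, abs=1e-9)

    def test_negative_net_clipped_with_warning(self):
        s = _const_series(100.0, 600.0)
        with pytest.warns(UserWarning, match="clipped"):
            w, net = tcm.net_aerobic_supply(s, 300.0, (0.0, 600.0),
                                            tcm.fixed_equivalent())
        assert w == 0.0 and net == 0.0

    def test_window_outside_data_rejected(self):
        s = _const_series(2500.0, 600.0)
        with pytest.raises(ValueError):
            tcm.net_aerobic_supply(s, 300.0, (700.0, 800.0),
                                   tcm.fixed_equivalent())


class TestEpocFit:
    def _decay(self, a=1500.0, ta=30.0, b=400.0, tb=300.0, c=300.0,
               noise=0.0, seed=0, dt=2.0):
        t = np.arange(0.0, 421.0, dt)
        y = a * np.exp(-t / ta) + b * np.exp(-t / tb) + c
        if noise:
            rng = np.random.default_rng(seed)
            y = y * (1 + noise * rng.standard_normal(t.size))
        return BreathSeries(t=t, vo2=np.clip(y, 0, None))

    def test_noiseless_round_trip_within_0p1pct(self):
        fit = tcm.fit_epoc(self._decay(), vo2rest_ml_min=300.0)
        assert fit.converged
        assert fit.a == pytest.approx(1500.0, rel=1e-3)
        assert fit.tau_a == pytest.approx(30.0, rel=1e-3)
        assert fit.b == pytest.approx(400.0, rel=1e-3)
        assert fit.tau_b == pytest.approx(300.0, rel=1e-3)
        assert fit.c == pytest.approx(300.0, rel=1e-3)

    def test_degenerate_slow_component(self):
        fit = tcm.fit_epoc(self._decay(b=0.0), vo2rest_ml_min=300.0)
        assert fit.b == pytest.approx(0.0, abs=1.0)
        assert fit.a == pytest.approx(1500.0, rel=5e-3)
        assert fit.tau_a == pytest.approx(30.0, rel=5e-3)

    def test_noisy_tau_a_recovery_smoke(self):
        errs = [abs(tcm.fit_epoc(self._decay(noise=0.04, seed=s),
                                 vo2rest_ml_min=300.0).tau_a - 30.0) / 30.0
                for s in range(8)]
        assert np.median(errs) < 0.15

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="post-exercise"):
            tcm.fit_epoc(self._decay(dt=2.0).__class__(
                t=np.arange(0.0, 100.0, 2.0), vo2=np.full(50, 500.0)))


class TestAlacticSupply:
    def test_zero_amplitude(self):
        fit = EpocFit(a=0.0, tau_a=30.0, b=100.0, tau_b=300.0, c=300.0,
                      rss=0.0, converged=True)
        assert tcm.alactic_supply(fit, tcm.fixed_equivalent()) == 0.0

    def test_analytic_value(self):
        # a = 1 L/min, tau_a = 30 s: (1/60)*30*(1-e^-2)*20.9 = 9.035 kJ
        fit = EpocFit(a=1000.0, tau_a=30.0, b=0.0, tau_b=300.0, c=300.0,
                      rss=0.0, converged=True)
        w = tcm.alactic_supply(fit, tcm.fixed_equivalent())
        assert w == pytest.approx(9.035, abs=2e-3)

    def test_analytic_equals_quadrature(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.uniform(100, 3000)
            ta = rng.uniform(10, 120)
            fit = EpocFit(a=a, tau_a=ta, b=0.0, tau_b=1000.0, c=0.0,
                          rss=0.0, converged=True)
            analytic = tcm.alactic_supply(fit, tcm.fixed_equivalent())
            num, _ = quad(lambda t: a * np.exp(-t / ta), 0.0, 2 * ta)
            num = num / 1000.0 / 60.0 * 20.9
            assert analytic == pytest.approx(num, rel=1e-6)

    def test_unconverged_fit_rejected(self):
        fit = EpocFit(a=1.0, tau_a=30.0, b=0.0, tau_b=300.0, c=0.0,
                      rss=1.0, converged=False)
        with pytest.raises(ValueError):
            tcm.alactic_supply(fit, tcm.fixed_equivalent())


class TestLactate:
    @pytest.mark.parametrize("pre, peak, expected", [
        (1.60, 13.73, 12.13),  # repeated sprints
        (1.62, 1.74, 0.12),    # continuous shuttles
        (1.50, 1.50, 0.0),
    ])
    def test_delta_lactate(self, pre, peak, expected):
        samples = LactateSamples(pre=pre, post=((1, peak * 0.8), (3, peak),
                                                (5, peak * 0.9), (7, peak * 0.8)))
        assert tcm.delta_lactate(samples) == pytest.approx(expected)

    def test_negative_delta_flagged(self):
        samples = LactateSamples(pre=2.0, post=((3, 1.5),))
        with pytest.warns(UserWarning, match="negative"):
            d = tcm.delta_lactate(samples)
        assert d == pytest.approx(-0.5)
        with pytest.warns(UserWarning):
            assert tcm.lactic_supply(d, 70.0, tcm.fixed_equivalent()) == 0.0

    @pytest.mark.parametrize("delta, mass, expected", [
        (0.0, 70.0, 0.0),
        (1.0, 70.0, 4.389),
        (12.13, 81.2, 61.76),  # cohort-mean sprint condition
    ])
    def test_lactic_supply(self, delta, mass, expected):
        w = tcm.lactic_supply(delta, mass, tcm.fixed_equivalent())
        assert w == pytest.approx(expected, abs=5e-3)


class TestEnergyEquivalent:
    def test_table_upper_entry(self):
        ee = tcm.individual_equivalent(1.00)
        assert ee.value == pytest.approx(21.12, abs=0.05)

    def test_clamping_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            hi = tcm.individual_equivalent(1.15)
        assert hi.value == tcm.individual_equivalent(1.00).value
        assert hi.rer_used == 1.00

    def test_fixed_mode(self):
        assert tcm.fixed_equivalent().value == 20.9

    def test_interpolation_monotone(self):
        vals = [tcm.individual_equivalent(r).value
                for r in (0.7, 0.8, 0.9, 1.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestBreakCorrection:
    def test_no_break_windows_is_zero(self):
        s = _const_series(2000.0, 600.0)
        w, net = tcm.break_aerobic_correction(s, [], 300.0,
                                              tcm.fixed_equivalent())
        assert w == 0.0

    def test_resting_level_breaks_are_net_zero(self):
        s = _const_series(300.0, 600.0)
        w, _ = tcm.break_aerobic_correction(s, [(100.0, 200.0)], 300.0,
                                            tcm.fixed_equivalent())
        assert w == pytest.approx(0.0, abs=1e-9)

    def test_overlapping_windows_rejected(self):
        s = _const_series(300.0, 600.0)
        with pytest.raises(ValueError, match="overlap"):
            tcm.break_aerobic_correction(s, [(0.0, 100.0), (50.0, 150.0)],
                                         300.0, tcm.fixed_equivalent())

    def test_exclusion_reduces_aerobic_on_sprints(self, athlete):
        for seed in (0, 1, 2):
            s = synth.generate_session("repeated_sprints", athlete, seed=seed)
            res = tcm.assemble_tcm(s.breaths, s.lactate, athlete,
                                   s.trace.effort_windows(),
                                   s.trace.break_windows())
            assert res.w_aer_excl < res.w_aer_incl


class TestAssemble:
    def test_additivity_identities(self, athlete, zero_noise_sessions):
        s = zero_noise_sessions["repeated_sprints"]
        res = tcm.assemble_tcm(s.breaths, s.lactate, athlete,
                               s.trace.effort_windows(),
                               s.trace.break_windows())
        assert res.w_tot_incl == res.w_aer_incl + res.w_alactic + res.w_lactic
        assert res.w_tot_excl == res.w_aer_excl + res.w_alactic + res.w_lactic
        assert res.w_ana == res.w_alactic + res.w_lactic

    def test_fixed_vs_individual_at_rer_giving_20p9(self, athlete):
        # at RER 0.9576923 the table interpolates to exactly 20.9 kJ/L,
        # so both equivalent modes must coincide
        s = synth.generate_session(
            "repeated_sprints", athlete,
            synth.default_kinetics("repeated_sprints").noiseless(), seed=3)
        rer = 0.95 + 0.05 * (20.9 - 20.86) / (21.12 - 20.86)
        breaths = BreathSeries(t=s.breaths.t, vo2=s.breaths.vo2,
                               vco2=s.breaths.vo2 * rer,
                               phase=s.breaths.phase)
        kw = dict(effort_windows=s.trace.effort_windows(),
                  break_windows=s.trace.break_windows())
        fix = tcm.assemble_tcm(breaths, s.lactate, athlete, ee_mode="fixed", **kw)
        ind = tcm.assemble_tcm(breaths, s.lactate, athlete,
                               ee_mode="individual", **kw)
        assert ind.ee.value == pytest.approx(20.9, rel=1e-9)
        assert ind.w_tot_excl == pytest.approx(fix.w_tot_excl, rel=1e-9)

    def test_missing_post_data_propagates_error(self, athlete):
        s = synth.generate_session("repeated_accelerations", athlete, seed=0)
        cut = s.breaths.t < s.trace.effort_windows()[-1][1] + 60.0
        short = BreathSeries(t=s.breaths.t[cut], vo2=s.breaths.vo2[cut],
                             vco2=s.breaths.vco2[cut])
        with pytest.raises(ValueError, match="post-exercise"):
            tcm.assemble_tcm(short, s.lactate, athlete,
                             s.trace.effort_windows(),
                             s.trace.break_windows())

    @pytest.mark.parametrize("name", ["continuous_shuttles",
                                      "repeated_accelerations",
                                      "repeated_sprints"])
    def test_zero_noise_truth_recovery(self, name, athlete,
                                       zero_noise_sessions):
        s = zero_noise_sessions[name]
        res = tcm.assemble_tcm(s.breaths, s.lactate, athlete,
                               s.trace.effort_windows(),
                               s.trace.break_windows())
        assert res.w_aer_excl == pytest.approx(s.truth.aerobic, rel=0.05)
        assert res.w_alactic == pytest.approx(s.truth.alactic, rel=0.05)
        assert res.w_lactic == pytest.approx(s.truth.lactic, rel=0.05)
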