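import numpy as np
import pytest

from imugrf import gait_kinetics as gk
from imugrf.errors import ContractError
from imugrf.gait_kinetics import StanceEvents
from imugrf.synthetic_runner import RunnerProfile, simulate_force


def half_sine_stance(tc=0.3, rate=1000.0, peak=np.pi / 2, pad=100):
    """Stance F(t) = peak * sin(pi t / tc) embedded in zeros."""
    n = int(round(tc * rate))
    t = np.arange(n + 1) / rate
    y = np.zeros(2 * pad + n + 1)
    y[pad : pad + n + 1] = peak * np.sin(np.pi * t / tc)
    ev = StanceEvents(ic_idx=pad, to_idx=pad + n, rate=rate)
    return y, ev


class TestPostprocessEstimate:
    def test_short_contact_removed(self):
        rate = 100.0
        y = np.zeros(2000)
        y[500:503] = 0.15  # 0.03 s blip
        out = gk.postprocess_estimate(y, rate)
        assert np.all(out[480:520] == 0.0)

    def test_quarter_second_contact_retained(self):
        rate = 100.0
        y = np.zeros(2000)
        t = np.linspace(0, np.pi, 25)
        y[1000:1025] = 2.0 * np.sin(t)
        out = gk.postprocess_estimate(y, rate)
        ev = gk.detect_stances(out, rate)
        assert len(ev) == 1
        assert ev[0].to_s - ev[0].ic_s >= 0.15

    def test_all_zero_input(self):
        out = gk.postprocess_estimate(np.zeros(1000), 100.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_values_below_threshold_zeroed(self):
        y = np.full(1000, 0.04)
        out = gk.postprocess_estimate(y, 100.0)
        np.testing.assert_array_equal(out, 0.0)


class TestDetectStances:
    def test_constructed_indices(self):
        rate = 100.0
        y = np.zeros(300)
        y[100:130] = 1.0  # indices 100..129 supra-threshold
        ev = gk.detect_stances(y, rate)
        assert len(ev) == 1
        assert ev[0].ic_s == pytest.approx(1.00)
        assert ev[0].to_s == pytest.approx(1.29)
        assert gk.contact_time(ev[0]) == pytest.approx(0.29)

    def test_all_below_threshold_empty(self):
        assert gk.detect_stances(np.full(500, 0.04), 100.0) == []

    def test_contact_time_equals_index_difference(self):
        ev = StanceEvents(ic_idx=17, to_idx=56, rate=100.0)
        assert gk.contact_time(ev) == pytest.approx((56 - 17) / 100.0)

    def test_boundary_stances_excluded(self):
        y = np.zeros(200)
        y[0:20] = 1.0
        y[100:120] = 1.0
        y[190:200] = 1.0
        ev = gk.detect_stances(y, 100.0)
        kept = gk.exclude_boundary_stances(ev, len(y))
        assert len(ev) == 3 and len(kept) == 1
        assert kept[0].ic_idx == 100


class TestStanceKinetics:
    def test_half_sine_closed_forms(self):
        y, ev = half_sine_stance(tc=0.3, rate=1000.0)
        k = gk.stance_kinetics(y, ev, 1000.0)
        assert k.stance_average_bw == pytest.approx(1.0, rel=0.005)
        assert k.impulse_bw_s == pytest.approx(0.30, rel=0.005)
        assert k.peak_bw == pytest.approx(np.pi / 2, rel=0.005)

    def test_constant_stance(self):
        rate = 100.0
        y = np.zeros(200)
        y[50:70] = 1.0  # 0.19 s span, 20 samples
        ev = StanceEvents(ic_idx=50, to_idx=69, rate=rate)
        k = gk.stance_kinetics(y, ev, rate)
        assert k.stance_average_bw == pytest.approx(1.0)
        assert k.peak_bw == pytest.approx(1.0)
        assert k.impulse_bw_s == pytest.approx(0.19, rel=1e-6)

    def test_matches_independent_integration_oracle(self):
        profile = RunnerProfile("P", 70.0)
        force, gt = simulate_force(profile, 3.35, 30.0, rate=1000.0)
        bw = (force.force_left + force.force_right) / force.body_weight
        bw = np.where(bw < 0.05, 0.0, bw)
        ev = gk.detect_stances(bw, 1000.0)[3]
        k = gk.stance_kinetics(bw, ev, 1000.0)
        span = bw[ev.ic_idx : ev.to_idx + 1]
        oracle = np.trapezoid(span, dx=1e-3)
        assert k.impulse_bw_s == pytest.approx(oracle, abs=1e-3)

    def test_degenerate_stance_rejected(self):
        y = np.zeros(100)
        y[10:12] = 1.0
        ev = StanceEvents(ic_idx=10, to_idx=11, rate=100.0)
        with pytest.raises(ContractError):
            gk.stance_kinetics(y, ev, 100.0)

    def test_invariants_on_simulator_stances(self):
        profile = RunnerProfile("P", 70.0, impact_amplitude_bw=0.2)
        force, _ = simulate_force(profile, 3.0, 30.0)
        bw = (force.force_left + force.force_right) / force.body_weight
        bw = np.where(bw < 0.05, 0.0, bw)
        for ev in gk.detect_stances(bw, 100.0)[1:-1]:
            k = gk.stance_kinetics(bw, ev, 100.0)
            assert k.stance_average_bw <= k.peak_bw
            assert 0 <= k.impulse_bw_s <= k.peak_bw * k.contact_time_s

    def test_invariant_to_appended_flight_zeros(self):
        y, ev = half_sine_stance()
        k1 = gk.stance_kinetics(y, ev, 1000.0)
        k2 = gk.stance_kinetics(np.concatenate([y, np.zeros(500)]), ev, 1000.0)
        assert k1 == k2


class TestFindImpactPeak:
    def test_early_bump_found(self):
        rate = 1000.0
        y, ev = half_sine_stance(tc=0.3, rate=rate)
        t = np.arange(len(y)) / rate
        center = (ev.ic_idx / rate) + 0.12 * 0.3  # 12% of stance
        y = y + 0.3 * np.exp(-0.5 * ((t - center) / 0.005) ** 2)
        peak_t = gk.find_impact_peak(y, ev, rate)
        assert peak_t == pytest.approx(center, abs=0.005)

    def test_pure_half_sine_has_none(self):
        y, ev = half_sine_stance()
        assert gk.find_impact_peak(y, ev, 1000.0) is None

    def test_two_early_bumps_first_returned(self):
        rate = 1000.0
        y, ev = half_sine_stance(tc=0.3, rate=rate)
        t = np.arange(len(y)) / rate
        ic_t = ev.ic_idx / rate
        for frac in (0.10, 0.25):
            y = y + 0.3 * np.exp(-0.5 * ((t - (ic_t + frac * 0.3)) / 0.004) ** 2)
        peak_t = gk.find_impact_peak(y, ev, rate)
        assert peak_t == pytest.approx(ic_t + 0.10 * 0.3, abs=0.005)


class TestAverageLoadingRate:
    def test_linear_ramp_exactly_40(self):
        rate = 100.0
        y = np.zeros(100)
        # ramp 0 -> 2 BW over 0.05 s to an impact peak at idx 15, then decay
        y[10:16] = np.linspace(0, 2, 6)
        y[16:20] = [1.2, 1.0, 1.4, 1.5]
        y[20:40] = 1.5
        ev = StanceEvents(ic_idx=10, to_idx=39, rate=rate)
        assert gk.find_impact_peak(y, ev, rate) == pytest.approx(0.15)
        assert gk.average_loading_rate(y, ev, rate) == pytest.approx(40.0)

    def test_half_sine_fixed_window_closed_form(self):
        rate = 1000.0
        y, ev = half_sine_stance(tc=0.3, rate=rate)
        # no impact peak -> falls back to the 10%-40% contact-time window
        lr = gk.average_loading_rate(y, ev, rate)
        f = lambda t: (np.pi / 2) * np.sin(np.pi * t / 0.3)
        expected = (f(0.12) - f(0.03)) / 0.09
        assert lr == pytest.approx(expected, rel=0.01)

    def test_scaling_force_doubles_rate(self):
        y, ev = half_sine_stance()
        lr1 = gk.average_loading_rate(y, ev, 1000.0)
        lr2 = gk.average_loading_rate(2 * y, ev, 1000.0)
        assert lr2 == pytest.approx(2 * lr1)

    def test_unknown_strategy_rejected(self):
        y, ev = half_sine_stance()
        with pytest.raises(ContractError):
            gk.average_loading_rate(y, ev, 1000.0, strategy="nope")


class TestSimulatorRecovery:
    """Generator analytic values vs extracted kinetics (the central surface)."""

    def test_recovery_at_1khz_within_tolerances(self):
        profile = RunnerProfile("P", 70.0)
        force, gt = simulate_force(profile, 3.35, 60.0, rate=1000.0)
        bw = (force.force_left + force.force_right) / force.body_weight
        bw = np.where(bw < 0.05, 0.0, bw)
        events = gk.detect_stances(bw, 1000.0)
        assert len(events) == len(gt.steps)
        for ev, s in zip(events[2:-2], gt.steps[2:-2]):
            assert abs(ev.ic_idx - round(s.ic_s * 1000)) <= 1
            assert abs(ev.to_idx - round(s.to_s * 1000)) <= 1
            k = gk.stance_kinetics(bw, ev, 1000.0)
            assert k.stance_average_bw == pytest.approx(s.stance_average_bw, rel=0.01)
            assert k.impulse_bw_s == pytest.approx(s.impulse_bw_s, rel=0.01)
            assert k.peak_bw == pytest.approx(s.peak_bw, rel=0.01)
            assert k.loading_rate_bw_s == pytest.approx(
                s.loading_rate_bw_s, rel=0.02
            )

    def test_events_within_one_sample_at_100hz(self, summed_bw):
        bw, gt = summed_bw
        events = gk.detect_stances(bw, 100.0)
        assert len(events) == len(gt.steps)
        for ev, s in zip(events, gt.steps):
            assert abs(ev.ic_idx - round(s.ic_s * 100)) <= 1
            assert abs(ev.to_idx - round(s.to_s * 100)) <= 1
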