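import numpy as np
import pytest

from imugrf import agreement_eval as ae
from imugrf.errors import ContractError
from imugrf.gait_kinetics import StanceEvents


class TestWaveformRmse:
    def test_identical_is_zero(self):
        x = np.random.default_rng(0).uniform(0, 2, 500)
        assert ae.waveform_rmse(x, x) == 0.0

    def test_constant_offset(self):
        x = np.zeros(100)
        assert ae.waveform_rmse(x, x + 0.1) == pytest.approx(0.1)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        m, e = rng.uniform(0, 2, 333), rng.uniform(0, 2, 333)
        oracle = np.sqrt(sum((a - b) ** 2 for a, b in zip(m, e)) / len(m))
        assert ae.waveform_rmse(m, e) == pytest.approx(oracle, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            ae.waveform_rmse(np.zeros(5), np.zeros(6))


class TestStanceRmse:
    def _setup(self):
        m = np.zeros(300)
        m[50:80] = 1.0
        m[150:180] = 1.2
        ev = [
            StanceEvents(ic_idx=50, to_idx=79, rate=100.0),
            StanceEvents(ic_idx=150, to_idx=179, rate=100.0),
        ]
        return m, ev

    def test_identical_zero(self):
        m, ev = self._setup()
        assert ae.stance_rmse(m, m.copy(), ev) == 0.0

    def test_offset_only_during_stance(self):
        m, ev = self._setup()
        e = m.copy()
        for s in ev:
            e[s.ic_idx : s.to_idx + 1] += 0.1
        assert ae.stance_rmse(m, e, ev) == pytest.approx(0.1)

    def test_swing_error_ignored(self):
        m, ev = self._setup()
        e = m.copy()
        e[0:40] += 5.0  # outside any stance
        assert ae.stance_rmse(m, e, ev) == 0.0

    def test_no_stances_undefined(self):
        assert ae.stance_rmse(np.zeros(10), np.zeros(10), []) is None

    def test_mean_over_stances_oracle(self):
        rng = np.random.default_rng(2)
        m, ev = self._setup()
        e = m + rng.normal(0, 0.1, m.shape)
        per = [
            np.sqrt(np.mean((m[s.ic_idx : s.to_idx + 1] - e[s.ic_idx : s.to_idx + 1]) ** 2))
            for s in ev
        ]
        assert ae.stance_rmse(m, e, ev) == pytest.approx(np.mean(per), abs=1e-12)


class TestEventDifferences:
    def _events(self, ics, tos, rate=100.0):
        return [
            StanceEvents(ic_idx=i, to_idx=t, rate=rate) for i, t in zip(ics, tos)
        ]

    def test_estimate_two_samples_early_is_positive(self):
        m = self._events([100, 200], [130, 230])
        e = self._events([98, 198], [128, 228])
        d = ae.event_differences(m, e)
        np.testing.assert_allclose(d["ic_diffs"], 0.02)
        np.testing.assert_allclose(d["to_diffs"], 0.02)

    def test_identical_all_zero(self):
        m = self._events([100, 200], [130, 230])
        d = ae.event_differences(m, m)
        np.testing.assert_array_equal(d["ic_diffs"], 0.0)
        assert d["unpaired_measured"] == 0

    def test_missing_final_estimated_stance(self):
        m = self._events([100, 200, 300], [130, 230, 330])
        e = self._events([100, 200], [130, 230])
        d = ae.event_differences(m, e)
        assert len(d["ic_diffs"]) == 2
        assert d["unpaired_measured"] == 1


class TestBlandAltman:
    def test_hand_computed_example(self):
        # diffs {0, 1, 2}: mean 1, SD 1 -> LoA 1 -/+ 1.96
        r = ae.bland_altman([1, 2, 3], [1, 1, 1])
        assert r.bias == pytest.approx(1.0)
        assert r.loa_low == pytest.approx(-0.96)
        assert r.loa_high == pytest.approx(2.96)

    def test_equal_vectors(self):
        r = ae.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.bias == 0.0 and r.loa_low == 0.0 and r.loa_high == 0.0

    def test_swapping_arguments_negates_bias(self):
        a, b = [1.0, 2.0, 4.0], [0.5, 1.0, 1.5]
        assert ae.bland_altman(a, b).bias == pytest.approx(-ae.bland_altman(b, a).bias)

    def test_loa_brackets_bias(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(2, 1, 30), rng.normal(2, 1, 30)
        r = ae.bland_altman(a, b)
        assert r.loa_low <= r.bias <= r.loa_high

    def test_too_few_pairs(self):
        with pytest.raises(ContractError):
            ae.bland_altman([1, 2], [1, 1])


class TestCorrelation:
    def test_perfect_linear_strong(self):
        x = np.arange(10.0)
        r2, label = ae.correlation_r2(2 * x + 1, x)
        assert r2 == pytest.approx(1.0)
        assert label == "strong"

    @pytest.mark.parametrize(
        "r2,expected",
        [
            (0.85, "strong"),
            (0.8, "strong"),
            (0.795, "moderate"),
            (0.5, "moderate"),
            (0.4, "weak"),
            (0.3, "weak"),
            (0.133, "negligible"),
        ],
    )
    def test_strength_bands(self, r2, expected):
        assert ae.strength_label(r2) == expected

    def test_zero_variance_undefined(self):
        assert ae.correlation_r2([1, 1, 1], [1, 2, 3]) is None

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=20), rng.normal(size=20)
        xc, yc = x - x.mean(), y - y.mean()
        r = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        r2, _ = ae.correlation_r2(y, x)
        assert r2 == pytest.approx(r * r, abs=1e-12)


class TestRegressionWithCi:
    def test_exact_line(self):
        x = np.arange(10.0)
        r = ae.regression_with_ci(3 * x - 2, x)
        assert r.slope == pytest.approx(3.0)
        assert r.intercept == pytest.approx(-2.0)
        assert r.r2 == pytest.approx(1.0)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 5, 40)
        y = 1.5 * x + rng.normal(0, 0.3, 40)
        r = ae.regression_with_ci(y, x)
        xm, ym = x.mean(), y.mean()
        slope = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
        assert r.slope == pytest.approx(slope, abs=1e-12)
        assert r.intercept == pytest.approx(ym - slope * xm, abs=1e-12)
        assert r.slope_ci[0] < r.slope < r.slope_ci[1]


def _ta(trial_id, velocity, stance=0.2, wave=0.25, ic=0.01, to=0.02, **kin):
    kinetics = {
        var: (np.array(v[0]), np.array(v[1])) for var, v in kin.items()
    }
    return ae.TrialAgreement(
        trial_id=trial_id,
        velocity=velocity,
        stance_rmse_bw=stance,
        waveform_rmse_bw=wave,
        ic_diff_s=ic,
        to_diff_s=to,
        kinetics=kinetics,
    )


class TestPerVelocitySummary:
    def test_single_trial_bin_sd_zero(self):
        df = ae.per_velocity_summary([_ta("t1", 2.24, stance=0.23)])
        row = df[df["velocity"] == 2.24].iloc[0]
        assert row["stance_rmse_bw_mean"] == pytest.approx(0.23)
        assert row["stance_rmse_bw_sd"] == 0.0

    def test_two_identical_trials_sd_zero(self):
        df = ae.per_velocity_summary(
            [_ta("a", 3.0, stance=0.2), _ta("b", 3.0, stance=0.2)]
        )
        assert df.iloc[0]["stance_rmse_bw_sd"] == 0.0

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(6)
        tas = [
            _ta(f"t{i}", v, stance=float(rng.uniform(0.1, 0.4)))
            for i, v in enumerate([3.0, 3.0, 3.0, 3.5, 3.5])
        ]
        df = ae.per_velocity_summary(tas)
        vals = [t.stance_rmse_bw for t in tas if t.velocity == 3.0]
        row = df[df["velocity"] == 3.0].iloc[0]
        assert row["stance_rmse_bw_mean"] == pytest.approx(np.mean(vals))
        assert row["stance_rmse_bw_sd"] == pytest.approx(np.std(vals, ddof=1))

    def test_reordering_invariance(self):
        tas = [
            _ta("a", 3.0, stance=0.1),
            _ta("b", 3.5, stance=0.2),
            _ta("c", 3.0, stance=0.3),
        ]
        d1 = ae.per_velocity_summary(tas)
        d2 = ae.per_velocity_summary(list(reversed(tas)))
        import pandas.testing as pdt

        pdt.assert_frame_equal(d1, d2)  # float-sum order tolerance only

    def test_empty_input(self):
        assert ae.per_velocity_summary([]).empty

    def test_kinetic_variable_rmse_column(self):
        ta = _ta(
            "t1",
            3.0,
            contact_time_s=([0.28, 0.30], [0.26, 0.29]),
        )
        df = ae.per_velocity_summary([ta])
        expected = np.sqrt(np.mean([(0.28 - 0.26) ** 2, (0.30 - 0.29) ** 2]))
        assert df.iloc[0]["contact_time_s_rmse_mean"] == pytest.approx(expected)
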