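"""Baseline normalization, redox ratio, phase labels, group statistics
and 10-90% transition times."""

import numpy as np
import pytest

from myofluor import (
    NoTransitionError,
    ProtocolTimecourse,
    group_summary,
    normalize_to_baseline,
    redox_ratio,
    segment_phases,
    transition_time_10_90,
)
from myofluor.timeseries import PROTOCOL_DURATION, SAMPLE_INTERVAL

TIMES = np.arange(0.0, PROTOCOL_DURATION, SAMPLE_INTERVAL)  # 306 samples


def make_tc(heart_id, values, group="control"):
    return ProtocolTimecourse(
        heart_id=heart_id,
        group=group,
        times=TIMES,
        intensities={"CH2": np.asarray(values, dtype=float)},
    )


class TestBaselineNormalization:
    def test_constant_series_becomes_unity(self):
        out = normalize_to_baseline(np.full(TIMES.size, 4.2), TIMES)
        np.testing.assert_allclose(out, 1.0)

    def test_step_series(self):
        series = np.where(TIMES < 60.0, 2.0, 3.0)
        out = normalize_to_baseline(series, TIMES)
        assert np.all(out[TIMES < 60.0] == 1.0)
        assert np.all(out[TIMES >= 60.0] == 1.5)

    def test_baseline_window_mean_is_exactly_one(self):
        rng = np.random.default_rng(0)
        series = 100.0 + rng.normal(0, 5, TIMES.size)
        out = normalize_to_baseline(series, TIMES)
        assert out[TIMES < 60.0].mean() == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        series = 10.0 + rng.random(TIMES.size)
        np.testing.assert_allclose(
            normalize_to_baseline(series, TIMES),
            normalize_to_baseline(7.0 * series, TIMES),
        )

    def test_zero_baseline_rejected(self):
        series = np.where(TIMES < 60.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="baseline mean"):
            normalize_to_baseline(series, TIMES)


class TestRedoxRatio:
    def test_equal_channels(self):
        assert redox_ratio(3.0, 3.0) == 0.5

    def test_single_channel_limit(self):
        assert redox_ratio(2.0, 0.0) == 1.0

    def test_common_rescaling_invariance(self):
        i2, i3 = np.array([1.0, 2.0, 3.0]), np.array([0.5, 2.0, 1.0])
        np.testing.assert_allclose(redox_ratio(i2, i3), redox_ratio(9.0 * i2, 9.0 * i3))

    def test_both_zero_rejected(self):
        with pytest.raises(ZeroDivisionError):
            redox_ratio(0.0, 0.0)


class TestPhaseSegmentation:
    def test_boundary_conventions(self):
        labels = segment_phases(np.array([0.0, 179.9, 180.0, 629.9, 630.0, 1525.0]))
        assert list(labels) == [
            "baseline", "baseline", "insult", "insult", "reperfusion", "reperfusion",
        ]

    def test_full_protocol_phase_counts(self):
        labels = segment_phases(TIMES)
        counts = {ph: int(np.sum(labels == ph)) for ph in np.unique(labels)}
        assert counts == {"baseline": 36, "insult": 90, "reperfusion": 180}

    def test_nonincreasing_boundaries_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            segment_phases(TIMES, (630.0, 180.0))


class TestGroupSummary:
    def test_identical_hearts_have_zero_sd(self):
        tcs = [make_tc(f"h{i}", np.full(TIMES.size, 5.0)) for i in range(3)]
        gs = group_summary(tcs, "raw_intensity/CH2")
        np.testing.assert_allclose(gs.sd, 0.0)
        np.testing.assert_allclose(gs.mean, 5.0)
        assert np.all(gs.n == 3)

    def test_two_constant_hearts(self):
        tcs = [make_tc("a", np.ones(TIMES.size)), make_tc("b", 3.0 * np.ones(TIMES.size))]
        gs = group_summary(tcs, "raw_intensity/CH2")
        np.testing.assert_allclose(gs.mean, 2.0)
        np.testing.assert_allclose(gs.sd, np.sqrt(2.0))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        tcs = [make_tc(f"h{i}", 1.0 + rng.random(TIMES.size)) for i in range(4)]
        gs1 = group_summary(tcs, "raw_intensity/CH2")
        gs2 = group_summary(tcs[::-1], "raw_intensity/CH2")
        np.testing.assert_allclose(gs1.mean, gs2.mean)
        np.testing.assert_allclose(gs1.sd, gs2.sd)

    def test_single_heart_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            group_summary([make_tc("solo", np.ones(TIMES.size))], "raw_intensity/CH2")


class TestTransitionTime:
    def test_saturating_exponential_gives_tau_ln9(self):
        tau = 40.0
        t = np.arange(0.0, 600.0, SAMPLE_INTERVAL)
        series = 1.0 - np.exp(-t / tau)
        tt = transition_time_10_90(series, t)
        assert tt == pytest.approx(tau * np.log(9.0), abs=SAMPLE_INTERVAL)

    def test_linear_ramp_with_hold(self):
        t = np.arange(0.0, 150.0 + 1e-9, 1.0)
        series = np.clip(t / 100.0, None, 1.0)  # ramps over [0, 100] s then holds
        assert transition_time_10_90(series, t) == pytest.approx(80.0, abs=1.0)

    def test_falling_transition_is_positive(self):
        tau = 30.0
        t = np.arange(0.0, 400.0, SAMPLE_INTERVAL)
        series = np.exp(-t / tau)
        tt = transition_time_10_90(series, t)
        assert tt == pytest.approx(tau * np.log(9.0), abs=SAMPLE_INTERVAL)

    def test_window_restriction(self):
        tau = 45.0
        onset = 300.0
        t = np.arange(0.0, 630.0, SAMPLE_INTERVAL)
        series = np.where(t < onset, 0.0, 1.0 - np.exp(-(t - onset) / tau))
        tt = transition_time_10_90(series, t, window=(onset, 630.0))
        assert tt == pytest.approx(tau * np.log(9.0), abs=SAMPLE_INTERVAL)

    def test_flat_series_has_no_transition(self):
        t = np.arange(0.0, 100.0, 5.0)
        with pytest.raises(NoTransitionError, match="flat"):
            transition_time_10_90(np.ones(t.size), t)


class TestTimecourseValidation:
    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ProtocolTimecourse("h", "control", np.array([0.0, 5.0, 5.0]))

    def test_mismatched_series_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            ProtocolTimecourse(
                "h", "control", TIMES, intensities={"CH2": np.ones(10)}
            )

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            ProtocolTimecourse("h", "ischemia", TIMES)
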