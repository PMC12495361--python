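"""DIBH/4DCT metrics: plateaus, drift, baseline shift, cycles, cohorts."""

import math

import numpy as np
import pytest
from scipy import stats

import couchcorr as cc
from couchcorr import (
    BreathingTrace,
    DegenerateFitError,
    DegenerateTestError,
    UndefinedMetricError,
    baseline_shift,
    cohort_summary,
    compare_scenarios,
    detect_plateaus,
    dibh_report,
    fourd_report,
    plateau_drift,
    segment_cycles,
)
from couchcorr.datasets import volunteer_4dct, volunteer_dibh
from couchcorr.metrics import round1

RATE = 50.0


def trapezoid_trace(levels, hold=6.5, ramp=1.0, base=5.0, slope=0.0, rate=RATE):
    """Piecewise trace: baseline 0 with ramped holds at the given levels."""
    segs = [(0.0, base)]
    for lv in levels:
        segs += [("up", ramp, lv), ("hold", hold, lv), ("down", ramp, lv), (0.0, base)]
    t_parts, a_parts, t0 = [], [], 0.0
    for seg in segs:
        if seg[0] == "up" or seg[0] == "down":
            _, dur, lv = seg
            tt = np.arange(0.0, dur, 1.0 / rate)
            frac = tt / dur
            aa = lv * (frac if seg[0] == "up" else 1 - frac)
        elif seg[0] == "hold":
            _, dur, lv = seg
            tt = np.arange(0.0, dur + 0.5 / rate, 1.0 / rate)
            aa = lv + slope * tt
        else:
            lv, dur = seg
            tt = np.arange(0.0, dur, 1.0 / rate)
            aa = np.full_like(tt, lv)
        t_parts.append(t0 + tt)
        a_parts.append(aa)
        t0 += tt[-1] + 1.0 / rate if len(tt) else dur
    return BreathingTrace(np.concatenate(t_parts), np.concatenate(a_parts))


def sinusoid_trace(
    f=0.2, a_pp=20.0, duration=60.0, rate=RATE, ramp=0.0, offset=0.0
):
    t = np.arange(0.0, duration + 0.5 / rate, 1.0 / rate)
    amp = (a_pp / 2) * (1 - np.cos(2 * np.pi * f * t)) + ramp * t + offset
    return BreathingTrace(t, amp)


class TestDetectPlateaus:
    def test_three_flat_tops(self):
        trace = trapezoid_trace([20.0, 20.0, 20.0])
        plateaus = detect_plateaus(trace)
        assert len(plateaus) == 3
        for p in plateaus:
            assert p.mean_amplitude == pytest.approx(20.0, abs=1e-9)
            assert p.drift == pytest.approx(0.0, abs=1e-9)

    def test_tilted_tops_recover_drift(self):
        trace = trapezoid_trace([20.0, 20.0, 20.0], slope=-0.4)
        plateaus = detect_plateaus(trace)
        assert len(plateaus) == 3
        for p in plateaus:
            assert p.drift == pytest.approx(-0.4, abs=1e-6)

    def test_simulated_hold_duration_recovered(self, dibh_corrected):
        """Noise-free DIBH simulation: durations match the 6.5 s protocol."""
        plateaus = detect_plateaus(dibh_corrected.corrected)
        assert len(plateaus) == 3
        for p in plateaus:
            assert p.duration == pytest.approx(6.5, abs=1.0 / RATE)

    def test_no_qualifying_segment_gives_empty_list(self):
        trace = sinusoid_trace(duration=30.0)
        assert detect_plateaus(trace) == []


class TestPlateauDrift:
    def test_constant_segment(self):
        t = np.arange(100) * 0.02
        assert plateau_drift(t, np.full(100, 5.0)) == pytest.approx(0.0, abs=1e-12)

    def test_exact_line(self):
        t = np.arange(200) * 0.02
        assert plateau_drift(t, 3.0 - 0.7 * t) == pytest.approx(-0.7, abs=1e-9)

    def test_noisy_line_within_confidence_interval(self):
        rng = np.random.default_rng(11)
        t = np.arange(300) * 0.02
        b = -0.4
        y = 10.0 + b * t + rng.normal(0, 0.3, t.size)
        slope = plateau_drift(t, y)
        # 99% CI from the reference OLS implementation
        ref = stats.linregress(t, y)
        assert slope == pytest.approx(ref.slope, abs=1e-12)
        assert abs(slope - b) <= 2.576 * ref.stderr

    def test_degenerate_timestamps(self):
        with pytest.raises(DegenerateFitError):
            plateau_drift([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestBaselineShift:
    def test_stationary_sinusoid_is_zero(self):
        assert baseline_shift(sinusoid_trace()) == pytest.approx(0.0, abs=1e-9)

    def test_ramp_matches_dense_grid_oracle(self):
        r = -0.05
        trace = sinusoid_trace(ramp=r)
        # brute-force oracle: end-expiration minima of the continuous signal
        # on a 1 kHz grid, i.e. points minimal within a full +/- half-period
        # neighbourhood (boundary-truncated neighbourhoods excluded, matching
        # the prominence rule's rejection of edge artifacts)
        tg = np.arange(0.0, 60.0, 1e-3)
        y = 10 * (1 - np.cos(2 * np.pi * 0.2 * tg)) + r * tg
        half = 2500  # samples in half a breathing period
        t_min, y_min = [], []
        for i in range(half, y.size - half):
            if y[i] == y[i - half : i + half + 1].min():
                t_min.append(tg[i])
                y_min.append(y[i])
        t_min = np.asarray(t_min)
        expected = y_min[-1] - y_min[0]
        assert baseline_shift(trace) == pytest.approx(expected, abs=0.02)
        assert baseline_shift(trace) == pytest.approx(
            r * (t_min[-1] - t_min[0]), abs=0.02
        )

    def test_translation_equivariance(self):
        base = sinusoid_trace(ramp=-0.03)
        shifted = sinusoid_trace(ramp=-0.03, offset=7.5)
        assert baseline_shift(shifted) == pytest.approx(
            baseline_shift(base), abs=1e-9
        )

    def test_monotone_trace_undefined(self):
        t = np.arange(0, 30, 0.02)
        with pytest.raises(UndefinedMetricError):
            baseline_shift(BreathingTrace(t, 0.5 * t))


class TestSegmentCycles:
    def test_sinusoid_durations(self):
        cycles = segment_cycles(sinusoid_trace(duration=30.0))
        assert len(cycles) >= 4
        for c in cycles:
            assert c.duration == pytest.approx(5.0, abs=1.0 / RATE)

    def test_sinusoid_amplitudes(self):
        for c in segment_cycles(sinusoid_trace(duration=30.0)):
            assert c.amplitude == pytest.approx(20.0, abs=1e-6)

    def test_guidance_waveform_periods(self):
        params = cc.GuidanceParams(A=30.0, T=10.0)
        t = np.arange(0.0, 30.0 + 0.01, 0.02)
        trace = BreathingTrace(t, cc.guidance_waveform(t, params))
        for c in segment_cycles(trace):
            assert c.duration == pytest.approx(10.0, abs=0.02)

    def test_too_few_maxima_gives_empty(self):
        t = np.arange(0, 4, 0.02)
        assert segment_cycles(BreathingTrace(t, np.cos(t))) == []


class TestReports:
    def test_dibh_report_direct_arithmetic(self):
        trace = trapezoid_trace([10.9, 10.7, 11.1])
        report = dibh_report(trace)
        assert report.amplitude_mean == pytest.approx(10.9, abs=1e-6)
        assert report.amplitude_sd == pytest.approx(0.2, abs=1e-6)

    def test_identical_plateaus_zero_sd(self, dibh_corrected):
        report = dibh_report(dibh_corrected.corrected)
        assert report.amplitude_mean == pytest.approx(20.0, abs=1e-9)
        assert report.amplitude_sd == pytest.approx(0.0, abs=1e-9)

    def test_single_plateau_sd_flagged_undefined(self):
        trace = trapezoid_trace([20.0])
        report = dibh_report(trace)
        assert report.n_plateaus == 1
        assert math.isnan(report.amplitude_sd)
        assert math.isnan(report.drift_sd)

    def test_fourd_report_stationary_sinusoid(self):
        report = fourd_report(sinusoid_trace())
        assert report.amplitude_mean == pytest.approx(20.0, abs=1e-6)
        assert report.duration_mean == pytest.approx(5.0, abs=1.0 / RATE)
        assert report.baseline_shift == pytest.approx(0.0, abs=1e-9)

    def test_fourd_report_ramp_shows_in_baseline(self):
        report = fourd_report(sinusoid_trace(ramp=-2.0 / 60.0))
        assert report.baseline_shift == pytest.approx(-2.0 * 50 / 60, rel=0.1)

    def test_amplitude_modulation_raises_sd(self):
        t = np.arange(0.0, 60.0, 1.0 / RATE)
        amp = (10 + 3 * np.sin(2 * np.pi * t / 60)) * (
            1 - np.cos(2 * np.pi * 0.2 * t)
        )
        report = fourd_report(BreathingTrace(t, amp))
        assert report.amplitude_sd > 0.5


class TestCohortSummary:
    def test_sample_sd_matches_brute_force(self):
        rng = np.random.default_rng(5)
        means = rng.normal(10, 3, 8)
        sds = rng.uniform(0.1, 2, 8)
        s = cohort_summary(zip(means, sds))
        mu = sum(means) / len(means)
        brute = math.sqrt(sum((x - mu) ** 2 for x in means) / (len(means) - 1))
        assert s.sd_total == pytest.approx(brute, abs=1e-12)

    def test_identical_subjects_zero_sd(self):
        s = cohort_summary([(5.0, 1.0), (5.0, 1.0)])
        assert s.sd_total == 0.0
        assert s.sd_of_sds == 0.0

    def test_too_few_subjects(self):
        with pytest.raises(UndefinedMetricError):
            cohort_summary([(1.0, 0.5)])

    def test_4dct_amplitude_column_is_internally_consistent(self):
        """The audio-scenario 4DCT amplitude column aggregates to 16.2 ± 9.5."""
        df = volunteer_4dct()
        g = df[df.scenario == "audio"]
        s = cohort_summary(zip(g.amplitude_mean, g.amplitude_sd))
        assert round1(s.mean_total) == 16.2
        assert round1(s.sd_total) == 9.5

    def test_presentation_rounding_half_up(self):
        assert round1(10.95) == 11.0
        assert round1(-0.36) == -0.4
        assert round1(0.449) == 0.4
        assert round1(-0.25) == -0.3


class TestCompareScenarios:
    def test_normal_groups_choose_paired_t(self):
        rng = np.random.default_rng(2)
        a = rng.normal(10, 1, 10)
        b = a + rng.normal(0, 0.5, 10)
        result = compare_scenarios(a, b)
        assert result.test_name == "paired t-test"
        # cross-check against the reference implementation
        assert result.p_value == pytest.approx(stats.ttest_rel(a, b).pvalue)

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(4)
        a = rng.normal(10, 1, 10)
        b = a + 50.0 + rng.normal(0, 0.5, 10)
        result = compare_scenarios(a, b)
        assert result.p_value < 0.05

    def test_non_normal_group_switches_to_mannwhitney(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 20)
        b = np.concatenate([rng.normal(0, 0.01, 19), [40.0]])  # gross outlier
        result = compare_scenarios(a, b)
        assert result.test_name == "Mann-Whitney U"
        assert result.p_value == pytest.approx(stats.mannwhitneyu(a, b).pvalue)

    def test_identical_groups_degenerate(self):
        a = np.arange(10.0)
        with pytest.raises(DegenerateTestError):
            compare_scenarios(a, a)

    def test_unpaired_mode(self):
        rng = np.random.default_rng(8)
        a = rng.normal(10, 1, 10)
        b = rng.normal(10, 1, 12)
        result = compare_scenarios(a, b, paired=False)
        assert result.test_name in ("independent t-test", "Mann-Whitney U")

    def test_volunteer_dibh_amplitudes_differ_with_table_motion(self):
        """Visual-feedback amplitude rises when the table moves."""
        df = volunteer_dibh()
        vis = df[df.scenario == "visual"].amplitude_mean.to_numpy()
        vt = df[df.scenario == "visual_table"].amplitude_mean.to_numpy()
        result = compare_scenarios(vis, vt)
        assert result.p_value < 0.05
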