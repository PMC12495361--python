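"""DIBH and 4DCT signal-quality metrics and cohort summaries.

Deep-inspiration breath-hold (DIBH) quality is described by the
reproducibility of successive breath-hold plateau amplitudes and by the
intra-breath-hold drift (mm/s, ordinary-least-squares slope).  4DCT
breathing quality is described by per-cycle peak-to-trough amplitude and
max-to-max cycle duration, and by the baseline shift: the amplitude of
the last end-expiration minimum minus that of the first (negative =
sagging baseline).

All standard deviations use the sample (n-1) convention.  Values are
carried at full precision; rounding to one decimal happens only in the
presentation helpers (round-half-up, so e.g. 10.95 prints as 11.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .errors import (
    DegenerateFitError,
    DegenerateTestError,
    UndefinedMetricError,
    ValidationError,
)
from .streams import BreathingTrace

__all__ = [
    "Plateau",
    "Cycle",
    "DibhReport",
    "FourDReport",
    "CohortSummary",
    "ComparisonResult",
    "detect_plateaus",
    "plateau_drift",
    "baseline_shift",
    "segment_cycles",
    "dibh_report",
    "fourd_report",
    "cohort_summary",
    "compare_scenarios",
    "round1",
    "format_pm",
]


@dataclass(frozen=True)
class Plateau:
    """One detected breath-hold plateau."""

    t_start: float
    t_end: float
    mean_amplitude: float  # mm, over the trimmed interior
    drift: float  # mm/s, OLS slope over the trimmed interior
    n_samples: int

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class Cycle:
    """One breathing cycle between consecutive maxima."""

    t_peak_start: float
    t_peak_end: float
    duration: float  # s, inter-peak interval
    amplitude: float  # mm, peak-to-trough within the cycle

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValidationError("cycle duration must be > 0")
        if self.amplitude < 0:
            raise ValidationError("cycle amplitude must be >= 0")


@dataclass(frozen=True)
class DibhReport:
    """Plateau reproducibility (amplitude) and stability (drift) summary.

    SD fields are NaN when fewer than two plateaus were found.
    """

    plateaus: tuple
    amplitude_mean: float
    amplitude_sd: float
    drift_mean: float
    drift_sd: float

    @property
    def n_plateaus(self) -> int:
        return len(self.plateaus)

    def to_dict(self) -> dict:
        return {
            "n_plateaus": self.n_plateaus,
            "amplitude_mean_mm": self.amplitude_mean,
            "amplitude_sd_mm": self.amplitude_sd,
            "drift_mean_mm_per_s": self.drift_mean,
            "drift_sd_mm_per_s": self.drift_sd,
            "plateaus": [
                {
                    "t_start_s": p.t_start,
                    "t_end_s": p.t_end,
                    "duration_s": p.duration,
                    "mean_amplitude_mm": p.mean_amplitude,
                    "drift_mm_per_s": p.drift,
                }
                for p in self.plateaus
            ],
        }


@dataclass(frozen=True)
class FourDReport:
    """Cycle amplitude/duration statistics plus baseline shift."""

    cycles: tuple
    amplitude_mean: float
    amplitude_sd: float
    duration_mean: float
    duration_sd: float
    baseline_shift: float

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def to_dict(self) -> dict:
        return {
            "n_cycles": self.n_cycles,
            "amplitude_mean_mm": self.amplitude_mean,
            "amplitude_sd_mm": self.amplitude_sd,
            "duration_mean_s": self.duration_mean,
            "duration_sd_s": self.duration_sd,
            "baseline_shift_mm": self.baseline_shift,
        }


@dataclass(frozen=True)
class CohortSummary:
    """Aggregation of per-subject (mean, sd) pairs.

    ``mean_total``/``sd_total`` summarise the subject means;
    ``mean_of_sds``/``sd_of_sds`` summarise the subject SDs.
    """

    mean_total: float
    sd_total: float
    mean_of_sds: float
    sd_of_sds: float
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_total": self.mean_total,
            "sd_total": self.sd_total,
            "mean_of_sds": self.mean_of_sds,
            "sd_of_sds": self.sd_of_sds,
        }


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of the scenario-comparison decision rule."""

    test_name: str  # "paired t-test" | "independent t-test" | "Mann-Whitney U"
    statistic: float
    p_value: float
    shapiro_p_a: float
    shapiro_p_b: float


def round1(x: float) -> float:
    """Presentation rounding to one decimal, half away from zero."""
    if not math.isfinite(x):
        return x
    d = Decimal(repr(round(float(x), 9)))
    sign = -1 if d < 0 else 1
    return sign * float(abs(d).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def format_pm(mean: float, sd: float) -> str:
    """Render ``mean ± sd`` at one-decimal presentation precision."""
    return f"{round1(mean):.1f} ± {round1(sd):.1f}"


def _smooth(amplitude: np.ndarray, dt: float, window_s: float) -> np.ndarray:
    """Centered moving average with an odd window of about ``window_s``."""
    if window_s <= 0:
        return amplitude
    half = int(round(window_s / (2 * dt)))
    size = 2 * half + 1
    if size < 3:
        return amplitude
    return uniform_filter1d(amplitude, size=size, mode="nearest")


def _sample_sd(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    return float(np.std(values, ddof=1)) if values.size >= 2 else math.nan


def plateau_drift(t, amplitude) -> float:
    """OLS slope (mm/s) of amplitude vs time over a plateau segment."""
    t = np.asarray(t, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if t.size < 2:
        raise DegenerateFitError("plateau drift needs >= 2 samples")
    if np.ptp(t) == 0:
        raise DegenerateFitError("all timestamps equal; slope undefined")
    # center time for numerical conditioning; slope is unaffected
    slope, _ = np.polyfit(t - t.mean(), amplitude, 1)
    return float(slope)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean mask as (start, stop) index pairs."""
    d = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1) - 1))


def _refine_run(amp: np.ndarray, start: int, stop: int) -> tuple[int, int]:
    """Expand a candidate plateau run over raw samples near the run mean.

    The centered smoothing used for slope detection blurs plateau edges
    by about half a window; this walks the raw signal outward from the
    detected core while samples stay within a noise-scaled tolerance of
    the core mean, recovering the true hold boundaries.
    """
    core = amp[start : stop + 1]
    m = float(core.mean())
    diffs = np.abs(np.diff(core))
    sigma = float(np.median(diffs)) / (0.6745 * math.sqrt(2)) if diffs.size else 0.0
    tol = max(4.0 * sigma, 1e-6)
    while start > 0 and abs(amp[start - 1] - m) <= tol:
        start -= 1
    while stop < len(amp) - 1 and abs(amp[stop + 1] - m) <= tol:
        stop += 1
    return start, stop


def detect_plateaus(
    trace: BreathingTrace,
    min_duration: float = 5.0,
    slope_tol: float = 1.0,
    trim_frac: float = 0.1,
    smooth_window: float = 0.25,
    height_frac: float = 0.5,
) -> list[Plateau]:
    """Detect breath-hold plateaus.

    A plateau is a maximal run of samples whose smoothed derivative
    magnitude is at most ``slope_tol`` (mm/s) and whose smoothed
    amplitude reaches ``height_frac`` of the trace's 95th-percentile
    amplitude, refined at the edges against the raw signal and kept if
    it lasts at least ``min_duration`` seconds.  Per-plateau mean and
    drift are computed over the interior after trimming ``trim_frac`` of
    the samples at each end, which excludes inhale/exhale ramps.

    Returns an empty list when nothing qualifies.
    """
    t, amp = trace.t, trace.amplitude
    if len(t) < 2 or t[-1] - t[0] < min_duration:
        raise ValidationError("trace shorter than min_duration")
    dt = trace.median_dt
    smoothed = _smooth(amp, dt, smooth_window)
    deriv = np.gradient(smoothed, t)
    height = height_frac * np.percentile(amp, 95)
    mask = (np.abs(deriv) <= slope_tol) & (smoothed >= height)

    refined = [_refine_run(amp, s, e) for s, e in _runs(mask)]
    # merge overlapping/adjacent refined runs
    merged: list[list[int]] = []
    for s, e in sorted(refined):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    plateaus = []
    for s, e in merged:
        if t[e] - t[s] < min_duration:
            continue
        n = e - s + 1
        k = int(trim_frac * n)
        lo, hi = s + k, e - k
        seg_t, seg_a = t[lo : hi + 1], amp[lo : hi + 1]
        plateaus.append(
            Plateau(
                t_start=float(t[s]),
                t_end=float(t[e]),
                mean_amplitude=float(seg_a.mean()),
                drift=plateau_drift(seg_t, seg_a),
                n_samples=n,
            )
        )
    return plateaus


def _extrema_indices(
    trace: BreathingTrace,
    prominence_frac: float,
    min_separation: float,
    smooth_window: float,
    minima: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Prominence-filtered extrema on the smoothed signal.

    Returns (indices, smoothed signal).
    """
    dt = trace.median_dt
    smoothed = _smooth(trace.amplitude, dt, smooth_window)
    signal = -smoothed if minima else smoothed
    rng = float(np.ptp(smoothed))
    if rng == 0:
        return np.array([], dtype=int), smoothed
    idx, _ = find_peaks(
        signal,
        prominence=prominence_frac * rng,
        distance=max(1, int(round(min_separation / dt))),
    )
    return idx, smoothed


def baseline_shift(
    trace: BreathingTrace,
    prominence_frac: float = 0.2,
    min_separation: float = 0.5,
    smooth_window: float = 0.25,
) -> float:
    """Baseline shift: last minus first end-expiration minimum (mm).

    End-expiration minima are prominence-filtered local minima of the
    lightly smoothed signal; their smoothed values are differenced so
    that tracking noise does not dominate the metric.  Negative values
    indicate a sagging baseline.

    Raises
    ------
    UndefinedMetricError
        If fewer than two end-expiration minima are found.
    """
    idx, smoothed = _extrema_indices(
        trace, prominence_frac, min_separation, smooth_window, minima=True
    )
    if idx.size < 2:
        raise UndefinedMetricError(
            f"baseline shift needs >= 2 end-expiration minima, found {idx.size}"
        )
    return float(smoothed[idx[-1]] - smoothed[idx[0]])


def segment_cycles(
    trace: BreathingTrace,
    prominence_frac: float = 0.2,
    min_separation: float = 0.5,
    smooth_window: float = 0.25,
) -> list[Cycle]:
    """Segment breathing cycles at max-to-max intervals.

    Cycle boundaries are prominence-filtered maxima of the smoothed
    signal; per-cycle amplitude is the raw max minus raw min within the
    interval, duration the inter-peak interval.  Returns an empty list
    with fewer than two qualifying maxima.
    """
    idx, _ = _extrema_indices(
        trace, prominence_frac, min_separation, smooth_window, minima=False
    )
    if idx.size < 2:
        return []
    cycles = []
    for a, b in zip(idx[:-1], idx[1:]):
        seg = trace.amplitude[a : b + 1]
        cycles.append(
            Cycle(
                t_peak_start=float(trace.t[a]),
                t_peak_end=float(trace.t[b]),
                duration=float(trace.t[b] - trace.t[a]),
                amplitude=float(seg.max() - seg.min()),
            )
        )
    return cycles


def dibh_report(trace: BreathingTrace, **plateau_params) -> DibhReport:
    """DIBH reproducibility/stability report over all detected plateaus."""
    plateaus = detect_plateaus(trace, **plateau_params)
    if not plateaus:
        raise UndefinedMetricError("no breath-hold plateau detected")
    amps = np.array([p.mean_amplitude for p in plateaus])
    drifts = np.array([p.drift for p in plateaus])
    return DibhReport(
        plateaus=tuple(plateaus),
        amplitude_mean=float(amps.mean()),
        amplitude_sd=_sample_sd(amps),
        drift_mean=float(drifts.mean()),
        drift_sd=_sample_sd(drifts),
    )


def fourd_report(trace: BreathingTrace, **cycle_params) -> FourDReport:
    """4DCT regularity report: cycle statistics plus baseline shift."""
    cycles = segment_cycles(trace, **cycle_params)
    if len(cycles) < 2:
        raise UndefinedMetricError(
            f"4DCT report needs >= 2 cycles, found {len(cycles)}"
        )
    shift = baseline_shift(trace, **cycle_params)
    amps = np.array([c.amplitude for c in cycles])
    durs = np.array([c.duration for c in cycles])
    return FourDReport(
        cycles=tuple(cycles),
        amplitude_mean=float(amps.mean()),
        amplitude_sd=_sample_sd(amps),
        duration_mean=float(durs.mean()),
        duration_sd=_sample_sd(durs),
        baseline_shift=shift,
    )


def cohort_summary(per_subject) -> CohortSummary:
    """Aggregate per-subject (mean, sd) pairs across a cohort.

    ``mean_total ± sd_total`` is the mean and sample SD of the subject
    means; ``mean_of_sds ± sd_of_sds`` the mean and sample SD of the
    subject SDs.  Full precision is kept; round at presentation time.
    """
    pairs = [(float(m), float(s)) for m, s in per_subject]
    if len(pairs) < 2:
        raise UndefinedMetricError("cohort summary needs >= 2 subjects")
    means = np.array([m for m, _ in pairs])
    sds = np.array([s for _, s in pairs])
    return CohortSummary(
        mean_total=float(means.mean()),
        sd_total=_sample_sd(means),
        mean_of_sds=float(sds.mean()),
        sd_of_sds=_sample_sd(sds),
        n=len(pairs),
    )


def compare_scenarios(
    group_a,
    group_b,
    alpha: float = 0.05,
    paired: bool = True,
) -> ComparisonResult:
    """Compare two scenarios with a normality-gated test choice.

    Shapiro-Wilk is run on both groups; if both p-values exceed
    ``alpha`` a t-test is applied (paired by default, independent with
    ``paired=False``), otherwise a Mann-Whitney U test.

    Raises
    ------
    DegenerateTestError
        If the paired differences have zero variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValidationError("compare_scenarios needs n >= 3 per group")
    if paired and a.size != b.size:
        raise ValidationError("paired comparison needs equal group sizes")
    if paired and np.ptp(a - b) == 0:
        raise DegenerateTestError("paired differences have zero variance")
    pa = float(stats.shapiro(a).pvalue)
    pb = float(stats.shapiro(b).pvalue)
    if pa > alpha and pb > alpha:
        if paired:
            res = stats.ttest_rel(a, b)
            name = "paired t-test"
        else:
            res = stats.ttest_ind(a, b)
            name = "independent t-test"
    else:
        res = stats.mannwhitneyu(a, b)
        name = "Mann-Whitney U"
    return ComparisonResult(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        shapiro_p_a=pa,
        shapiro_p_b=pb,
    )
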