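"""Protocol time-course assembly and metabolic metrics.

The perfusion protocol has three phases — 3 min baseline with oxygenated
buffer, 7.5 min insult (deoxygenated or glucose-free buffer, or
oxygenated buffer for controls), 15 min reperfusion — sampled every 5 s.
Per-channel intensities are normalized to the first minute of baseline,
the optical redox ratio RR = I_CH2 / (I_CH2 + I_CH3) summarises the
NAD(P)H/FAD balance, and group curves are means ± SD across hearts.
Transition kinetics are characterised by the 10-90% rise/fall time of a
metric within a protocol phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import CHANNEL_NAMES
from .decay import BiExpFit

__all__ = [
    "PROTOCOL_BOUNDARIES",
    "PROTOCOL_DURATION",
    "SAMPLE_INTERVAL",
    "BASELINE_WINDOW",
    "PHASES",
    "ProtocolTimecourse",
    "GroupSummary",
    "NoTransitionError",
    "normalize_to_baseline",
    "redox_ratio",
    "segment_phases",
    "metric_series",
    "group_summary",
    "transition_time_10_90",
]

#: Solution-switch times in seconds: end of baseline, end of insult.
PROTOCOL_BOUNDARIES = (180.0, 630.0)
PROTOCOL_DURATION = 1530.0
SAMPLE_INTERVAL = 5.0
#: Intensities are normalized to the mean over the first minute.
BASELINE_WINDOW = 60.0
PHASES = ("baseline", "insult", "reperfusion")

GROUPS = ("control", "hypoxia", "glucose_depletion")


class NoTransitionError(ValueError):
    """The series has no 10-90% transition within the requested window."""


@dataclass
class ProtocolTimecourse:
    """Per-heart time series of intensities, decay fits and reflectance metrics."""

    heart_id: str
    group: str
    times: np.ndarray
    intensities: dict[str, np.ndarray] = field(default_factory=dict)
    fits: dict[str, list[BiExpFit | None]] = field(default_factory=dict)
    reflectance: dict[str, np.ndarray] = field(default_factory=dict)
    boundaries: tuple[float, float] = PROTOCOL_BOUNDARIES

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        b0, b1 = self.boundaries
        if not (0 <= b0 < b1 <= self.times[-1] + SAMPLE_INTERVAL):
            raise ValueError("phase boundaries must lie within the time range")
        n = self.times.size
        for name, series in list(self.intensities.items()) + list(self.reflectance.items()):
            if np.asarray(series).size != n:
                raise ValueError(f"series {name!r} length does not match times")

    @property
    def phases(self) -> np.ndarray:
        return segment_phases(self.times, self.boundaries)


@dataclass
class GroupSummary:
    """Across-heart mean and sample SD of one metric on a common time grid."""

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    group: str = ""
    metric: str = ""


def normalize_to_baseline(
    series: np.ndarray, times: np.ndarray, window: float = BASELINE_WINDOW
) -> np.ndarray:
    """Divide a metric series by its mean over the first ``window`` seconds."""
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    mask = times < window
    if not np.any(mask):
        raise ValueError(f"no samples within the first {window} s")
    baseline = float(np.nanmean(series[mask]))
    if baseline == 0 or not np.isfinite(baseline):
        raise ValueError("baseline mean is zero or undefined; cannot normalize")
    return series / baseline


def redox_ratio(i_ch2, i_ch3):
    """Optical redox ratio RR = I_CH2 / (I_CH2 + I_CH3).

    CH2 carries mostly NAD(P)H fluorescence and CH3 mostly FAD (with some
    NAD(P)H), so RR ~ NAD(P)H / (NAD(P)H + FAD) rises when glycolysis
    dominates over oxidative phosphorylation. Works elementwise on
    arrays. Typically applied to baseline-normalized intensities.
    """
    i2 = np.asarray(i_ch2, dtype=float)
    i3 = np.asarray(i_ch3, dtype=float)
    if np.any(i2 < 0) or np.any(i3 < 0):
        raise ValueError("intensities must be non-negative")
    total = i2 + i3
    if np.any(total == 0):
        raise ZeroDivisionError("redox ratio undefined where both channels are zero")
    out = i2 / total
    return float(out) if out.ndim == 0 else out


def nadh_fad_ratio(i_ch2, i_ch3):
    """Plain NAD(P)H / FAD intensity ratio I_CH2 / I_CH3 (alternative metric)."""
    i2 = np.asarray(i_ch2, dtype=float)
    i3 = np.asarray(i_ch3, dtype=float)
    if np.any(i3 == 0):
        raise ZeroDivisionError("ratio undefined where CH3 intensity is zero")
    out = i2 / i3
    return float(out) if out.ndim == 0 else out


def segment_phases(
    times: np.ndarray, boundaries: tuple[float, float] = PROTOCOL_BOUNDARIES
) -> np.ndarray:
    """Label each time point baseline / insult / reperfusion.

    Half-open convention: [0, b0) baseline, [b0, b1) insult,
    [b1, end] reperfusion.
    """
    times = np.asarray(times, dtype=float)
    b0, b1 = boundaries
    if not b0 < b1:
        raise ValueError("boundaries must be increasing")
    labels = np.where(times < b0, "baseline", np.where(times < b1, "insult", "reperfusion"))
    return labels.astype(object)


def metric_series(tc: ProtocolTimecourse, metric: str) -> np.ndarray:
    """Resolve a metric name on a time course.

    Names: ``intensity/CHn`` (baseline-normalized), ``raw_intensity/CHn``,
    ``tau_mean/CHn``, ``alpha1/CHn``, ``tau1/CHn``, ``tau2/CHn``,
    ``redox_ratio``, or any key of ``tc.reflectance`` (e.g.
    ``oxygenation``, ``cytochrome``).
    """
    if metric == "redox_ratio":
        i2 = normalize_to_baseline(tc.intensities["CH2"], tc.times)
        i3 = normalize_to_baseline(tc.intensities["CH3"], tc.times)
        return redox_ratio(i2, i3)
    if metric in tc.reflectance:
        return np.asarray(tc.reflectance[metric], dtype=float)
    if "/" in metric:
        kind, ch = metric.split("/", 1)
        if ch not in CHANNEL_NAMES:
            raise KeyError(f"unknown channel {ch!r}")
        if kind == "intensity":
            return normalize_to_baseline(tc.intensities[ch], tc.times)
        if kind == "raw_intensity":
            return np.asarray(tc.intensities[ch], dtype=float)
        if kind in ("tau_mean", "alpha1", "tau1", "tau2", "chi2"):
            fits = tc.fits.get(ch)
            if fits is None:
                raise KeyError(f"no decay fits stored for channel {ch}")
            out = np.full(len(fits), np.nan)
            for i, fit in enumerate(fits):
                if fit is None:
                    continue
                if kind == "tau_mean":
                    out[i] = fit.tau_mean
                elif kind == "alpha1":
                    out[i] = fit.alpha1
                elif kind == "chi2":
                    out[i] = fit.chi2
                else:
                    out[i] = getattr(fit.params, kind)
            return out
    raise KeyError(f"unknown metric {metric!r}")


def group_summary(
    timecourses: list[ProtocolTimecourse],
    metric: str,
    match_tolerance: float = SAMPLE_INTERVAL / 2,
) -> GroupSummary:
    """Across-heart mean and sample SD (n-1) of one metric per time point.

    Hearts are aligned to the first heart's time grid by nearest-time
    matching within ``match_tolerance`` seconds; unmatched or NaN samples
    simply reduce n at that time point.
    """
    if len(timecourses) < 2:
        raise ValueError("group summary requires at least 2 hearts")
    ref_times = timecourses[0].times
    stacked = np.full((len(timecourses), ref_times.size), np.nan)
    for i, tc in enumerate(timecourses):
        values = metric_series(tc, metric)
        idx = np.searchsorted(tc.times, ref_times)
        idx = np.clip(idx, 0, tc.times.size - 1)
        left = np.clip(idx - 1, 0, tc.times.size - 1)
        use_left = np.abs(tc.times[left] - ref_times) < np.abs(tc.times[idx] - ref_times)
        nearest = np.where(use_left, left, idx)
        matched = np.abs(tc.times[nearest] - ref_times) <= match_tolerance
        stacked[i, matched] = values[nearest[matched]]
    n = np.sum(~np.isnan(stacked), axis=0)
    mean = np.full(ref_times.size, np.nan)
    sd = np.full(ref_times.size, np.nan)
    with np.errstate(invalid="ignore"):
        mean[n >= 1] = np.nanmean(stacked[:, n >= 1], axis=0)
        sd[n >= 2] = np.nanstd(stacked[:, n >= 2], axis=0, ddof=1)
    return GroupSummary(
        times=ref_times,
        mean=mean,
        sd=sd,
        n=n,
        group=timecourses[0].group,
        metric=metric,
    )


def transition_time_10_90(
    series: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] | None = None,
    plateau_fraction: float = 0.2,
    min_change: float = 1e-12,
) -> float:
    """10-90% transition time of a monotone change within a time window.

    The initial level is the first sample in the window and the plateau
    level is the median of the final ``plateau_fraction`` of the window
    (robust to drift). The 10% and 90% crossings of the initial-to-plateau
    excursion are located by linear interpolation; the result is
    t(90%) - t(10%), positive for rises and falls alike.

    Raises
    ------
    NoTransitionError
        If the excursion is smaller than ``min_change`` or a crossing is
        never reached within the window.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if window is not None:
        mask = (times >= window[0]) & (times <= window[1])
        series, times = series[mask], times[mask]
    if series.size < 3:
        raise NoTransitionError("window contains too few samples")
    initial = series[0]
    n_tail = max(1, int(np.ceil(plateau_fraction * series.size)))
    plateau = float(np.median(series[-n_tail:]))
    span = plateau - initial
    if abs(span) <= min_change:
        raise NoTransitionError("no transition: series is flat within tolerance")
    # normalize so the transition runs 0 -> 1 regardless of direction
    s = (series - initial) / span

    def first_crossing(level: float) -> float:
        above = s >= level
        if not np.any(above):
            raise NoTransitionError(f"series never reaches the {level:.0%} level")
        k = int(np.argmax(above))
        if k == 0:
            return float(times[0])
        # linear interpolation between samples k-1 and k
        s0, s1 = s[k - 1], s[k]
        frac = (level - s0) / (s1 - s0)
        return float(times[k - 1] + frac * (times[k] - times[k - 1]))

    t10 = first_crossing(0.1)
    t90 = first_crossing(0.9)
    if t90 < t10:
        raise NoTransitionError("non-monotone transition: 90% level crossed before 10%")
    return t90 - t10
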