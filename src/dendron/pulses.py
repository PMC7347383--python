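"""LH pulse identification and surge classification.

A pulse is an increment in LH from nadir to peak of strictly more than 25%
(100 x (peak - nadir) / nadir).  The rule is made sequential by a
left-to-right sweep: the running nadir is the minimum sample since the last
confirmed peak (initialised at the first sample, which can only ever serve
as a nadir); each local maximum is tested against it, and a confirmed call
resets the nadir search to just after the peak.  Local maxima are runs of
equal values strictly greater than both adjacent values (the final sample
qualifies if at least its inner neighbour); the earliest sample of a run
represents it.

The surge classifier is a package convention, not a published criterion:
a surge is called when the largest post-baseline sample exceeds both a fold
threshold over the first (baseline) sample and an absolute floor, and the
raw fold rise is always reported so users can re-threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate_lh import LHSeries

__all__ = [
    "PulseCriteria",
    "PulseCall",
    "PulseSummary",
    "SurgeCall",
    "detect_pulses",
    "summarize_pulses",
    "classify_surge",
]


@dataclass(frozen=True)
class PulseCriteria:
    """Pulse-calling rule: minimum nadir-to-peak increment (percent,
    strict) and the assay detectability floor for a valid nadir (ng/ml)."""

    min_increment_pct: float = 25.0
    min_value: float = 0.02

    def __post_init__(self) -> None:
        if not self.min_increment_pct > 0:
            raise ValueError("min_increment_pct must be positive")
        if self.min_value < 0:
            raise ValueError("min_value must be non-negative")


@dataclass
class PulseCall:
    """One identified pulse."""

    nadir_time: float
    nadir_value: float
    peak_time: float
    peak_value: float

    @property
    def increment_pct(self) -> float:
        return 100.0 * (self.peak_value - self.nadir_value) / self.nadir_value

    @property
    def amplitude(self) -> float:
        """Peak minus nadir, ng/ml."""
        return self.peak_value - self.nadir_value


@dataclass
class PulseSummary:
    """Per-animal pulse statistics."""

    n_pulses: int
    frequency_per_hour: float
    mean_amplitude: float | None
    mean_lh: float
    interpulse_intervals: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n_pulses": self.n_pulses,
            "frequency_per_hour": self.frequency_per_hour,
            "mean_amplitude_ng_per_ml": self.mean_amplitude,
            "mean_lh_ng_per_ml": self.mean_lh,
            "interpulse_intervals_min":
                [float(v) for v in self.interpulse_intervals],
        }


@dataclass
class SurgeCall:
    """Outcome of the surge classifier for one animal."""

    baseline_value: float
    max_post_value: float
    fold_rise: float
    is_surge: bool
    fold_threshold: float
    absolute_floor: float

    def to_dict(self) -> dict:
        return {
            "baseline_value": self.baseline_value,
            "max_post_value": self.max_post_value,
            "fold_rise": self.fold_rise,
            "is_surge": self.is_surge,
            "fold_threshold": self.fold_threshold,
            "absolute_floor": self.absolute_floor,
        }


def _local_max_reps(y: np.ndarray) -> list[int]:
    """Earliest indices of local-maximum runs.

    A maximal run of equal values is a local maximum when the values on
    both sides are strictly smaller; at the right end only the inner side
    is required.  A run starting at index 0 is excluded: the first sample
    only ever serves as a nadir.
    """
    n = len(y)
    reps = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        left_ok = i > 0 and y[i - 1] < y[i]
        right_ok = j == n - 1 or y[j + 1] < y[i]
        if left_ok and right_ok:
            reps.append(i)
        i = j + 1
    return reps


def detect_pulses(series: LHSeries,
                  criteria: PulseCriteria | None = None) -> list[PulseCall]:
    """Identify LH pulses by the strict >25% nadir-to-peak rule.

    Requires at least 3 uniformly spaced samples.  Raises if a zero nadir
    could enter the relative increment with ``min_value`` at 0.
    """
    if criteria is None:
        criteria = PulseCriteria()
    y = np.asarray(series.lh, dtype=float)
    t = np.asarray(series.times, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 samples")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError("pulse detection requires uniform sampling")
    if criteria.min_value <= 0 and np.any(y == 0):
        raise ValueError("zero nadir with min_value=0 would divide by zero")

    peak_set = set(_local_max_reps(y))
    calls: list[PulseCall] = []
    nadir_idx, nadir_val = 0, y[0]
    have_nadir = True
    for i in range(1, len(y)):
        if i in peak_set and have_nadir:
            if (nadir_val >= criteria.min_value and nadir_val > 0
                    and 100.0 * (y[i] - nadir_val) / nadir_val
                    > criteria.min_increment_pct):
                calls.append(PulseCall(nadir_time=float(t[nadir_idx]),
                                       nadir_value=float(nadir_val),
                                       peak_time=float(t[i]),
                                       peak_value=float(y[i])))
                have_nadir = False  # search restarts after this peak
                continue
        if have_nadir:
            if y[i] < nadir_val:
                nadir_idx, nadir_val = i, y[i]
        else:
            nadir_idx, nadir_val = i, y[i]
            have_nadir = True
    return calls


def summarize_pulses(calls: list[PulseCall], series: LHSeries) -> PulseSummary:
    """Summarise pulse calls over the sampled duration.

    Frequency is pulses per hour over ``n_samples * interval``; mean
    amplitude is reported as missing (None) when there are no calls.
    """
    t = np.asarray(series.times, dtype=float)
    if len(t) > 1:
        duration_min = len(t) * float(np.median(np.diff(t)))
    else:
        duration_min = 0.0
    n = len(calls)
    freq = n / (duration_min / 60.0) if duration_min > 0 else 0.0
    mean_amp = float(np.mean([c.amplitude for c in calls])) if n else None
    ipis = np.diff([c.peak_time for c in calls]) if n >= 2 else np.empty(0)
    return PulseSummary(n_pulses=n, frequency_per_hour=freq,
                        mean_amplitude=mean_amp,
                        mean_lh=float(np.mean(series.lh)),
                        interpulse_intervals=ipis)


def classify_surge(series: LHSeries, fold_threshold: float = 2.0,
                   absolute_floor: float = 1.0) -> SurgeCall:
    """Classify a surge-mode series.

    The first sample is the baseline; a surge is called when the maximum
    later sample strictly exceeds both ``fold_threshold`` times the
    baseline and ``absolute_floor`` ng/ml.  The fold rise is reported even
    when no surge is called.
    """
    y = np.asarray(series.lh, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 samples (baseline + one later)")
    baseline = float(y[0])
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    max_post = float(y[1:].max())
    fold = max_post / baseline
    return SurgeCall(baseline_value=baseline, max_post_value=max_post,
                     fold_rise=fold,
                     is_surge=(fold > fold_threshold
                               and max_post > absolute_floor),
                     fold_threshold=fold_threshold,
                     absolute_floor=absolute_floor)
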