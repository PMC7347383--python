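"""Synthetic tail-tip LH time series with known secretion events.

Two modes emulate the standard mouse serial-bleeding designs:

* pulsatile (ovariectomized-like): episodic boluses of ~3 ng/ml riding on a
  low baseline, with near-regular ~15 min inter-pulse intervals, sampled
  every 3 min for 120 min;
* surge (OVX + estradiol + progesterone-like): a sigmoidal rise beginning
  between 17:00 and 18:00, sampled at 16:00 (baseline), 19:00, 20:00 and
  21:00, with an optional suppressed (flat) variant.

The pulsatile generator is built for round-trip validation of the
nadir-to-peak pulse caller: between secretion events the level above
baseline decays exponentially with the clearance half-life, while within
the sampling interval that contains an event the sampled level rises by
exactly the bolus amplitude (secretion dominates clearance during the
event).  The sampled nadir-to-peak rise of an isolated pulse therefore
equals the drawn amplitude, which is what the caller measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PulsatileParams",
    "SurgeParams",
    "LHSeries",
    "SecretionTruth",
    "generate_pulsatile",
    "generate_surge",
]


@dataclass(frozen=True)
class PulsatileParams:
    """Parameters of the episodic-secretion model.

    ``mean_ipi`` (min) and ``ipi_shape`` define Gamma-distributed
    inter-event intervals (shape 8 gives near-regular pulsing); bolus
    amplitudes are lognormal with mean ``bolus_amp_mean`` (ng/ml) and
    coefficient of variation ``bolus_amp_cv``.  ``clearance_halflife`` is
    the exponential decay half-life of LH above baseline (min).
    """

    mean_ipi: float = 15.0
    ipi_shape: float = 8.0
    bolus_amp_mean: float = 3.0
    bolus_amp_cv: float = 0.2
    clearance_halflife: float = 10.0
    baseline: float = 0.5
    sample_interval: float = 3.0
    duration: float = 120.0
    noise_cv: float = 0.05
    assay_floor: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mean_ipi", "ipi_shape", "bolus_amp_mean",
                     "clearance_halflife", "baseline", "sample_interval",
                     "duration", "assay_floor"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.bolus_amp_cv < 0 or self.noise_cv < 0:
            raise ValueError("coefficients of variation must be non-negative")
        if self.sample_interval > self.mean_ipi / 2:
            raise ValueError("sample_interval must not exceed mean_ipi/2 "
                             "(pulses would be undetectable)")


@dataclass(frozen=True)
class SurgeParams:
    """Parameters of the timed LH surge model (times in clock hours)."""

    baseline: float = 0.5
    onset_time: float = 17.5
    peak_amp: float = 6.0
    rise_tau: float = 0.75
    fall_tau: float | None = None
    sample_times: tuple[float, ...] = (16.0, 19.0, 20.0, 21.0)
    noise_cv: float = 0.05
    assay_floor: float = 0.02
    suppressed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.baseline > 0 or not self.peak_amp > 0 or not self.rise_tau > 0:
            raise ValueError("baseline, peak_amp and rise_tau must be positive")
        if len(self.sample_times) < 2:
            raise ValueError("need at least a baseline and one later sample")
        if not self.onset_time > self.sample_times[0]:
            raise ValueError("onset_time must follow the baseline sample")


@dataclass
class LHSeries:
    """A sampled LH trace for one animal.

    ``times`` are minutes in pulse mode, clock hours in surge mode;
    ``lh`` is ng/ml.
    """

    times: np.ndarray
    lh: np.ndarray
    animal_id: str = "sim"
    mode: str = "pulse"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lh = np.asarray(self.lh, dtype=float)
        if len(self.times) != len(self.lh):
            raise ValueError("times and lh must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.lh < 0):
            raise ValueError("LH values must be non-negative")


@dataclass
class SecretionTruth:
    """Ground-truth secretion events behind a pulsatile series."""

    event_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    event_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {"event_times_min": [float(t) for t in self.event_times],
                "event_amplitudes_ng_per_ml":
                    [float(a) for a in self.event_amplitudes]}


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int
               ) -> np.ndarray:
    if cv <= 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - sigma2 / 2
    return np.exp(rng.normal(mu, np.sqrt(sigma2), size=size))


def generate_pulsatile(params: PulsatileParams
                       ) -> tuple[LHSeries, SecretionTruth]:
    """Simulate one pulsatile LH series and its ground truth.

    Event times follow a Gamma renewal process; the sampled series rises by
    the bolus amplitude across the sampling interval containing each event
    and decays exponentially toward baseline otherwise.  Multiplicative
    lognormal noise of CV ``noise_cv`` is applied and values are clipped at
    the assay floor.  Event placement, amplitudes and noise use separate
    random sub-streams, so the truth is stable under changes of
    ``noise_cv`` alone.
    """
    ss = np.random.SeedSequence(params.seed)
    ev_rng, amp_rng, noise_rng = [np.random.default_rng(c) for c in ss.spawn(3)]

    scale = params.mean_ipi / params.ipi_shape
    times = []
    t = 0.0
    while True:
        t += ev_rng.gamma(params.ipi_shape, scale)
        if t >= params.duration:
            break
        times.append(t)
    event_times = np.asarray(times)
    amps = _lognormal(amp_rng, params.bolus_amp_mean, params.bolus_amp_cv,
                      len(event_times))

    sample_t = np.arange(0.0, params.duration, params.sample_interval)
    decay = 0.5 ** (params.sample_interval / params.clearance_halflife)
    above = np.zeros(len(sample_t))
    level = 0.0
    for k, tk in enumerate(sample_t):
        if k == 0:
            above[0] = 0.0
            continue
        in_bin = (event_times > sample_t[k - 1]) & (event_times <= tk)
        if in_bin.any():
            level = level + amps[in_bin].sum()
        else:
            level = level * decay
        above[k] = level

    lh = params.baseline + above
    if params.noise_cv > 0:
        lh = lh * _lognormal(noise_rng, 1.0, params.noise_cv, len(lh))
    lh = np.maximum(lh, params.assay_floor)
    series = LHSeries(times=sample_t, lh=lh, mode="pulse")
    return series, SecretionTruth(event_times=event_times,
                                  event_amplitudes=amps)


def generate_surge(params: SurgeParams) -> LHSeries:
    """Simulate the four-sample LH surge design.

    The surge is a logistic rise of amplitude ``peak_amp`` above baseline
    with half-rise at ``onset_time + 2 * rise_tau`` (so the level at onset
    is ~12% of the peak), optionally followed by an exponential decay with
    ``fall_tau``.  ``suppressed=True`` returns baseline-level values at all
    samples, emulating a blocked surge.
    """
    ss = np.random.SeedSequence(params.seed)
    noise_rng = np.random.default_rng(ss.spawn(1)[0])
    t = np.asarray(params.sample_times, dtype=float)
    if params.suppressed:
        lh = np.full_like(t, params.baseline)
    else:
        t_half = params.onset_time + 2.0 * params.rise_tau
        rise = 1.0 / (1.0 + np.exp(-(t - t_half) / params.rise_tau))
        if params.fall_tau is not None:
            fall_start = t_half + 2.0 * params.rise_tau
            rise = rise * np.exp(-np.maximum(0.0, t - fall_start)
                                 / params.fall_tau)
        lh = params.baseline + params.peak_amp * rise
    if params.noise_cv > 0:
        lh = lh * _lognormal(noise_rng, 1.0, params.noise_cv, len(lh))
    lh = np.maximum(lh, params.assay_floor)
    return LHSeries(times=t, lh=lh, mode="surge")
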