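"""Running-cycle segmentation from shank gyroscope signals.

The angular-velocity signal of the tibialis-anterior sensor shows one
dominant local maximum per cycle at mid-swing. Segmentation proceeds in
stages: smooth with a sliding-average filter whose width tracks the motion
period, estimate the period from the autocorrelation function, pick swing
peaks, then locate heel-strike and toe-off as signal minima between peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema, find_peaks

from .errors import (
    InsufficientDataError,
    ParameterError,
    PeriodicityError,
    SegmentationError,
)
from .signal_io import SampledSignal, Side

#: Default autocorrelation search range: cadence 37–150 cycles/min per leg.
DEFAULT_PERIOD_RANGE_S = (0.4, 1.6)

#: Minimum peak separation and prominence, as fractions of the period and of
#: the filtered signal's dynamic range.
MIN_PEAK_SEPARATION_FRAC = 0.6
MIN_PEAK_PROMINENCE_FRAC = 0.3

STANCE = "stance"
SWING = "swing"


@dataclass(frozen=True)
class FilterWindow:
    """Width of the sliding-average filter, in samples."""

    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ParameterError(f"window must be >= 1 sample, got {self.n_samples}")


@dataclass
class GaitEvents:
    """Sample indices of gait events on the (filtered) gyro timebase.

    Between consecutive swing peaks there is exactly one heel strike
    followed by exactly one toe-off.
    """

    swing_peaks: np.ndarray
    heel_strikes: np.ndarray
    toe_offs: np.ndarray

    def __post_init__(self) -> None:
        for name in ("swing_peaks", "heel_strikes", "toe_offs"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            object.__setattr__(self, name, arr)
            if np.any(np.diff(arr) <= 0):
                raise SegmentationError(f"{name} not strictly increasing")
        if not (len(self.heel_strikes) == len(self.toe_offs) == len(self.swing_peaks) - 1):
            raise SegmentationError(
                "expected one heel strike and one toe-off per inter-peak interval"
            )
        for k in range(len(self.heel_strikes)):
            if not (
                self.swing_peaks[k]
                < self.heel_strikes[k]
                < self.toe_offs[k]
                <= self.swing_peaks[k + 1]
            ):
                raise SegmentationError(
                    f"events out of order in interval {k}: "
                    f"peak {self.swing_peaks[k]} -> hs {self.heel_strikes[k]} "
                    f"-> to {self.toe_offs[k]} -> peak {self.swing_peaks[k + 1]}"
                )


@dataclass
class Phase:
    f: int
    name: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Cycle:
    i: int
    start_s: float
    end_s: float
    phases: list[Phase]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class CyclePartition:
    """Contiguous, non-overlapping running cycles of one leg; the phases of
    each cycle tile it exactly."""

    side: Side
    cycles: list[Cycle] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cycles)

    def to_dict(self) -> dict:
        return {
            "side": self.side.value,
            "cycles": [
                {
                    "i": c.i,
                    "start_s": c.start_s,
                    "end_s": c.end_s,
                    "phases": [
                        {
                            "f": p.f,
                            "name": p.name,
                            "start_s": p.start_s,
                            "end_s": p.end_s,
                        }
                        for p in c.phases
                    ],
                }
                for c in self.cycles
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CyclePartition":
        return cls(
            side=Side(d["side"]),
            cycles=[
                Cycle(
                    i=c["i"],
                    start_s=c["start_s"],
                    end_s=c["end_s"],
                    phases=[
                        Phase(p["f"], p["name"], p["start_s"], p["end_s"])
                        for p in c["phases"]
                    ],
                )
                for c in d["cycles"]
            ],
        )


def moving_average(x: SampledSignal, w: FilterWindow) -> SampledSignal:
    """Sliding-average filter: y[i] = (1/N) * sum_{j=0..N-1} x[i+j].

    Output has length len(x) - N + 1; t0 is shifted forward by (N-1)/2
    samples so features keep their time position.
    """
    n = w.n_samples
    if n > len(x.samples):
        raise ParameterError(
            f"filter window ({n}) larger than signal ({len(x.samples)})"
        )
    csum = np.concatenate(([0.0], np.cumsum(x.samples)))
    y = (csum[n:] - csum[:-n]) / n
    return SampledSignal(y, x.rate_hz, x.t0_s + (n - 1) / 2 / x.rate_hz)


def autocorrelation(samples: np.ndarray) -> np.ndarray:
    """Biased sample autocorrelation r[k] = (1/n) sum (x_i - m)(x_{i+k} - m)."""
    x = np.asarray(samples, dtype=np.float64)
    x = x - x.mean()
    n = len(x)
    full = np.correlate(x, x, mode="full")
    return full[n - 1 :] / n


def estimate_period(
    x: SampledSignal,
    min_s: float = DEFAULT_PERIOD_RANGE_S[0],
    max_s: float = DEFAULT_PERIOD_RANGE_S[1],
) -> float:
    """Motion period (s): lag of the highest local autocorrelation maximum
    within [min_s, max_s]."""
    if not min_s < max_s:
        raise ParameterError(f"need min_s < max_s, got [{min_s}, {max_s}]")
    if x.duration_s < 3 * max_s:
        raise ParameterError(
            f"signal too short ({x.duration_s:.2f} s) to resolve periods "
            f"up to {max_s} s; need >= {3 * max_s:.2f} s"
        )
    r = autocorrelation(x.samples)
    if r[0] <= 0:
        raise PeriodicityError("zero-variance signal has no period")
    lo = max(int(math.floor(min_s * x.rate_hz)), 1)
    hi = min(int(math.ceil(max_s * x.rate_hz)), len(r) - 2)
    if hi <= lo:
        raise ParameterError("search range contains no lags at this rate")
    # local maxima of r over the closed lag range [lo, hi]
    maxima = argrelextrema(r[lo - 1 : hi + 2], np.greater)[0] + lo - 1
    maxima = maxima[(maxima >= lo) & (maxima <= hi)]
    if maxima.size == 0:
        raise PeriodicityError(
            f"no autocorrelation maximum in [{min_s}, {max_s}] s — aperiodic signal?"
        )
    best = maxima[np.argmax(r[maxima])]
    return best / x.rate_hz


def detect_swing_peaks(x_filtered: SampledSignal, period_s: float) -> np.ndarray:
    """Indices of swing-phase maxima: local maxima separated by at least
    0.6 period with prominence at least 0.3 of the dynamic range."""
    s = x_filtered.samples
    rng = float(s.max() - s.min())
    if rng <= 0:
        raise SegmentationError("flat signal: no peaks")
    distance = max(int(round(MIN_PEAK_SEPARATION_FRAC * period_s * x_filtered.rate_hz)), 1)
    peaks, _ = find_peaks(s, distance=distance, prominence=MIN_PEAK_PROMINENCE_FRAC * rng)
    if len(peaks) < 2:
        raise SegmentationError(f"found {len(peaks)} swing peak(s); need >= 2")
    return peaks.astype(np.int64)


def detect_cycle_events(
    x_filtered: SampledSignal, swing_peaks: np.ndarray
) -> GaitEvents:
    """Heel strike = earliest global minimum in the half interval after each
    swing peak; toe-off = earliest global minimum in the half interval before
    the next peak."""
    peaks = np.asarray(swing_peaks, dtype=np.int64)
    if len(peaks) < 2:
        raise SegmentationError("need >= 2 swing peaks to place events")
    s = x_filtered.samples
    heel, toe = [], []
    for k in range(len(peaks) - 1):
        interval = peaks[k + 1] - peaks[k]
        half = interval / 2
        hs_lo, hs_hi = peaks[k] + 1, peaks[k] + int(math.floor(half)) + 1
        to_lo, to_hi = peaks[k + 1] - int(math.floor(half)), peaks[k + 1] + 1
        hs = hs_lo + int(np.argmin(s[hs_lo:hs_hi]))  # argmin ties -> earliest
        to = to_lo + int(np.argmin(s[to_lo:to_hi]))
        if to <= hs:
            raise SegmentationError(
                f"degenerate stance in interval {k}: heel strike {hs} >= toe-off {to}"
            )
        heel.append(hs)
        toe.append(to)
    return GaitEvents(peaks, np.array(heel), np.array(toe))


def partition_cycles(
    events: GaitEvents,
    rate_hz: float,
    n_cycles: int = 20,
    side: Side = Side.LEFT,
    t0_s: float = 0.0,
) -> CyclePartition:
    """Build a stance/swing partition from gait events.

    Cycle k runs from heel strike k to heel strike k+1 (the leading swing
    fragment before the first heel strike is dropped; the trailing swing of
    the last available cycle ends at the final swing peak). Each cycle has
    exactly two phases: stance [heel strike, toe-off) then swing.
    """
    k_avail = len(events.heel_strikes)
    if k_avail < n_cycles:
        raise InsufficientDataError(
            f"only {k_avail} complete cycle(s) available, need {n_cycles}"
        )

    def t(idx: int) -> float:
        return t0_s + idx / rate_hz

    cycles: list[Cycle] = []
    for k in range(n_cycles):
        hs = events.heel_strikes[k]
        to = events.toe_offs[k]
        if k + 1 < k_avail:
            end = events.heel_strikes[k + 1]
        else:
            end = events.swing_peaks[k + 1]
        if not hs < to < end:
            raise SegmentationError(f"cycle {k} phases do not tile: {hs}, {to}, {end}")
        cycles.append(
            Cycle(
                i=k,
                start_s=t(hs),
                end_s=t(end),
                phases=[
                    Phase(1, STANCE, t(hs), t(to)),
                    Phase(2, SWING, t(to), t(end)),
                ],
            )
        )
    return CyclePartition(side=side, cycles=cycles)


def pick_filter_window(period_samples: float) -> FilterWindow:
    """Sliding-average width tied to the motion period: period/20, clamped
    to [3, period/4], forced odd."""
    n = int(round(period_samples / 20))
    n = max(3, min(n, max(int(period_samples / 4), 3)))
    if n % 2 == 0:
        n += 1
    return FilterWindow(n)


def segment_gait(
    gyro: SampledSignal,
    n_cycles: int = 20,
    side: Side = Side.LEFT,
    period_range_s: tuple[float, float] = DEFAULT_PERIOD_RANGE_S,
) -> CyclePartition:
    """Full gyro-to-cycles pipeline for one leg.

    A provisional period estimated on the raw signal sets the filter window;
    the period is then re-estimated once on the filtered signal before peak
    and event detection.
    """
    lo, hi = period_range_s
    period0 = estimate_period(gyro, lo, hi)
    w = pick_filter_window(period0 * gyro.rate_hz)
    filt = moving_average(gyro, w)
    period = estimate_period(filt, lo, hi)
    peaks = detect_swing_peaks(filt, period)
    events = detect_cycle_events(filt, peaks)
    return partition_cycles(
        events, filt.rate_hz, n_cycles=n_cycles, side=side, t0_s=filt.t0_s
    )
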