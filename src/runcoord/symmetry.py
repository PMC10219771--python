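"""Left/right symmetry of muscular effort.

For each muscle the squared (energy) EMG is enveloped by a cubic spline
through its local maxima, resampled onto a time-normalized per-cycle grid,
and the two sides are compared by a normalized cross-correlation at the
antiphase lag of half a cycle. The per-recording symmetry coefficient is
the unweighted mean over muscles, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d
from scipy.signal import argrelextrema, find_peaks

from .errors import (
    ConfigurationError,
    EnvelopeError,
    MetadataError,
    ParameterError,
    SymmetryUndefinedError,
)
from .gait import CyclePartition
from .signal_io import Recording, SampledSignal, Side

DEFAULT_POINTS_PER_CYCLE = 200


@dataclass
class EnergyEnvelope:
    """Spline envelope of EMG energy, resampled to ``cycle_len_pts`` points
    per cycle and concatenated over ``n_cycles`` cycles."""

    values: np.ndarray
    cycle_len_pts: int
    n_cycles: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.values) != self.n_cycles * self.cycle_len_pts:
            raise ValueError(
                f"envelope length {len(self.values)} != "
                f"{self.n_cycles} x {self.cycle_len_pts}"
            )
        if np.any(self.values < 0):
            raise ValueError("envelope values must be non-negative")

    def cycle(self, i: int) -> np.ndarray:
        return self.values[i * self.cycle_len_pts : (i + 1) * self.cycle_len_pts]


@dataclass
class SymmetryReport:
    per_muscle: dict[str, float] = field(default_factory=dict)

    @property
    def alpha_pct(self) -> float:
        if not self.per_muscle:
            raise ValueError("no per-muscle coefficients")
        return float(np.mean(list(self.per_muscle.values())))

    def to_dict(self) -> dict:
        return {"per_muscle": dict(self.per_muscle), "alpha_pct": self.alpha_pct}


def energy_signal(x: SampledSignal) -> SampledSignal:
    """Instantaneous energy: pointwise square of the EMG (mV^2)."""
    return SampledSignal(np.square(x.samples), x.rate_hz, x.t0_s)


def energy_envelope(
    e: SampledSignal,
    part: CyclePartition,
    points_per_cycle: int = DEFAULT_POINTS_PER_CYCLE,
) -> EnergyEnvelope:
    """Cubic spline through the local maxima of the energy signal, sampled
    on a uniform grid of ``points_per_cycle`` points per cycle.

    Endpoints of the analysed span are included as knots; negative spline
    excursions are clamped to zero. ``points_per_cycle`` is forced even so
    the antiphase half-cycle lag is an exact number of grid points.
    """
    if points_per_cycle < 16:
        raise ParameterError("points_per_cycle must be >= 16")
    if points_per_cycle % 2:
        points_per_cycle += 1
    if not part.cycles:
        raise ParameterError("empty cycle partition")
    span_start, span_end = part.cycles[0].start_s, part.cycles[-1].end_s
    if e.t0_s > span_start + 1e-9 or e.end_s < span_end - 1e-9:
        raise ParameterError(
            f"energy signal [{e.t0_s:.3f}, {e.end_s:.3f}] s does not cover "
            f"cycles [{span_start:.3f}, {span_end:.3f}] s"
        )
    seg = e.slice_time(span_start, span_end)
    # short-window averaging before knot picking: the raw squared EMG
    # oscillates at the carrier rate, and splining through its raw maxima
    # would track interference noise instead of effort bursts
    mean_cycle_s = (span_end - span_start) / len(part.cycles)
    sigma = max(0.02 * mean_cycle_s * seg.rate_hz, 1.0)
    s = gaussian_filter1d(seg.samples, sigma)
    # knots: local maxima at least ~3% of a cycle apart
    distance = max(int(round(0.03 * mean_cycle_s * seg.rate_hz)), 1)
    peaks, _ = find_peaks(s, distance=distance)
    if peaks.size < 4:
        # plateau maxima (e.g. a constant signal, whose envelope is itself)
        peaks = argrelextrema(s, np.greater_equal)[0]
        peaks = peaks[(peaks > 0) & (peaks < len(s) - 1)]
    if peaks.size < 4:
        raise EnvelopeError(
            f"only {peaks.size} local maxima in the analysed span; signal too sparse"
        )
    knots = peaks
    if knots[0] != 0:
        knots = np.concatenate(([0], knots))
    if knots[-1] != len(s) - 1:
        knots = np.concatenate((knots, [len(s) - 1]))
    # a smooth signal has sparse maxima and is (locally) its own envelope:
    # fill knot gaps wider than twice the nominal spacing with regular
    # samples so the spline does not bridge over entire cycles
    filled = [int(knots[0])]
    for k in knots[1:]:
        base, gap = filled[-1], int(k) - filled[-1]
        if gap > 2 * distance:
            n_extra = gap // distance - 1
            filled.extend(
                int(round(base + gap * (m + 1) / (n_extra + 1)))
                for m in range(n_extra)
            )
        filled.append(int(k))
    knots = np.unique(np.asarray(filled))
    spline = CubicSpline(seg.t0_s + knots / seg.rate_hz, s[knots])

    chunks = []
    for c in part.cycles:
        grid = c.start_s + (c.end_s - c.start_s) * np.arange(points_per_cycle) / points_per_cycle
        chunks.append(spline(grid))
    values = np.clip(np.concatenate(chunks), 0.0, None)
    return EnergyEnvelope(values, points_per_cycle, len(part.cycles))


def _half_cycle_shift(env: EnergyEnvelope) -> np.ndarray:
    """Circularly shift each cycle's block by half a cycle (the antiphase
    lag); with an even grid the +/- half-cycle shifts coincide, making the
    comparison symmetric in its arguments."""
    half = env.cycle_len_pts // 2
    blocks = env.values.reshape(env.n_cycles, env.cycle_len_pts)
    return np.roll(blocks, -half, axis=1).ravel()


def cross_corr_symmetry(env_l: EnergyEnvelope, env_r: EnergyEnvelope) -> float:
    """Normalized cross-correlation of the two envelopes at the half-cycle
    antiphase lag, clamped to [0, 1] and scaled to percent.

    The zero-mean cross sum is divided by the LARGER of the two envelopes'
    squared norms, not by their product: identical profiles give 100%,
    uncorrelated ones ~0%, a common gain on both limbs cancels — and,
    unlike the Pearson coefficient, a gain deficit on one limb lowers the
    value (envelopes equal up to gain g < 1 score g x 100%), which is what
    a symmetry measure of muscular *effort* has to register.
    """
    if (env_l.cycle_len_pts, env_l.n_cycles) != (env_r.cycle_len_pts, env_r.n_cycles):
        raise ParameterError("envelopes must share grid (cycle_len_pts, n_cycles)")
    x1 = env_l.values
    x2 = _half_cycle_shift(env_r)
    x1 = x1 - x1.mean()
    x2 = x2 - x2.mean()
    s11, s22 = float(np.dot(x1, x1)), float(np.dot(x2, x2))
    if s11 == 0 or s22 == 0:
        raise SymmetryUndefinedError("zero-variance envelope: symmetry undefined")
    r = float(np.dot(x1, x2)) / max(s11, s22)
    return max(0.0, min(1.0, r)) * 100.0


def symmetry_coefficient(
    rec: Recording,
    part_l: CyclePartition,
    part_r: CyclePartition,
    muscles: list[str] | None = None,
    points_per_cycle: int = DEFAULT_POINTS_PER_CYCLE,
) -> SymmetryReport:
    """Per-muscle antiphase correlation and its unweighted mean (alpha, %).

    Both sides' envelopes are evaluated on the left leg's cycle grid (a
    shared timebase) so the right leg's activity appears at the half-cycle
    antiphase lag that :func:`cross_corr_symmetry` removes. ``part_r`` is
    required so a caller cannot compute symmetry without having segmented
    both legs.
    """
    if muscles is None:
        muscles = sorted(
            set(rec.emg_muscles(Side.LEFT)) & set(rec.emg_muscles(Side.RIGHT))
        )
    if not muscles:
        raise ConfigurationError("no muscle present on both sides")
    if not part_r.cycles:
        raise ConfigurationError("right-leg partition is empty")
    report = SymmetryReport()
    for muscle in muscles:
        try:
            sig_l = rec.emg(muscle, Side.LEFT)
            sig_r = rec.emg(muscle, Side.RIGHT)
        except MetadataError as exc:
            raise ConfigurationError(
                f"muscle {muscle!r} missing on one side: {exc}"
            ) from exc
        env_l = energy_envelope(energy_signal(sig_l), part_l, points_per_cycle)
        env_r = energy_envelope(energy_signal(sig_r), part_l, points_per_cycle)
        report.per_muscle[muscle] = cross_corr_symmetry(env_l, env_r)
    return report
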